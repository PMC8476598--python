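#!/usr/bin/env python
"""Score the held-out virtual validation cohort with the fitted pipeline.

Runs the combined inference (tumor segmentation gating the biomarker
model), computes per-slide biomarker area percentages and the short/long
ratio, classifies by the cutoff rule, and reports diagnostic metrics and
ground-truth recovery IoUs. Writes one score table per replicate.

Run after 02:  python analysis/03_score_validation_cohort.py
"""

import argparse
from pathlib import Path

from wsidbm.pipeline import FittedPipeline, evaluate_on_cohort
from wsidbm.slide_core import write_score_table
from wsidbm.synthetic_cohort import load_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohorts/test"))
    ap.add_argument("--model", type=Path, default=Path("results/models/pipeline.json"))
    ap.add_argument("--out", type=Path, default=Path("results/scores"))
    args = ap.parse_args()

    cohort = load_cohort(args.cohort)
    pipe = FittedPipeline.load(args.model)
    res = evaluate_on_cohort(pipe, cohort)
    args.out.mkdir(parents=True, exist_ok=True)
    for rid, tab in res["scores"].items():
        rows = [
            {
                "slide_id": r.slide_id,
                "long_dbm_pct": r.long_dbm_pct,
                "short_dbm_pct": r.short_dbm_pct,
                "ratio": r.ratio,
                "outcome": cohort.outcome_of_slide(r.slide_id).value,
                "prediction": r.prediction,
            }
            for r in tab.itertuples()
        ]
        path = write_score_table(rows, args.out / f"scores_rep{rid}.csv")
        m = res["metrics"][rid]
        print(
            f"replicate {rid}: {m.n_correct}/{m.n} correct | "
            f"sensitivity {m.sensitivity:.0f}% specificity {m.specificity:.0f}% "
            f"ppv {m.ppv:.0f}% accuracy {m.accuracy:.0f}% -> {path}"
        )
    conc = res["concordance"]
    if conc:
        print(
            f"replicate agreement {conc.agreement_pct:.0f}%; "
            f"rep2 misclassified subset of rep1: {conc.rep2_subset_of_rep1}"
        )
    print(f"stage-1 tumor IoU {res['tumor_iou']:.3f}; dbm_short recovery IoU {res['dbm_short_iou']:.3f}")


if __name__ == "__main__":
    main()
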