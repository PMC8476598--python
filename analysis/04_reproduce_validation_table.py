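#!/usr/bin/env python
"""Reproduce the published validation-table classification exactly.

Applies the ratio >= 30 cutoff rule to the packaged per-slide validation
fixture (22 test slides × 2 replicates), verifies the published prediction
column row for row, and prints the replicate-2 diagnostic metrics and the
replicate-concordance observation. Writes results/table3_metrics.json.

Run:  python analysis/04_reproduce_validation_table.py
"""

import argparse
import json
from pathlib import Path

from wsidbm.evaluation import (
    evaluate,
    fixture_predictions,
    load_validation_fixture,
    replicate_concordance,
)
from wsidbm.slide_core import Outcome


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cutoff", type=float, default=30.0)
    ap.add_argument("--out", type=Path, default=Path("results/table3_metrics.json"))
    args = ap.parse_args()

    fixture = load_validation_fixture()
    report = {"cutoff": args.cutoff}
    for rep in (1, 2):
        preds, outs = fixture_predictions(fixture, rep, cutoff=args.cutoff)
        printed = {
            r.slide_id: Outcome.parse(r.prediction)
            for r in fixture[fixture.replicate == rep].itertuples()
        }
        match = sum(preds[s] is printed[s] for s in printed)
        m = evaluate(preds, outs)
        report[f"replicate_{rep}"] = {
            "printed_predictions_matched": f"{match}/22",
            "confusion": {"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn},
            **m.rounded(),
        }
        print(f"replicate {rep}: matched printed predictions {match}/22; "
              f"{m.n_correct}/22 correct; rounded metrics {m.rounded()}")
    p1, outs = fixture_predictions(fixture, 1, cutoff=args.cutoff)
    p2, _ = fixture_predictions(fixture, 2, cutoff=args.cutoff)
    conc = replicate_concordance(p1, p2, outs)
    report["concordance"] = {
        "agreement_pct": conc.agreement_pct,
        "misclassified_rep1": sorted(conc.misclassified_rep1),
        "misclassified_rep2": sorted(conc.misclassified_rep2),
        "rep2_subset_of_rep1": conc.rep2_subset_of_rep1,
    }
    print(
        f"misclassified rep1 {sorted(conc.misclassified_rep1)}, "
        f"rep2 {sorted(conc.misclassified_rep2)}; subset: {conc.rep2_subset_of_rep1}"
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
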