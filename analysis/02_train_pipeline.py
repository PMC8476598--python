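#!/usr/bin/env python
"""Train the three-stage pipeline on the simulated training cohort.

Stage 1 learns tumor segmentation from the ground-truth tumor annotations;
stage 2 relabels the predicted tumor regions with each patient's outcome
group and learns the weak association; stage 3 confidence-filters stage-2
output into digital-biomarker annotations, curates them against the
exclusion classes, and trains the final model in two replicates with
identical parameters. The fitted pipeline is saved as JSON for the scoring
step.

Run after 01:  python analysis/02_train_pipeline.py
"""

import argparse
from pathlib import Path

from wsidbm.pipeline import PipelineConfig, train_pipeline
from wsidbm.synthetic_cohort import load_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohorts/train"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cutoff", type=float, default=1.0)
    ap.add_argument("--out", type=Path, default=Path("results/models/pipeline.json"))
    args = ap.parse_args()

    cohort = load_cohort(args.cohort)
    print(f"training on {len(cohort.slides)} slides from {len(cohort.labels)} patients")
    pipe = train_pipeline(cohort, PipelineConfig(cutoff=args.cutoff), seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pipe.save(args.out)
    print(f"curation confidence threshold chosen from ladder: {pipe.confidence_threshold}")
    for rep in pipe.replicates:
        final = rep.learner.training_log[-1]["train_log_loss"]
        print(f"replicate {rep.replicate_id} (seed {rep.seed}): final train log-loss {final:.4f}")
    print(f"saved -> {args.out}")


if __name__ == "__main__":
    main()
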