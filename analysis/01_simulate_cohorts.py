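#!/usr/bin/env python
"""Generate the virtual training and validation cohorts used by the analysis.

Emulates the study design at desk scale: two outcome groups (platinum-free
interval <= 6 months vs >= 18 months), several slides per training patient,
and a separate 22-patient validation cohort with one slide each. Writes the
slides, per-pixel ground-truth masks, and metadata/truth tables under
results/cohorts/.

Run:  python analysis/01_simulate_cohorts.py [--seed 11]
"""

import argparse
from pathlib import Path

from wsidbm.pipeline import benchmark_specs
from wsidbm.synthetic_cohort import generate_cohort, write_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results/cohorts"))
    args = ap.parse_args()

    train_spec, test_spec = benchmark_specs(mixture_bias=0.6, contrast=1.0, seed=args.seed)
    for name, spec in (("train", train_spec), ("test", test_spec)):
        cohort = generate_cohort(spec)
        outdir = write_cohort(cohort, args.out / name)
        meta = cohort.metadata
        groups = meta.drop_duplicates("patient_id").group.value_counts()
        print(
            f"{name}: {len(cohort.slides)} slides from {meta.patient_id.nunique()} patients "
            f"({groups.get('PFI_S', 0)} short / {groups.get('PFI_L', 0)} long) -> {outdir}"
        )
        tt = cohort.truth_table.merge(meta, on="slide_id")
        by_group = tt.groupby("group")[["p_short_like", "p_long_like"]].mean()
        print("  mean planted texture fractions of tumor area:")
        print(by_group.to_string())


if __name__ == "__main__":
    main()
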