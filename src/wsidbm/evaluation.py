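"""Diagnostic-test metrics, replicate concordance, and the published
per-slide validation fixture.

The packaged fixture (``data/table3_fixture.csv``) transcribes the original
workflow's published per-slide validation results: 22 test slides × 2
replicate trainings of the final model, with long/short biomarker area
percentages, their ratio, the true outcome group and the published
prediction. It is the exact-reproduction surface for the classifier rule:
applying the ratio-cutoff rule to the fixture's printed ratio column must
reproduce the published prediction column row for row.

Two rows per replicate print a long-biomarker area of 0.0 % that is not a
true zero (flagged in ``long_pct_is_floor``); ratios were computed from
unrounded values upstream, which is why the evaluation path uses the
printed ratio column and only cross-checks the rounded-column recomputation.

Positive class throughout: the short-PFI group.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .slide_core import MetadataError, Outcome

__all__ = [
    "ConcordanceReport",
    "MetricsReport",
    "evaluate",
    "evaluate_fixture_replicate",
    "fixture_predictions",
    "load_validation_fixture",
    "replicate_concordance",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (the convention of the published metrics:
    72.7 → 73, 90.9 → 91, 88.9 → 89, 81.8 → 82)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-matrix metrics with PFI_S as the positive class.

    Percentages are kept at full precision; ``rounded()`` gives the
    whole-percent half-up view used for comparison with published values.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_correct / self.n if self.n else float("nan")

    def rounded(self) -> dict[str, float]:
        return {
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
            "ppv": round_half_up(self.ppv),
            "npv": round_half_up(self.npv),
            "accuracy": round_half_up(self.accuracy),
        }


def _as_outcome_map(values: Mapping[str, object]) -> dict[str, Outcome]:
    return {str(k): v if isinstance(v, Outcome) else Outcome.parse(str(v)) for k, v in values.items()}


def evaluate(
    predictions: Mapping[str, object], outcomes: Mapping[str, object]
) -> MetricsReport:
    """Confusion-matrix metrics over a slide set (positive class PFI_S).

    Raises listing the symmetric difference if the two inputs do not cover
    the same slides.
    """
    preds = _as_outcome_map(predictions)
    outs = _as_outcome_map(outcomes)
    if set(preds) != set(outs):
        only_p = sorted(set(preds) - set(outs))
        only_o = sorted(set(outs) - set(preds))
        raise MetadataError(
            f"slide sets differ: only in predictions {only_p}, only in outcomes {only_o}"
        )
    tp = fp = tn = fn = 0
    for sid, truth in outs.items():
        pred = preds[sid]
        if truth is Outcome.PFI_S:
            tp += pred is Outcome.PFI_S
            fn += pred is Outcome.PFI_L
        else:
            tn += pred is Outcome.PFI_L
            fp += pred is Outcome.PFI_S
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between two replicate trainings on the same slide set."""

    n: int
    n_agree: int
    misclassified_rep1: frozenset[str]
    misclassified_rep2: frozenset[str]

    @property
    def agreement_pct(self) -> float:
        return 100.0 * self.n_agree / self.n if self.n else float("nan")

    @property
    def rep2_subset_of_rep1(self) -> bool:
        return self.misclassified_rep2 <= self.misclassified_rep1


def replicate_concordance(
    preds_rep1: Mapping[str, object],
    preds_rep2: Mapping[str, object],
    outcomes: Mapping[str, object],
) -> ConcordanceReport:
    p1, p2, outs = _as_outcome_map(preds_rep1), _as_outcome_map(preds_rep2), _as_outcome_map(outcomes)
    if not (set(p1) == set(p2) == set(outs)):
        raise MetadataError(
            "replicate predictions and outcomes must cover the same slides; got "
            f"{sorted(set(p1) ^ set(outs))} / {sorted(set(p2) ^ set(outs))} mismatched"
        )
    agree = sum(p1[s] is p2[s] for s in outs)
    mis1 = frozenset(s for s in outs if p1[s] is not outs[s])
    mis2 = frozenset(s for s in outs if p2[s] is not outs[s])
    return ConcordanceReport(
        n=len(outs), n_agree=agree, misclassified_rep1=mis1, misclassified_rep2=mis2
    )


# ---------------------------------------------------------------------------
# The published validation fixture
# ---------------------------------------------------------------------------


def load_validation_fixture() -> pd.DataFrame:
    """Load the packaged 44-row validation fixture (both replicates).

    Validates the transcription invariants: 22 unique slides per replicate,
    the printed ratio ascending within each replicate, and outcomes
    consistent for each slide across replicates.
    """
    with resources.files("wsidbm.data").joinpath("table3_fixture.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"slide_id": str})
    for rep, grp in df.groupby("replicate"):
        if grp["slide_id"].nunique() != 22 or len(grp) != 22:
            raise MetadataError(f"fixture replicate {rep}: expected 22 unique slides")
        if not np.all(np.diff(grp["ratio"].to_numpy()) >= 0):
            raise MetadataError(f"fixture replicate {rep}: ratio column not ascending")
    pivot = df.pivot(index="slide_id", columns="replicate", values="outcome")
    if not (pivot[1] == pivot[2]).all():
        raise MetadataError("fixture: outcome differs across replicates for some slide")
    return df


def fixture_predictions(
    df: pd.DataFrame, replicate: int, cutoff: float = 30.0
) -> tuple[dict[str, Outcome], dict[str, Outcome]]:
    """(cutoff-rule predictions from the printed ratio column, outcomes)."""
    grp = df[df["replicate"] == replicate]
    preds = {
        r.slide_id: (Outcome.PFI_S if r.ratio >= cutoff else Outcome.PFI_L)
        for r in grp.itertuples()
    }
    outs = {r.slide_id: Outcome.parse(r.outcome) for r in grp.itertuples()}
    return preds, outs


def evaluate_fixture_replicate(replicate: int = 2, cutoff: float = 30.0) -> MetricsReport:
    preds, outs = fixture_predictions(load_validation_fixture(), replicate, cutoff)
    return evaluate(preds, outs)
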