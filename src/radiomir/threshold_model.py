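"""Threshold (perfect-separation) analysis of detection fluorescence.

Each gene's fold-change test yields a binary outcome — failure (F) when the
fold change is zero, success (S) otherwise. When the two classes are
perfectly separable in fluorescence, the detection threshold θ is only
identified up to an interval: (max fluorescence among failures,
min fluorescence among successes). The interval is reported in full; the
operative cutpoint used for classification is its midpoint, with
``x > θ → S`` and ``x ≤ θ → F``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .normalization import GeneSignal


@dataclass(frozen=True)
class DetectionOutcome:
    gene_id: str
    outcome: str  # "S" or "F"
    fluorescence: float


@dataclass(frozen=True)
class ThresholdInterval:
    condition_id: str
    lower: float  # max fluorescence among failures
    upper: float  # min fluorescence among successes
    separated: bool

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2.0


def classify_outcomes(
    fold_changes: dict[str, float],
    signals: list[GeneSignal],
) -> list[DetectionOutcome]:
    """Label each gene S/F from its fold change; attach its mean fluorescence."""
    by_gene = {s.gene_id: s for s in signals}
    missing = sorted(g for g in fold_changes if g not in by_gene)
    if missing:
        raise ValidationError(f"no signal for gene(s): {', '.join(missing)}")
    return [
        DetectionOutcome(
            gene_id=g,
            outcome="F" if fc == 0 else "S",
            fluorescence=by_gene[g].mean_intensity,
        )
        for g, fc in fold_changes.items()
    ]


def estimate_threshold(outcomes: list[DetectionOutcome], condition_id: str) -> ThresholdInterval:
    """Interval bracketing θ: (max failure fluorescence, min success fluorescence)."""
    failures = [o.fluorescence for o in outcomes if o.outcome == "F"]
    successes = [o.fluorescence for o in outcomes if o.outcome == "S"]
    if not failures or not successes:
        raise ValidationError("threshold undefined: single-class data")
    lower = max(failures)
    upper = min(successes)
    return ThresholdInterval(condition_id=condition_id, lower=lower, upper=upper, separated=lower < upper)


def apply_threshold(x: float, interval: ThresholdInterval) -> str:
    """Classify a fluorescence value against the midpoint cutpoint."""
    if not interval.separated:
        raise ValidationError("cannot apply an unseparated threshold interval")
    return "S" if x > interval.midpoint else "F"
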