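"""Control-ratio normalization of probe-level fluorescence.

The scheme follows the classic housekeeping-control design of spotted miRNA
arrays: every gene is printed in triplicate; replicate spots are averaged;
each gene's mean intensity is divided by the mean intensity of the
positive-control (housekeeping, e.g. U6 / 5S rRNA analogue) probes on the
same array; bacterial negative-control probes define the background used for
detection QC. Fold change between two conditions is the ratio of the two
normalized values, with 0 encoding non-detection on either side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .array_io import ArrayCondition
from .errors import ValidationError

CHANNELS = ("F635", "F532")


@dataclass
class GeneSignal:
    """Per-gene aggregated fluorescence for one array condition."""

    gene_id: str
    mean_intensity: float
    sd_intensity: float
    n_replicates: int
    detected: bool
    control_class: str = "probe"


@dataclass
class NormalizedExpression:
    """Per-gene intensity as a ratio to the positive-control average."""

    gene_id: str
    value: float
    condition_ref: str
    cv: float  # replicate-level coefficient of variation, for SD propagation
    detected: bool


@dataclass
class QCReport:
    condition_ref: str
    background: float | None
    flagged_genes: list[str] = field(default_factory=list)
    warning: str | None = None


@dataclass(frozen=True)
class FoldChange:
    fc: float
    sd: float


def aggregate_replicates(
    condition: ArrayCondition,
    channel: str = "F635",
    detection_floor: float = 0.0,
) -> list[GeneSignal]:
    """Average triplicate spots per gene.

    Sample SD uses the n−1 denominator (SD = 0 for a single spot); a gene is
    ``detected`` when its mean exceeds ``detection_floor``.
    """
    if channel not in CHANNELS:
        raise ValidationError(f"channel must be one of {CHANNELS}")
    if not condition.spots:
        raise ValidationError(f"condition {condition.condition_id} has no spots")
    attr = "signal_f635" if channel == "F635" else "signal_f532"
    by_gene: dict[str, list[float]] = {}
    cls: dict[str, str] = {}
    for spot in condition.spots:
        by_gene.setdefault(spot.gene_id, []).append(getattr(spot, attr))
        cls[spot.gene_id] = spot.control_class
    signals = []
    for gene, vals in by_gene.items():
        arr = np.asarray(vals, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        signals.append(
            GeneSignal(
                gene_id=gene,
                mean_intensity=mean,
                sd_intensity=sd,
                n_replicates=arr.size,
                detected=mean > detection_floor,
                control_class=cls[gene],
            )
        )
    return signals


def qc_negative_controls(signals: list[GeneSignal]) -> QCReport:
    """Flag probe genes whose mean does not exceed the negative-control background.

    Background is the arithmetic mean of negative-control gene means. Flagged
    genes are also marked ``detected = False`` in place. With no negative
    controls present the report carries a warning and no flags.
    """
    condition_ref = ""
    negatives = [s.mean_intensity for s in signals if s.control_class == "negative_control"]
    if not negatives:
        return QCReport(condition_ref, background=None, warning="no negative controls present")
    background = float(np.mean(negatives))
    flagged = []
    for s in signals:
        if s.control_class == "probe" and s.mean_intensity <= background:
            s.detected = False
            flagged.append(s.gene_id)
    return QCReport(condition_ref, background=background, flagged_genes=flagged)


def normalize(signals: list[GeneSignal], condition_ref: str = "") -> list[NormalizedExpression]:
    """Divide each gene mean by the average of positive-control gene means."""
    positives = [s.mean_intensity for s in signals if s.control_class == "positive_control"]
    if not positives or np.mean(positives) == 0:
        raise ValidationError("normalization undefined: no nonzero positive controls")
    ref = float(np.mean(positives))
    out = []
    for s in signals:
        cv = s.sd_intensity / s.mean_intensity if s.mean_intensity > 0 else 0.0
        out.append(
            NormalizedExpression(
                gene_id=s.gene_id,
                value=s.mean_intensity / ref,
                condition_ref=condition_ref,
                cv=cv,
                detected=s.detected,
            )
        )
    return out


def fold_change(
    treated: list[NormalizedExpression],
    control: list[NormalizedExpression],
) -> dict[str, FoldChange]:
    """Per-gene ratio of normalized values, treated / control.

    If either side is undetected the fold change is reported as 0 with SD 0
    (the convention the screen tables use for absent signal). Otherwise the
    SD is first-order (delta-method) propagation of the replicate CVs:
    ``sd ≈ fc * sqrt(cv_t² + cv_c²)``.
    """
    t = {e.gene_id: e for e in treated}
    c = {e.gene_id: e for e in control}
    asym = sorted(set(t) ^ set(c))
    if asym:
        raise ValidationError(f"genes present on one side only: {', '.join(asym)}")
    out: dict[str, FoldChange] = {}
    for gene, te in t.items():
        ce = c[gene]
        if not te.detected or not ce.detected or ce.value == 0:
            out[gene] = FoldChange(0.0, 0.0)
            continue
        fc = te.value / ce.value
        sd = fc * math.sqrt(te.cv**2 + ce.cv**2)
        out[gene] = FoldChange(fc, sd)
    return out
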