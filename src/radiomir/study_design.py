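"""Correlation-based sample-size calculation.

The group size needed to detect an expected correlation R between paired
observations is, via the Fisher z-transform C(R) = ½·ln[(1+R)/(1−R)],

    n = (z_alpha + z_beta)² / C(R)² + 3

with (z_alpha + z_beta)² defaulting to 8.52 (≈ 2.92², two-sided alpha 0.05
at ~80% power). n decreases monotonically in R and approaches its floor of
3 as R → 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

DEFAULT_Z_SUM_SQ = 8.52


@dataclass(frozen=True)
class PowerSpec:
    r: float
    z_sum_sq: float
    c: float  # Fisher z-transform of r
    n_raw: float
    n_required: int
    rounding: str


def fisher_z(r: float) -> float:
    """C(r) = ½ ln((1+r)/(1−r))."""
    if not 0 < r < 1:
        raise ValidationError("correlation must be in (0,1) exclusive")
    return 0.5 * math.log((1 + r) / (1 - r))


def sample_size(r: float, z_sum_sq: float = DEFAULT_Z_SUM_SQ, rounding: str = "ceil") -> PowerSpec:
    """Patients per group needed to detect correlation ``r``.

    ``rounding='ceil'`` (default) is conservative; ``'nearest'`` rounds to
    the closest integer.
    """
    if z_sum_sq <= 0:
        raise ValidationError("z_sum_sq must be positive")
    if rounding not in ("ceil", "nearest"):
        raise ValidationError("rounding must be 'ceil' or 'nearest'")
    c = fisher_z(r)
    n_raw = z_sum_sq / c**2 + 3
    n_required = math.ceil(n_raw) if rounding == "ceil" else round(n_raw)
    return PowerSpec(r=r, z_sum_sq=z_sum_sq, c=c, n_raw=n_raw, n_required=int(n_required), rounding=rounding)
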