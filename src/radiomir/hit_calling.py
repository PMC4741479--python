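"""Hit calling on screen fold changes: the ±2-SD rule.

A miRNA is called *up* when fc − 1 ≥ k·sd (fc > 1), *down* when
1 − fc ≥ k·sd (fc < 1), *undetected* when fc = 0 and sd = 0 (absent signal,
not repression), and *unchanged* otherwise; k defaults to 2. Ties with the
k·sd bound count as significant. A zero SD with fc ∉ {0, 1} is called
significant: any nonzero effect exceeds a zero-width noise band.
"""

from __future__ import annotations

from dataclasses import dataclass

from .array_io import GENOTYPES, FoldChangeRecord
from .errors import ValidationError

CALLS = ("up", "down", "unchanged", "undetected")


@dataclass(frozen=True)
class HitCall:
    mirna_id: str
    genotype: str
    call: str
    effect: float  # fc − 1, signed
    threshold_used: float  # k · sd


@dataclass(frozen=True)
class ScreenSummary:
    n_up: int
    n_down: int
    n_altered: int
    n_undetected: int
    n_unchanged: int
    sd_multiplier: float
    genotype: str


def call_hit(
    mirna_id: str,
    genotype: str,
    fc: float,
    sd: float,
    sd_multiplier: float = 2.0,
) -> HitCall:
    """Classify one fold change ± SD."""
    if fc < 0 or sd < 0:
        raise ValidationError(f"fc and sd must be non-negative for {mirna_id!r}")
    if sd_multiplier <= 0:
        raise ValidationError("sd_multiplier must be positive")
    threshold = sd_multiplier * sd
    if fc == 0 and sd == 0:
        call = "undetected"
    elif fc > 1 and fc - 1 >= threshold:
        call = "up"
    elif fc < 1 and 1 - fc >= threshold:
        call = "down"
    else:
        call = "unchanged"
    return HitCall(mirna_id=mirna_id, genotype=genotype, call=call, effect=fc - 1, threshold_used=threshold)


def format_hit_table(calls: list[HitCall], summary: "ScreenSummary") -> str:
    """Deterministic TSV rendering of a call table, summary line last.

    Byte-stable for identical inputs; used for the checked-in regression
    table and by the CLI.
    """
    lines = ["mirna_id\tgenotype\tcall\teffect\tthreshold_used"]
    for h in calls:
        lines.append(f"{h.mirna_id}\t{h.genotype}\t{h.call}\t{h.effect!r}\t{h.threshold_used!r}")
    lines.append(
        f"# summary genotype={summary.genotype} sd_multiplier={summary.sd_multiplier!r} "
        f"n_up={summary.n_up} n_down={summary.n_down} n_altered={summary.n_altered} "
        f"n_undetected={summary.n_undetected} n_unchanged={summary.n_unchanged}"
    )
    return "\n".join(lines) + "\n"


def screen_hits(
    records: list[FoldChangeRecord],
    genotype: str = "ATM_null",
    sd_multiplier: float = 2.0,
) -> tuple[list[HitCall], ScreenSummary]:
    """Call every record for one genotype and summarize the counts."""
    if genotype not in GENOTYPES:
        raise ValidationError(f"genotype must be one of {GENOTYPES}")
    if not records:
        raise ValidationError("empty record list")
    calls = []
    for rec in records:
        fc, sd = rec.fc_sd(genotype)
        calls.append(call_hit(rec.mirna_id, genotype, fc, sd, sd_multiplier))
    n = {c: sum(1 for h in calls if h.call == c) for c in CALLS}
    summary = ScreenSummary(
        n_up=n["up"],
        n_down=n["down"],
        n_altered=n["up"] + n["down"],
        n_undetected=n["undetected"],
        n_unchanged=n["unchanged"],
        sd_multiplier=sd_multiplier,
        genotype=genotype,
    )
    return calls, summary
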