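"""Cohort concordance screen: from patient expression to a signature.

Patients fall into three arms — irradiated with complete response
(*responder*, radiosensitive), irradiated with tumor progression
(*progressor*, radioresistant), and *untreated*. For each miRNA the arm
means are compared to the untreated mean as ratios, and responders are
tested against progressors with a Welch t-test on log2(x + pseudo).

A miRNA joins the signature when

1. its responder and progressor directions (sign of the log2 ratio beyond a
   dead band ``epsilon``) are opposite and non-flat — the inverse-pattern
   requirement,
2. the responder direction matches the in vitro reference direction, and
3. the responder-vs-progressor p-value is at most ``alpha``.

The in vitro reference is either a genotype (directions derived from the
screen table via the hit-calling rule) or an explicit miRNA → up/down map.

The module also compares ATM protein (RPPA) levels between responders and
progressors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .array_io import GENOTYPES, GROUPS, FoldChangeRecord, PatientRecord
from .errors import ValidationError
from .hit_calling import call_hit


@dataclass(frozen=True)
class GroupRatio:
    mirna_id: str
    ratio_responder: float
    ratio_progressor: float
    p_value: float
    n_responder: int
    n_progressor: int
    n_untreated: int
    undefined: bool = False  # untreated mean (plus pseudocount) was zero


@dataclass(frozen=True)
class SignatureEntry:
    mirna_id: str
    direction_responder: str  # up / down / flat
    direction_progressor: str
    invitro_direction: str  # up / down / unchanged / undetected
    concordant: bool
    p_value: float


@dataclass(frozen=True)
class AtmComparison:
    mean_responder: float
    mean_progressor: float
    p_value: float
    direction: int  # sign of (mean_responder − mean_progressor)
    n_responder: int
    n_progressor: int


def _split_groups(cohort: list[PatientRecord]) -> dict[str, list[PatientRecord]]:
    groups: dict[str, list[PatientRecord]] = {g: [] for g in GROUPS}
    for p in cohort:
        groups[p.group].append(p)
    return groups


def group_ratios(
    cohort: list[PatientRecord],
    pseudo: float = 1.0,
    log_transform: bool = True,
    equal_var: bool = False,
) -> list[GroupRatio]:
    """Per-miRNA arm-mean ratios vs untreated, with a responder-vs-progressor t-test.

    Ratios use ``(mean + pseudo) / (mean_untreated + pseudo)``; the t-test is
    Welch by default (``equal_var=True`` gives the pooled Student variant) on
    log2(x + pseudo) expression unless ``log_transform`` is off.
    """
    if pseudo < 0:
        raise ValidationError("pseudocount must be non-negative")
    groups = _split_groups(cohort)
    empty = [g for g in GROUPS if not groups[g]]
    if empty:
        raise ValidationError(f"cohort is missing group(s): {', '.join(empty)}")
    mirnas = list(cohort[0].expression)
    out = []
    for m in mirnas:
        vals = {g: np.array([p.expression[m] for p in groups[g]], dtype=float) for g in GROUPS}
        means = {g: float(v.mean()) for g, v in vals.items()}
        denom = means["untreated"] + pseudo
        undefined = denom == 0
        rr = math.nan if undefined else (means["responder"] + pseudo) / denom
        rp = math.nan if undefined else (means["progressor"] + pseudo) / denom
        if log_transform:
            a = np.log2(vals["responder"] + pseudo)
            b = np.log2(vals["progressor"] + pseudo)
        else:
            a, b = vals["responder"], vals["progressor"]
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        p = float(res.pvalue)
        if math.isnan(p):  # zero variance in both groups, identical means
            p = 1.0
        out.append(
            GroupRatio(
                mirna_id=m,
                ratio_responder=rr,
                ratio_progressor=rp,
                p_value=p,
                n_responder=len(vals["responder"]),
                n_progressor=len(vals["progressor"]),
                n_untreated=len(vals["untreated"]),
                undefined=undefined,
            )
        )
    return out


def _direction(ratio: float, epsilon: float) -> str:
    if math.isnan(ratio):
        return "flat"
    log2r = math.log2(ratio) if ratio > 0 else -math.inf
    if log2r > epsilon:
        return "up"
    if log2r < -epsilon:
        return "down"
    return "flat"


def concordance_screen(
    ratios: list[GroupRatio],
    screen: list[FoldChangeRecord],
    reference: str | dict[str, str] = "ATM_null",
    epsilon: float = 0.25,
    alpha: float = 0.05,
    sd_multiplier: float = 2.0,
) -> list[SignatureEntry]:
    """Score every miRNA for concordance with the in vitro reference.

    Returns one entry per ratio miRNA found in the screen; the signature is
    the ``concordant`` subset. Ratio miRNAs absent from the screen are
    skipped with a warning.
    """
    by_id = {r.mirna_id: r for r in screen}
    if isinstance(reference, str):
        if reference not in GENOTYPES:
            raise ValidationError(f"unknown reference genotype {reference!r}")
        invitro = {
            m: call_hit(m, reference, *by_id[m].fc_sd(reference), sd_multiplier).call
            for m in by_id
        }
    else:
        bad = {d for d in reference.values() if d not in ("up", "down")}
        if bad:
            raise ValidationError(f"direction table contains invalid direction(s): {bad}")
        invitro = {m: reference.get(m, "unchanged") for m in by_id}
    entries = []
    for r in ratios:
        if r.mirna_id not in by_id:
            warnings.warn(f"miRNA {r.mirna_id!r} not in screen table; ignored", stacklevel=2)
            continue
        d_resp = _direction(r.ratio_responder, epsilon)
        d_prog = _direction(r.ratio_progressor, epsilon)
        ref_dir = invitro[r.mirna_id]
        concordant = (
            d_resp != "flat"
            and d_prog != "flat"
            and d_resp != d_prog
            and ref_dir in ("up", "down")
            and d_resp == ref_dir
            and r.p_value <= alpha
        )
        entries.append(
            SignatureEntry(
                mirna_id=r.mirna_id,
                direction_responder=d_resp,
                direction_progressor=d_prog,
                invitro_direction=ref_dir,
                concordant=concordant,
                p_value=r.p_value,
            )
        )
    return entries


def signature_members(entries: list[SignatureEntry]) -> list[str]:
    """The concordant subset, in entry order."""
    return [e.mirna_id for e in entries if e.concordant]


def atm_group_comparison(cohort: list[PatientRecord]) -> AtmComparison:
    """Welch t-test of ATM RPPA levels, responders vs progressors."""
    groups = _split_groups(cohort)
    resp = np.array([p.atm_protein for p in groups["responder"] if p.atm_protein is not None], dtype=float)
    prog = np.array([p.atm_protein for p in groups["progressor"] if p.atm_protein is not None], dtype=float)
    if len(resp) < 2 or len(prog) < 2:
        raise ValidationError("insufficient RPPA data: need ≥2 ATM values per response group")
    res = stats.ttest_ind(resp, prog, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0
    diff = float(resp.mean() - prog.mean())
    return AtmComparison(
        mean_responder=float(resp.mean()),
        mean_progressor=float(prog.mean()),
        p_value=p,
        direction=int(np.sign(diff)),
        n_responder=len(resp),
        n_progressor=len(prog),
    )


def relative_expression_matrix(
    cohort: list[PatientRecord],
    mirnas: list[str] | None = None,
    pseudo: float = 1.0,
):
    """Per-patient expression relative to the untreated arm mean (heatmap input).

    Returns a pandas DataFrame (patients × miRNAs) of
    ``(x + pseudo) / (untreated mean + pseudo)`` for irradiated patients.
    """
    import pandas as pd

    groups = _split_groups(cohort)
    if not groups["untreated"]:
        raise ValidationError("cohort is missing group(s): untreated")
    if mirnas is None:
        mirnas = list(cohort[0].expression)
    untreated_mean = {
        m: float(np.mean([p.expression[m] for p in groups["untreated"]])) for m in mirnas
    }
    rows = {}
    for g in ("responder", "progressor"):
        for p in groups[g]:
            rows[p.patient_id] = [
                (p.expression[m] + pseudo) / (untreated_mean[m] + pseudo) for m in mirnas
            ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=mirnas)
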