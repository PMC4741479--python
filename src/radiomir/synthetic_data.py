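"""Synthetic stand-ins for the two data sources the pipeline consumes.

``simulate_array`` emulates a two-cell-line irradiation experiment on a
spotted miRNA array: a wild-type and an ATM-deficient lymphoblastoid line,
each hybridized mock-treated and irradiated, genes in triplicate, with
housekeeping positive controls and bacterial-sequence negative controls.
Planted multiplicative IR effects (0 encodes IR-induced dropout) are the
ground truth the screen should recover.

``simulate_cohort`` emulates a three-arm patient cohort (responder /
progressor / untreated) with lognormal biological noise on expression,
planted group multipliers on chosen miRNAs, and a group-shifted Gaussian
ATM protein level on the RPPA scale.

Both simulators are deterministic under their seed and return first-class
truth tables so recovery tests never re-derive ground truth from configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import ArrayCondition, PatientRecord, ProbeSpot
from .errors import ValidationError

#: cell line -> genotype, mirroring the classic A-T proband/relative pair
CELL_LINES: dict[str, str] = {"GM0536": "ATM_wt", "GM1526": "ATM_null"}

IR_DOSE_GY = 6.0


@dataclass
class ArraySimConfig:
    seed: int = 0
    n_mirnas: int = 24
    n_positive_controls: int = 4
    n_negative_controls: int = 8
    baseline_log_mean: float = 6.5  # natural-log scale of true abundance (a.u.)
    baseline_log_sd: float = 1.0
    spot_cv: float = 0.05
    control_level: float = 2000.0
    background_level: float = 30.0
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    dropout_rate: float = 0.0

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ValidationError("n_mirnas must be ≥1")
        if self.n_positive_controls < 2:
            raise ValidationError("need ≥2 positive controls (U6/5S analogues)")
        if self.n_negative_controls < 0:
            raise ValidationError("n_negative_controls must be ≥0")
        if self.spot_cv < 0:
            raise ValidationError("spot_cv must be ≥0")
        if self.control_level <= 0 or self.background_level <= 0:
            raise ValidationError("control and background levels must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0,1)")
        for (genotype, mirna), eff in self.effects.items():
            if genotype not in set(CELL_LINES.values()):
                raise ValidationError(f"unknown genotype in effects: {genotype!r}")
            if eff < 0:
                raise ValidationError(f"effect for {mirna!r} must be ≥0")


@dataclass
class CohortSimConfig:
    seed: int = 0
    n_per_group: int = 10
    mirnas: list[str] = field(default_factory=list)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_cv: float = 0.3
    planted: dict[str, tuple[float, float]] = field(default_factory=dict)
    atm_baseline: float = 0.0
    atm_progressor_shift: float = 0.5
    atm_noise_sd: float = 0.2

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be ≥2")
        if not self.mirnas:
            raise ValidationError("mirnas list must be non-empty")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ValidationError("mirnas must be unique")
        if self.noise_cv < 0 or self.atm_noise_sd < 0:
            raise ValidationError("noise parameters must be ≥0")
        for m, (mr, mp) in self.planted.items():
            if m not in self.mirnas:
                raise ValidationError(f"planted miRNA {m!r} not in mirnas list")
            if mr <= 0 or mp <= 0:
                raise ValidationError(f"multipliers for {m!r} must be >0")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_array(config: ArraySimConfig) -> tuple[dict[str, ArrayCondition], pd.DataFrame]:
    """Generate the four array conditions (2 cell lines × mock/IR) plus truth.

    Spot intensity = true level × lognormal(1, spot_cv); the IR true level is
    the mock level times the planted effect; positive/negative controls sit
    at their configured levels with the same spot noise. The truth table has
    one row per (cell line, miRNA) with the effect and dropout flags.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mirnas = [f"hsa-mir-sim{i:03d}" for i in range(1, config.n_mirnas + 1)]
    positives = [f"U6-analog-{i}" for i in range(1, config.n_positive_controls + 1)]
    negatives = [f"gnd-analog-{i}" for i in range(1, config.n_negative_controls + 1)]
    # per-gene baseline shared across cell lines (same biology, same probes)
    baselines = dict(
        zip(mirnas, np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_mirnas)))
    )
    conditions: dict[str, ArrayCondition] = {}
    truth_rows = []
    for cell_line, genotype in CELL_LINES.items():
        dropped = {
            treatment: {m: bool(rng.random() < config.dropout_rate) for m in mirnas}
            for treatment in ("mock", "IR")
        }
        for m in mirnas:
            truth_rows.append(
                {
                    "cell_line": cell_line,
                    "genotype": genotype,
                    "mirna_id": m,
                    "effect": config.effects.get((genotype, m), 1.0),
                    "dropped_mock": dropped["mock"][m],
                    "dropped_ir": dropped["IR"][m],
                }
            )
        for treatment in ("mock", "IR"):
            spots: list[ProbeSpot] = []
            idx = 0
            levels: list[tuple[str, float, str]] = []
            for m in mirnas:
                level = baselines[m]
                if treatment == "IR":
                    level *= config.effects.get((genotype, m), 1.0)
                if dropped[treatment][m]:
                    level = 0.0
                levels.append((m, level, "probe"))
            levels += [(g, config.control_level, "positive_control") for g in positives]
            levels += [(g, config.background_level, "negative_control") for g in negatives]
            for gene, level, cls in levels:
                noise = _lognormal_noise(rng, config.spot_cv, 3)
                for rep in range(3):
                    block, row, col = 1, idx // 12 + 1, idx % 12 + 1
                    idx += 1
                    intensity = float(level * noise[rep])
                    spots.append(
                        ProbeSpot(
                            gene_id=gene,
                            block=block,
                            row=row,
                            col=col,
                            replicate_index=rep + 1,
                            signal_f635=intensity,
                            signal_f532=intensity,
                            control_class=cls,
                        )
                    )
            cond = ArrayCondition(
                cell_line=cell_line,
                genotype=genotype,
                treatment=treatment,
                dose=0.0 if treatment == "mock" else IR_DOSE_GY,
                spots=spots,
            )
            conditions[cond.condition_id] = cond
    truth = pd.DataFrame(truth_rows)
    return conditions, truth


def simulate_cohort(config: CohortSimConfig) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a three-arm cohort with planted group effects plus truth.

    Untreated expression is the lognormal per-miRNA baseline times patient
    noise; responder/progressor expression additionally carries the planted
    group multiplier. ATM protein is Gaussian on the RPPA scale, shifted by
    ``atm_progressor_shift`` in progressors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    baselines = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(config.mirnas))
    mult = {
        "untreated": np.ones(len(config.mirnas)),
        "responder": np.array([config.planted.get(m, (1.0, 1.0))[0] for m in config.mirnas]),
        "progressor": np.array([config.planted.get(m, (1.0, 1.0))[1] for m in config.mirnas]),
    }
    prefixes = {"responder": "RESP", "progressor": "PROG", "untreated": "UNTR"}
    patients: list[PatientRecord] = []
    for group in ("responder", "progressor", "untreated"):
        noise = _lognormal_noise(rng, config.noise_cv, (n, len(config.mirnas)))
        expr = baselines[None, :] * mult[group][None, :] * noise
        atm_mean = config.atm_baseline + (config.atm_progressor_shift if group == "progressor" else 0.0)
        atm = rng.normal(atm_mean, config.atm_noise_sd, n)
        for i in range(n):
            patients.append(
                PatientRecord(
                    patient_id=f"{prefixes[group]}-{i + 1:02d}",
                    group=group,
                    expression={m: float(expr[i, j]) for j, m in enumerate(config.mirnas)},
                    atm_protein=float(atm[i]),
                )
            )
    truth = pd.DataFrame(
        {
            "mirna_id": config.mirnas,
            "responder_multiplier": mult["responder"],
            "progressor_multiplier": mult["progressor"],
            "baseline": baselines,
        }
    )
    return patients, truth


def paper_pattern_config(
    seed: int = 0,
    n_per_group: int = 10,
    noise_cv: float = 0.3,
    effect: float = 2.0,
) -> CohortSimConfig:
    """Cohort config planting the five-miRNA signature pattern.

    Signature miRNAs get a two-fold effect in the direction of the packaged
    direction table in responders and the inverse in progressors; all other
    screen miRNAs are null.
    """
    from .array_io import load_direction_table, load_table1

    directions = load_direction_table()
    mirnas = [r.mirna_id for r in load_table1()]
    planted: dict[str, tuple[float, float]] = {}
    for m, d in directions.items():
        if d == "up":
            planted[m] = (effect, 1.0 / effect)
        else:
            planted[m] = (1.0 / effect, effect)
    return CohortSimConfig(seed=seed, n_per_group=n_per_group, mirnas=mirnas, noise_cv=noise_cv, planted=planted)
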