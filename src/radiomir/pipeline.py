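"""End-to-end orchestration of the screen and signature stages.

``run_screen`` composes normalization → threshold analysis → hit calling on
a directory of four array tables (two cell lines × mock/IR) and writes a
screen table in the published five-column layout, a threshold report, and a
hit-call table. ``run_signature`` replays the cohort concordance screen on
any cohort TSV against a screen table and a direction reference.

All outputs are written to a temporary directory and renamed into place, so
a failed run leaves no partial state. Every default that fills a parameter
the published procedure leaves open is logged at INFO.
"""

from __future__ import annotations

import csv
import logging
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import array_io, cohort_signature, hit_calling, normalization, threshold_model
from .array_io import ArrayCondition
from .errors import RadiomirError, ValidationError

logger = logging.getLogger("radiomir")

GENOTYPE_BY_CELL_LINE_FILE = "{cell_line}__{genotype}__{treatment}__{dose}.tsv"


@dataclass
class PipelineConfig:
    """Effective configuration; every field has a documented default."""

    channel: str = "F635"
    detection_floor: float = 0.0
    sd_multiplier: float = 2.0
    reference: str = "direction_table"  # or ATM_wt / ATM_null / path to a TSV
    alpha: float = 0.05
    epsilon: float = 0.25
    pseudo: float = 1.0
    rounding: str = "ceil"
    seed: int = 0
    allow_partial: bool = False

    def log_effective(self) -> None:
        for key, value in asdict(self).items():
            logger.info("config %s = %r", key, value)


def array_filename(condition: ArrayCondition) -> str:
    return GENOTYPE_BY_CELL_LINE_FILE.format(
        cell_line=condition.cell_line,
        genotype=condition.genotype,
        treatment=condition.treatment,
        dose=condition.dose,
    )


def _parse_array_filename(path: Path) -> dict:
    parts = path.stem.split("__")
    if len(parts) != 4:
        raise ValidationError(
            f"array filename {path.name!r} does not match "
            "'<cell_line>__<genotype>__<treatment>__<dose>.tsv'"
        )
    return {
        "cell_line": parts[0],
        "genotype": parts[1],
        "treatment": parts[2],
        "dose": float(parts[3]),
    }


def load_array_dir(array_dir: str | Path) -> dict[str, ArrayCondition]:
    """Read every array table in a directory; require mock+IR per cell line."""
    array_dir = Path(array_dir)
    files = sorted(array_dir.glob("*__*__*__*.tsv"))
    conditions: dict[str, ArrayCondition] = {}
    for f in files:
        meta = _parse_array_filename(f)
        cond = array_io.read_array_table(f, **meta)
        conditions[cond.condition_id] = cond
    cell_lines = {c.cell_line for c in conditions.values()}
    missing = [
        f"{cl}_{tr}" for cl in sorted(cell_lines) for tr in ("mock", "IR")
        if f"{cl}_{tr}" not in conditions
    ]
    if not conditions or missing:
        raise ValidationError(
            "array directory incomplete; expected mock and IR per cell line, "
            f"missing: {', '.join(missing) or 'all files'}"
        )
    return conditions


def _atomic_outputs(out_dir: Path):
    """Context: stage files in a temp dir, rename into out_dir on success."""

    class _Stager:
        def __enter__(self):
            self.tmp = Path(tempfile.mkdtemp(prefix=".radiomir-", dir=out_dir.parent))
            return self.tmp

        def __exit__(self, exc_type, exc, tb):
            if exc_type is None:
                out_dir.mkdir(parents=True, exist_ok=True)
                for f in sorted(self.tmp.iterdir()):
                    f.replace(out_dir / f.name)
            shutil.rmtree(self.tmp, ignore_errors=True)
            return False

    out_dir.parent.mkdir(parents=True, exist_ok=True)
    return _Stager()


def run_screen(array_dir: str | Path, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Normalize, screen, threshold, and call hits for one array experiment.

    Writes ``screen.tsv`` (five-column screen layout), ``thresholds.tsv``
    (one row per condition), ``hits_<genotype>.tsv`` per genotype, and
    ``summary.tsv``. Returns the in-memory results keyed by output name.
    """
    out_dir = Path(out_dir)
    config.log_effective()
    conditions = load_array_dir(array_dir)
    by_cell_line: dict[str, dict[str, ArrayCondition]] = {}
    for cond in conditions.values():
        by_cell_line.setdefault(cond.cell_line, {})[cond.treatment] = cond

    fold_maps: dict[str, dict[str, normalization.FoldChange]] = {}
    genotype_of: dict[str, str] = {}
    signals_by_condition: dict[str, list[normalization.GeneSignal]] = {}
    for cell_line, arms in by_cell_line.items():
        genotype_of[cell_line] = arms["IR"].genotype
        norm = {}
        for treatment, cond in arms.items():
            signals = normalization.aggregate_replicates(
                cond, channel=config.channel, detection_floor=config.detection_floor
            )
            qc = normalization.qc_negative_controls(signals)
            if qc.warning:
                logger.warning("%s: %s", cond.condition_id, qc.warning)
            signals_by_condition[cond.condition_id] = signals
            norm[treatment] = normalization.normalize(signals, condition_ref=cond.condition_id)
        probes_ir = [e for e in norm["IR"] if _is_probe(e.gene_id, signals_by_condition[arms["IR"].condition_id])]
        probes_mock = [e for e in norm["mock"] if _is_probe(e.gene_id, signals_by_condition[arms["mock"].condition_id])]
        fold_maps[cell_line] = normalization.fold_change(probes_ir, probes_mock)

    genotypes = set(genotype_of.values())
    if genotypes != {"ATM_wt", "ATM_null"}:
        raise ValidationError(f"expected one ATM_wt and one ATM_null cell line, got {sorted(genotypes)}")
    wt_line = next(cl for cl, g in genotype_of.items() if g == "ATM_wt")
    null_line = next(cl for cl, g in genotype_of.items() if g == "ATM_null")
    genes = sorted(fold_maps[wt_line])
    if set(genes) != set(fold_maps[null_line]):
        raise ValidationError("cell lines carry different probe gene sets")
    records = [
        array_io.FoldChangeRecord(
            mirna_id=g,
            fc_wt=fold_maps[wt_line][g].fc,
            sd_wt=fold_maps[wt_line][g].sd,
            fc_null=fold_maps[null_line][g].fc,
            sd_null=fold_maps[null_line][g].sd,
        )
        for g in genes
    ]

    intervals = []
    for cond in conditions.values():
        fc_map = {g: fold_maps[cond.cell_line][g].fc for g in fold_maps[cond.cell_line]}
        probe_signals = [s for s in signals_by_condition[cond.condition_id] if s.control_class == "probe"]
        outcomes = threshold_model.classify_outcomes(fc_map, probe_signals)
        try:
            intervals.append(threshold_model.estimate_threshold(outcomes, cond.condition_id))
        except ValidationError as exc:
            logger.info("%s: %s", cond.condition_id, exc)

    hits = {}
    summaries = {}
    for genotype in ("ATM_wt", "ATM_null"):
        hits[genotype], summaries[genotype] = hit_calling.screen_hits(
            records, genotype=genotype, sd_multiplier=config.sd_multiplier
        )

    with _atomic_outputs(out_dir) as tmp:
        array_io.write_screen_table(records, tmp / "screen.tsv")
        with (tmp / "thresholds.tsv").open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["condition_id", "lower", "upper", "separated"])
            for iv in intervals:
                w.writerow([iv.condition_id, repr(iv.lower), repr(iv.upper), iv.separated])
        for genotype in ("ATM_wt", "ATM_null"):
            (tmp / f"hits_{genotype}.tsv").write_text(
                hit_calling.format_hit_table(hits[genotype], summaries[genotype]), encoding="utf-8"
            )
    return {"screen": records, "thresholds": intervals, "hits": hits, "summaries": summaries}


def _is_probe(gene_id: str, signals: list[normalization.GeneSignal]) -> bool:
    for s in signals:
        if s.gene_id == gene_id:
            return s.control_class == "probe"
    return False


def resolve_reference(config: PipelineConfig) -> str | dict[str, str]:
    """Map the config's reference field to what concordance_screen accepts."""
    if config.reference == "direction_table":
        return array_io.load_direction_table()
    if config.reference in ("ATM_wt", "ATM_null"):
        return config.reference
    path = Path(config.reference)
    if path.exists():
        out = {}
        with path.open(encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                out[row["mirna_id"]] = row["direction"]
        return out
    raise ValidationError(f"unknown reference {config.reference!r}")


def run_signature(
    screen_path: str | Path,
    cohort_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Cohort concordance screen plus the ATM group comparison.

    Writes ``signature.tsv`` (all entries; ``concordant`` marks members),
    ``ratios.tsv``, ``atm_comparison.tsv`` (when RPPA data are present), and
    the relative-expression matrix ``relative_expression.tsv``.
    """
    out_dir = Path(out_dir)
    config.log_effective()
    screen = array_io.read_screen_table(screen_path)
    cohort = array_io.read_cohort_table(cohort_path)
    screen_ids = {r.mirna_id for r in screen}
    cohort_ids = set(cohort[0].expression)
    extra = sorted(cohort_ids - screen_ids)
    if extra and not config.allow_partial:
        raise ValidationError(
            f"cohort miRNAs absent from screen table: {', '.join(extra)} "
            "(pass allow_partial to ignore them)"
        )
    ratios = cohort_signature.group_ratios(cohort, pseudo=config.pseudo)
    entries = cohort_signature.concordance_screen(
        ratios,
        screen,
        reference=resolve_reference(config),
        epsilon=config.epsilon,
        alpha=config.alpha,
        sd_multiplier=config.sd_multiplier,
    )
    atm = None
    if any(p.atm_protein is not None for p in cohort):
        try:
            atm = cohort_signature.atm_group_comparison(cohort)
        except RadiomirError as exc:
            logger.warning("ATM comparison skipped: %s", exc)
    matrix = cohort_signature.relative_expression_matrix(cohort, pseudo=config.pseudo)

    with _atomic_outputs(out_dir) as tmp:
        with (tmp / "signature.tsv").open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["mirna_id", "direction_responder", "direction_progressor",
                 "invitro_direction", "concordant", "p_value"]
            )
            for e in entries:
                w.writerow(
                    [e.mirna_id, e.direction_responder, e.direction_progressor,
                     e.invitro_direction, e.concordant, repr(e.p_value)]
                )
        with (tmp / "ratios.tsv").open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["mirna_id", "ratio_responder", "ratio_progressor", "p_value",
                 "n_responder", "n_progressor", "n_untreated"]
            )
            for r in ratios:
                w.writerow(
                    [r.mirna_id, repr(r.ratio_responder), repr(r.ratio_progressor),
                     repr(r.p_value), r.n_responder, r.n_progressor, r.n_untreated]
                )
        if atm is not None:
            with (tmp / "atm_comparison.tsv").open("w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["mean_responder", "mean_progressor", "p_value", "direction",
                            "n_responder", "n_progressor"])
                w.writerow([repr(atm.mean_responder), repr(atm.mean_progressor),
                            repr(atm.p_value), atm.direction, atm.n_responder, atm.n_progressor])
        matrix.to_csv(tmp / "relative_expression.tsv", sep="\t", index_label="patient_id")
    return {"entries": entries, "ratios": ratios, "atm": atm, "matrix": matrix}
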