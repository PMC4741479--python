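"""Tabular I/O for every format the pipeline touches.

Three TSV dialects, all UTF-8 with a mandatory header row:

* **array table** — probe-level fluorescence, GenePix-results style: one row
  per spot with grid position (block, row, col), the two channel intensities
  (F635, F532) and a control-class annotation. Genes are spotted in
  triplicate.
* **screen table** — one row per miRNA with fold change ± SD for each
  genotype (the exchange format of the in vitro screen).
* **cohort table** — one row per patient: id, response group, one expression
  column per miRNA, and an optional ``atm_protein`` RPPA column.

Readers validate eagerly and raise :class:`~radiomir.errors.FormatError` for
dialect problems and :class:`~radiomir.errors.ValidationError` for domain
violations; writers emit files the readers round-trip bit-identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, ValidationError

CONTROL_CLASSES = ("probe", "positive_control", "negative_control")
GENOTYPES = ("ATM_wt", "ATM_null")
TREATMENTS = ("mock", "IR")
GROUPS = ("responder", "progressor", "untreated")

_ARRAY_COLUMNS = ("gene_id", "block", "row", "col", "F635", "F532", "control_class")
_SCREEN_COLUMNS = ("mirna_id", "fc_wt", "sd_wt", "fc_null", "sd_null")


@dataclass(frozen=True)
class ProbeSpot:
    """One printed spot on the array."""

    gene_id: str
    block: int
    row: int
    col: int
    replicate_index: int
    signal_f635: float
    signal_f532: float
    control_class: str = "probe"

    def __post_init__(self) -> None:
        if self.control_class not in CONTROL_CLASSES:
            raise ValidationError(
                f"unknown control_class {self.control_class!r}; "
                f"allowed: {', '.join(CONTROL_CLASSES)}"
            )
        if self.signal_f635 < 0 or self.signal_f532 < 0:
            raise ValidationError(
                f"negative intensity for gene {self.gene_id!r}: "
                f"F635={self.signal_f635}, F532={self.signal_f532}"
            )
        if min(self.block, self.row, self.col) < 1:
            raise ValidationError("block/row/col must be positive")


@dataclass
class ArrayCondition:
    """One hybridized array: a cell line under one treatment arm."""

    cell_line: str
    genotype: str
    treatment: str
    dose: float
    spots: list[ProbeSpot] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"genotype must be one of {GENOTYPES}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"treatment must be one of {TREATMENTS}")
        if self.treatment == "mock" and self.dose != 0:
            raise ValidationError("mock treatment implies dose 0")

    @property
    def condition_id(self) -> str:
        return f"{self.cell_line}_{self.treatment}"


@dataclass(frozen=True)
class FoldChangeRecord:
    """One screen-table row: fold change ± SD per genotype."""

    mirna_id: str
    fc_wt: float
    sd_wt: float
    fc_null: float
    sd_null: float

    def __post_init__(self) -> None:
        for name in ("fc_wt", "sd_wt", "fc_null", "sd_null"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative for {self.mirna_id!r}")

    def fc_sd(self, genotype: str) -> tuple[float, float]:
        """Return (fc, sd) for one genotype."""
        if genotype == "ATM_wt":
            return self.fc_wt, self.sd_wt
        if genotype == "ATM_null":
            return self.fc_null, self.sd_null
        raise ValidationError(f"genotype must be one of {GENOTYPES}")


@dataclass
class PatientRecord:
    """One cohort member: response group, expression vector, optional ATM RPPA."""

    patient_id: str
    group: str
    expression: dict[str, float]
    atm_protein: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"group {self.group!r} for patient {self.patient_id!r} not allowed; "
                f"allowed: {', '.join(GROUPS)}"
            )


# ---------------------------------------------------------------------------
# array tables


def read_array_table(
    path: str | Path,
    *,
    cell_line: str,
    genotype: str,
    treatment: str,
    dose: float,
) -> ArrayCondition:
    """Read a probe-level array table into an :class:`ArrayCondition`.

    ``replicate_index`` is assigned by order of appearance per gene; a
    duplicate (block, row, col) position is rejected.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _ARRAY_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        spots: list[ProbeSpot] = []
        seen_pos: set[tuple[int, int, int]] = set()
        rep_count: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                block, r, c = int(row["block"]), int(row["row"]), int(row["col"])
                f635, f532 = float(row["F635"]), float(row["F532"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if f635 < 0 or f532 < 0:
                raise ValidationError(f"{path}:{lineno}: negative intensity")
            pos = (block, r, c)
            if pos in seen_pos:
                raise ValidationError(f"{path}:{lineno}: duplicate spot position {pos}")
            seen_pos.add(pos)
            gene = row["gene_id"]
            rep_count[gene] = rep_count.get(gene, 0) + 1
            spots.append(
                ProbeSpot(
                    gene_id=gene,
                    block=block,
                    row=r,
                    col=c,
                    replicate_index=rep_count[gene],
                    signal_f635=f635,
                    signal_f532=f532,
                    control_class=row["control_class"],
                )
            )
    return ArrayCondition(cell_line=cell_line, genotype=genotype, treatment=treatment, dose=dose, spots=spots)


def write_array_table(condition: ArrayCondition, path: str | Path) -> None:
    """Write the probe-level table; metadata lives in the filename/caller."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ARRAY_COLUMNS)
        for s in condition.spots:
            writer.writerow(
                [s.gene_id, s.block, s.row, s.col, repr(s.signal_f635), repr(s.signal_f532), s.control_class]
            )


# ---------------------------------------------------------------------------
# screen tables


def read_screen_table(path: str | Path) -> list[FoldChangeRecord]:
    """Read a five-column screen table; order preserved, ids unique."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _SCREEN_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        records: list[FoldChangeRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            mirna = row["mirna_id"]
            if mirna in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate miRNA id {mirna!r}")
            seen.add(mirna)
            try:
                rec = FoldChangeRecord(
                    mirna_id=mirna,
                    fc_wt=float(row["fc_wt"]),
                    sd_wt=float(row["sd_wt"]),
                    fc_null=float(row["fc_null"]),
                    sd_null=float(row["sd_null"]),
                )
            except (TypeError, ValueError):
                raise FormatError(f"{path}:{lineno}: non-numeric cell in row for {mirna!r}") from None
            records.append(rec)
    return records


def write_screen_table(records: Iterable[FoldChangeRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SCREEN_COLUMNS)
        for r in records:
            writer.writerow([r.mirna_id, repr(r.fc_wt), repr(r.sd_wt), repr(r.fc_null), repr(r.sd_null)])


# ---------------------------------------------------------------------------
# cohort tables

_COHORT_FIXED = ("patient_id", "group")


def read_cohort_table(path: str | Path, *, strict: bool = True) -> list[PatientRecord]:
    """Read a wide cohort table (one expression column per miRNA).

    With ``strict`` (default), an empty expression cell is an error; otherwise
    it is recorded as NaN.
    """
    import math

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _COHORT_FIXED if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        has_atm = "atm_protein" in header
        mirna_cols = [c for c in header if c not in _COHORT_FIXED and c != "atm_protein"]
        if not mirna_cols:
            raise FormatError(f"{path}: no miRNA expression columns found")
        patients: list[PatientRecord] = []
        for lineno, row in enumerate(reader, start=2):
            expr: dict[str, float] = {}
            for m in mirna_cols:
                cell = row[m]
                if cell is None or cell == "":
                    if strict:
                        raise ValidationError(
                            f"{path}:{lineno}: missing expression for {m!r} (strict mode)"
                        )
                    expr[m] = math.nan
                    continue
                try:
                    val = float(cell)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric expression cell {m!r}={cell!r}") from None
                if val < 0:
                    raise ValidationError(f"{path}:{lineno}: negative expression for {m!r}")
                expr[m] = val
            atm: float | None = None
            if has_atm and row["atm_protein"] not in (None, ""):
                try:
                    atm = float(row["atm_protein"])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric atm_protein cell") from None
            patients.append(
                PatientRecord(patient_id=row["patient_id"], group=row["group"], expression=expr, atm_protein=atm)
            )
    return patients


def write_cohort_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    patients = list(patients)
    if not patients:
        raise ValidationError("cannot write an empty cohort table")
    mirnas = list(patients[0].expression)
    for p in patients:
        if list(p.expression) != mirnas:
            raise ValidationError(
                f"patient {p.patient_id!r} has a different miRNA column set"
            )
    has_atm = any(p.atm_protein is not None for p in patients)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = list(_COHORT_FIXED) + mirnas + (["atm_protein"] if has_atm else [])
        writer.writerow(header)
        for p in patients:
            row = [p.patient_id, p.group] + [repr(p.expression[m]) for m in mirnas]
            if has_atm:
                row.append("" if p.atm_protein is None else repr(p.atm_protein))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return resources.files("radiomir.data").joinpath(name)


def load_table1() -> list[FoldChangeRecord]:
    """The packaged transcription of the published in vitro screen (28 rows)."""
    with resources.as_file(_data_path("table1_screen.tsv")) as p:
        return read_screen_table(p)


def load_direction_table() -> dict[str, str]:
    """The packaged five-member signature direction table (miRNA id -> up/down)."""
    with resources.as_file(_data_path("signature_directions.tsv")) as p:
        out: dict[str, str] = {}
        with open(p, encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                if row["direction"] not in ("up", "down"):
                    raise ValidationError(f"bad direction {row['direction']!r}")
                out[row["mirna_id"]] = row["direction"]
        return out
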