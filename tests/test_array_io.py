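"""Readers/writers for the three TSV dialects: validation and round-trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from radiomir import (
    ArrayCondition,
    FoldChangeRecord,
    FormatError,
    PatientRecord,
    ProbeSpot,
    ValidationError,
    read_array_table,
    read_cohort_table,
    read_screen_table,
    write_array_table,
    write_cohort_table,
    write_screen_table,
)

ARRAY_HEADER = "gene_id\tblock\trow\tcol\tF635\tF532\tcontrol_class\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestArrayTable:
    def test_minimal_triplicate_file(self, tmp_path):
        body = "".join(
            f"mir-a\t1\t1\t{i}\t{100 + 10 * (i - 1)}\t50\tprobe\n" for i in (1, 2, 3)
        )
        p = _write(tmp_path, "a.tsv", ARRAY_HEADER + body)
        cond = read_array_table(p, cell_line="GM0536", genotype="ATM_wt", treatment="mock", dose=0)
        assert len(cond.spots) == 3
        assert [s.replicate_index for s in cond.spots] == [1, 2, 3]
        assert [s.signal_f635 for s in cond.spots] == [100, 110, 120]

    def test_negative_intensity_reports_line(self, tmp_path):
        p = _write(tmp_path, "a.tsv", ARRAY_HEADER + "mir-a\t1\t1\t1\t-5\t50\tprobe\n")
        with pytest.raises(ValidationError, match=":2"):
            read_array_table(p, cell_line="x", genotype="ATM_wt", treatment="mock", dose=0)

    def test_missing_column_named(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "gene_id\tblock\trow\tcol\tF635\tcontrol_class\nx\t1\t1\t1\t1\tprobe\n")
        with pytest.raises(FormatError, match="F532"):
            read_array_table(p, cell_line="x", genotype="ATM_wt", treatment="mock", dose=0)

    def test_unknown_control_class_rejected(self, tmp_path):
        p = _write(tmp_path, "a.tsv", ARRAY_HEADER + "mir-a\t1\t1\t1\t5\t5\tblank\n")
        with pytest.raises(ValidationError, match="control_class"):
            read_array_table(p, cell_line="x", genotype="ATM_wt", treatment="mock", dose=0)

    def test_duplicate_position_rejected(self, tmp_path):
        body = "mir-a\t1\t1\t1\t5\t5\tprobe\nmir-b\t1\t1\t1\t5\t5\tprobe\n"
        p = _write(tmp_path, "a.tsv", ARRAY_HEADER + body)
        with pytest.raises(ValidationError, match="duplicate"):
            read_array_table(p, cell_line="x", genotype="ATM_wt", treatment="mock", dose=0)

    @given(
        genes=st.lists(
            st.tuples(
                st.integers(0, 10_000),
                st.lists(st.floats(0, 1e6, allow_nan=False, allow_infinity=False), min_size=3, max_size=3),
                st.sampled_from(["probe", "positive_control", "negative_control"]),
            ),
            min_size=1,
            max_size=12,
            unique_by=lambda g: g[0],
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_round_trip_is_identity(self, genes, tmp_path_factory):
        spots = []
        idx = 0
        for gid, intensities, cls in genes:
            for rep, val in enumerate(intensities, start=1):
                spots.append(
                    ProbeSpot(
                        gene_id=f"g{gid}",
                        block=1,
                        row=idx // 12 + 1,
                        col=idx % 12 + 1,
                        replicate_index=rep,
                        signal_f635=val,
                        signal_f532=val / 2,
                        control_class=cls,
                    )
                )
                idx += 1
        cond = ArrayCondition(cell_line="GM0536", genotype="ATM_wt", treatment="IR", dose=6, spots=spots)
        p = tmp_path_factory.mktemp("rt") / "a.tsv"
        write_array_table(cond, p)
        back = read_array_table(p, cell_line="GM0536", genotype="ATM_wt", treatment="IR", dose=6)
        assert back.spots == cond.spots


class TestScreenTable:
    def test_fixture_parses_to_28_records(self, table1):
        assert len(table1) == 28

    def test_fixture_mir016_values(self, table1_by_id):
        r = table1_by_id["hsa-mir-016"]
        assert (r.fc_wt, r.sd_wt, r.fc_null, r.sd_null) == (0.88144, 0.1411, 2.24896, 0.1462)

    def test_header_only_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "mirna_id\tfc_wt\tsd_wt\tfc_null\tsd_null\n")
        assert read_screen_table(p) == []

    def test_duplicate_id_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "s.tsv",
            "mirna_id\tfc_wt\tsd_wt\tfc_null\tsd_null\nm\t1\t0\t1\t0\nm\t2\t0\t2\t0\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_screen_table(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "mirna_id\tfc_wt\tsd_wt\tfc_null\tsd_null\nm\tx\t0\t1\t0\n")
        with pytest.raises(FormatError, match=":2"):
            read_screen_table(p)

    @given(
        rows=st.lists(
            st.tuples(
                st.integers(0, 10_000),
                st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=4),
            ),
            min_size=0,
            max_size=20,
            unique_by=lambda r: r[0],
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_round_trip_is_identity(self, rows, tmp_path_factory):
        records = [FoldChangeRecord(f"m{gid}", *vals) for gid, vals in rows]
        p = tmp_path_factory.mktemp("rt") / "s.tsv"
        write_screen_table(records, p)
        assert read_screen_table(p) == records


class TestCohortTable:
    HEADER = "patient_id\tgroup\tmir-a\tmir-b\n"

    def test_three_patient_file(self, tmp_path):
        body = "p1\tresponder\t1\t2\np2\tprogressor\t3\t4\np3\tuntreated\t5\t6\n"
        patients = read_cohort_table(_write(tmp_path, "c.tsv", self.HEADER + body))
        assert [p.group for p in patients] == ["responder", "progressor", "untreated"]
        assert patients[0].expression == {"mir-a": 1.0, "mir-b": 2.0}
        assert patients[0].atm_protein is None

    def test_bad_group_label_lists_allowed(self, tmp_path):
        p = _write(tmp_path, "c.tsv", self.HEADER + "p1\tradiated\t1\t2\n")
        with pytest.raises(ValidationError, match="responder, progressor, untreated"):
            read_cohort_table(p)

    def test_missing_cell_strict_vs_permissive(self, tmp_path):
        p = _write(tmp_path, "c.tsv", self.HEADER + "p1\tresponder\t\t2\n")
        with pytest.raises(ValidationError, match="missing expression"):
            read_cohort_table(p)
        patients = read_cohort_table(p, strict=False)
        assert math.isnan(patients[0].expression["mir-a"])

    def test_round_trip_with_atm(self, tmp_path):
        patients = [
            PatientRecord("p1", "responder", {"mir-a": 1.5, "mir-b": 0.25}, atm_protein=0.1),
            PatientRecord("p2", "untreated", {"mir-a": 3.0, "mir-b": 7.125}, atm_protein=None),
        ]
        p = tmp_path / "c.tsv"
        write_cohort_table(patients, p)
        assert read_cohort_table(p) == patients

    def test_inconsistent_columns_rejected_on_write(self, tmp_path):
        patients = [
            PatientRecord("p1", "responder", {"mir-a": 1.0}),
            PatientRecord("p2", "untreated", {"mir-b": 1.0}),
        ]
        with pytest.raises(ValidationError, match="column set"):
            write_cohort_table(patients, tmp_path / "c.tsv")
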