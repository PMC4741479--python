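"""Group ratios, the directional concordance screen, and the ATM comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from radiomir import (
    FoldChangeRecord,
    GroupRatio,
    PatientRecord,
    ValidationError,
    atm_group_comparison,
    concordance_screen,
    group_ratios,
    relative_expression_matrix,
    signature_members,
)


def _cohort(resp, prog, untr, mirna="m", atm=None):
    patients = []
    for group, values in (("responder", resp), ("progressor", prog), ("untreated", untr)):
        for i, v in enumerate(values):
            patients.append(
                PatientRecord(
                    f"{group[:4]}{i}",
                    group,
                    {mirna: float(v)} if not isinstance(v, dict) else v,
                    atm_protein=None if atm is None else atm[group][i],
                )
            )
    return patients


def welch_p_closed_form(a, b):
    """Independent oracle: Welch statistic + Welch–Satterthwaite df by hand."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df, 2 * stats.t.sf(abs(t), df)


class TestGroupRatios:
    def test_direct_ratio_without_pseudocount(self):
        cohort = _cohort([20, 20], [5, 5], [10, 10])
        [r] = group_ratios(cohort, pseudo=0)
        assert r.ratio_responder == pytest.approx(2.0)
        assert r.ratio_progressor == pytest.approx(0.5)

    def test_identical_groups_are_null(self):
        cohort = _cohort([3, 4, 5], [3, 4, 5], [3, 4, 5])
        [r] = group_ratios(cohort, pseudo=0)
        assert r.ratio_responder == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_welch_example_matches_closed_form(self):
        cohort = _cohort([1, 2, 3], [2, 3, 4], [1, 1])
        [r] = group_ratios(cohort, log_transform=False)
        t, df, p = welch_p_closed_form([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871, abs=1e-8)
        assert df == pytest.approx(4.0)
        assert r.p_value == pytest.approx(p, abs=1e-12)
        assert r.p_value == pytest.approx(0.2878641347, abs=1e-9)

    def test_missing_group_named(self):
        cohort = [PatientRecord("p", "responder", {"m": 1.0}), PatientRecord("q", "responder", {"m": 2.0})]
        with pytest.raises(ValidationError, match="progressor"):
            group_ratios(cohort)

    def test_label_flip_inverts_ratio_pairs(self):
        rng = np.random.default_rng(7)
        vals = {g: rng.lognormal(3, 0.4, 5) for g in ("responder", "progressor", "untreated")}
        cohort = _cohort(vals["responder"], vals["progressor"], vals["untreated"])
        swap = {"responder": "progressor", "progressor": "responder", "untreated": "untreated"}
        flipped = [
            PatientRecord(p.patient_id, swap[p.group], p.expression, p.atm_protein) for p in cohort
        ]
        [a], [b] = group_ratios(cohort), group_ratios(flipped)
        assert b.ratio_responder == pytest.approx(a.ratio_progressor)
        assert b.ratio_progressor == pytest.approx(a.ratio_responder)
        assert b.p_value == pytest.approx(a.p_value)

    def test_pseudocount_continuity_on_positive_data(self):
        cohort = _cohort([20, 22], [5, 6], [10, 11])
        [plain] = group_ratios(cohort, pseudo=0)
        for pseudo in (1e-3, 1e-6, 1e-9):
            [r] = group_ratios(cohort, pseudo=pseudo)
            assert r.ratio_responder == pytest.approx(plain.ratio_responder, rel=pseudo)


class TestConcordanceScreen:
    SCREEN = [FoldChangeRecord("m", 1.0, 0.1, 2.0, 0.1)]

    def _ratio(self, rr, rp, p):
        return GroupRatio("m", rr, rp, p, 3, 3, 3)

    def test_all_clauses_satisfied(self):
        entries = concordance_screen([self._ratio(2.0, 0.5, 0.01)], self.SCREEN, reference={"m": "up"})
        assert entries[0].concordant and signature_members(entries) == ["m"]

    def test_same_direction_pair_is_discordant(self):
        entries = concordance_screen([self._ratio(2.0, 1.6, 0.01)], self.SCREEN, reference={"m": "up"})
        assert not entries[0].concordant

    def test_flat_responder_is_discordant(self):
        entries = concordance_screen([self._ratio(1.02, 0.5, 0.01)], self.SCREEN, reference={"m": "up"})
        assert entries[0].direction_responder == "flat" and not entries[0].concordant

    def test_reference_direction_must_match(self):
        entries = concordance_screen([self._ratio(2.0, 0.5, 0.01)], self.SCREEN, reference={"m": "down"})
        assert not entries[0].concordant

    def test_insignificant_p_is_discordant(self):
        entries = concordance_screen([self._ratio(2.0, 0.5, 0.2)], self.SCREEN, reference={"m": "up"})
        assert not entries[0].concordant

    def test_genotype_reference_uses_hit_rule(self):
        # ATM_null fc 2.0 ± 0.1 → in vitro "up"
        entries = concordance_screen([self._ratio(2.0, 0.5, 0.01)], self.SCREEN, reference="ATM_null")
        assert entries[0].invitro_direction == "up" and entries[0].concordant
        # ATM_wt fc 1.0 → "unchanged": never concordant
        entries = concordance_screen([self._ratio(2.0, 0.5, 0.01)], self.SCREEN, reference="ATM_wt")
        assert entries[0].invitro_direction == "unchanged" and not entries[0].concordant

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            concordance_screen([self._ratio(2.0, 0.5, 0.01)], self.SCREEN, reference="ATM_het")

    def test_mirna_missing_from_screen_warned_and_skipped(self):
        ratios = [self._ratio(2.0, 0.5, 0.01), GroupRatio("other", 2.0, 0.5, 0.01, 3, 3, 3)]
        with pytest.warns(UserWarning, match="other"):
            entries = concordance_screen(ratios, self.SCREEN, reference={"m": "up"})
        assert [e.mirna_id for e in entries] == ["m"]

    def test_label_flip_maps_up_reference_onto_down_reference(self):
        up_entry = concordance_screen([self._ratio(2.4, 0.4, 0.01)], self.SCREEN, reference={"m": "up"})[0]
        flipped = concordance_screen([self._ratio(0.4, 2.4, 0.01)], self.SCREEN, reference={"m": "down"})[0]
        assert up_entry.concordant and flipped.concordant


class TestAtmComparison:
    def test_separated_groups_direction_negative(self):
        atm = {"responder": [1.0, 1.01, 0.99], "progressor": [2.0, 2.01, 1.99], "untreated": [0, 0, 0]}
        cohort = _cohort([1] * 3, [1] * 3, [1] * 3, atm=atm)
        cmp = atm_group_comparison(cohort)
        assert cmp.direction == -1 and cmp.p_value < 1e-6

    def test_identical_groups_null(self):
        atm = {"responder": [1.0, 2.0], "progressor": [1.0, 2.0], "untreated": [0, 0]}
        cohort = _cohort([1] * 2, [1] * 2, [1] * 2, atm=atm)
        cmp = atm_group_comparison(cohort)
        assert cmp.direction == 0 and cmp.p_value == pytest.approx(1.0)

    def test_insufficient_rppa_rejected(self):
        atm = {"responder": [1.0, None], "progressor": [2.0, 2.1], "untreated": [None, None]}
        cohort = _cohort([1] * 2, [1] * 2, [1] * 2, atm=atm)
        with pytest.raises(ValidationError, match="RPPA"):
            atm_group_comparison(cohort)

    def test_planted_shift_detected_in_most_seeds(self):
        from radiomir import CohortSimConfig, simulate_cohort

        hits = 0
        for seed in range(100):
            cfg = CohortSimConfig(
                seed=seed, n_per_group=10, mirnas=["m"], noise_cv=0.1,
                atm_baseline=0.0, atm_progressor_shift=0.5, atm_noise_sd=0.2,
            )
            cohort, _ = simulate_cohort(cfg)
            cmp = atm_group_comparison(cohort)
            hits += cmp.p_value <= 0.05 and cmp.direction == -1
        assert hits >= 95  # effect size 2.5 SD at n = 10/group


class TestRelativeExpressionMatrix:
    def test_values_relative_to_untreated_mean(self):
        cohort = _cohort([20], [5], [10, 10])
        m = relative_expression_matrix(cohort, pseudo=0)
        assert m.loc["resp0", "m"] == pytest.approx(2.0)
        assert m.loc["prog0", "m"] == pytest.approx(0.5)
        assert list(m.index) == ["resp0", "prog0"]
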