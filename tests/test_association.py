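"""Burden, score-trend, frequency and age analyses."""

import numpy as np
import pandas as pd
import pytest

import missensemix as mm
from missensemix.association import gene_exposure

from conftest import (counts_cohort, make_cohort, single_category_scheme,
                      subject_row, variant_row)


class TestGroupBurden:
    def test_published_brca2_helix_low_counts_give_or_098(self):
        # carriers 2062/2323 vs non-carriers 33,006/36,517, one variant per
        # category realisation; the joint model reduces to the 2x2 fit
        cohort = counts_cohort("BRCA2", {"v_low": (2062, 2323)}, 33006, 36517,
                               helix=0.3)
        asg = mm.assign_groups(cohort.variants, mm.builtin_scheme("BRCA2"))
        res = mm.group_burden(cohort, asg)
        row = res.table.set_index("category").loc["Helix-low"]
        assert row["OR"] == pytest.approx(0.98, abs=0.005)
        assert row["n_case_carriers"] == 2062

    def test_empty_category_reported_as_na(self):
        cohort = counts_cohort("BRCA2", {"v_low": (30, 40)}, 500, 600, helix=0.3)
        asg = mm.assign_groups(cohort.variants, mm.builtin_scheme("BRCA2"))
        row = mm.group_burden(cohort, asg).table.set_index("category").loc["Helix-high"]
        assert np.isnan(row["OR"]) and row["n_case_carriers"] == 0

    def test_invariant_to_subject_order_and_stratum_names(self, small_cohort):
        cohort, _ = small_cohort
        asg = mm.assign_groups(cohort.variants, mm.builtin_scheme("CHEK2"))
        cohort2 = mm.Cohort(cohort.variants,
                            cohort.subjects.sample(frac=1, random_state=0)
                            .reset_index(drop=True))
        renamed = cohort.subjects.copy()
        renamed["stratum"] = renamed["stratum"].map(
            {"A": "zz", "B": "yy", "F": "xx"})
        cohort3 = mm.Cohort(cohort.variants, renamed)
        t1 = mm.group_burden(cohort, asg).table["OR"].to_numpy()
        t2 = mm.group_burden(cohort2, asg).table["OR"].to_numpy()
        t3 = mm.group_burden(cohort3, asg).table["OR"].to_numpy()
        np.testing.assert_allclose(t1, t2, rtol=1e-8)
        np.testing.assert_allclose(t1, t3, rtol=1e-8)

    def test_permuted_labels_give_null_odds_ratios(self, small_cohort):
        cohort, _ = small_cohort
        asg = mm.assign_groups(cohort.variants, mm.builtin_scheme("ATM"))
        rng = np.random.default_rng(11)
        covered = 0
        n_rows = 0
        for rep in range(20):
            subj = cohort.subjects.copy()
            subj["status"] = rng.permutation(subj["status"].to_numpy())
            permuted = mm.Cohort(cohort.variants, subj)
            tab = mm.group_burden(permuted, asg).table.dropna(subset=["OR"])
            covered += int(((tab["ci_low"] <= 1) & (tab["ci_high"] >= 1)).sum())
            n_rows += len(tab)
        assert covered / n_rows >= 0.9


class TestScoreTrend:
    @staticmethod
    def _carrier_cohort(slope, n=10_000, seed=4, shift=0.0):
        rng = np.random.default_rng(seed)
        score = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.1 + slope * score)))
        status = np.where(rng.random(n) < p, "case", "control")
        vrows = [variant_row(f"v{i}", helix=float(score[i] + shift))
                 for i in range(n)]
        srows = [subject_row(f"s{i}", status[i], (f"v{i}",)) for i in range(n)]
        return make_cohort(vrows, srows)

    def test_recovers_generating_slope(self):
        cohort = self._carrier_cohort(0.5)
        res = mm.carrier_score_trend(cohort, "G", "helix")
        assert res.ci_low <= np.exp(0.5) <= res.ci_high

    def test_location_invariance(self):
        c1 = self._carrier_cohort(0.4, n=2000, seed=5)
        c2 = self._carrier_cohort(0.4, n=2000, seed=5, shift=10.0)
        r1 = mm.carrier_score_trend(c1, "G", "helix")
        r2 = mm.carrier_score_trend(c2, "G", "helix")
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-6)

    def test_constant_score_rejected(self):
        vrows = [variant_row(f"v{i}", helix=0.4) for i in range(4)]
        srows = [subject_row(f"s{i}", st, (f"v{i}",))
                 for i, st in enumerate(["case", "control", "case", "control"])]
        with pytest.raises(ValueError, match="constant"):
            mm.carrier_score_trend(make_cohort(vrows, srows), "G", "helix")


class TestFrequencyBurden:
    def test_single_bin_matches_all_carrier_burden(self):
        cohort = counts_cohort("G", {"v1": (50, 30), "v2": (20, 25)}, 800, 900)
        res = mm.frequency_burden(cohort, "G")
        asg = mm.assign_groups(cohort.variants, single_category_scheme())
        burden = mm.group_burden(cohort, asg).table.iloc[0]
        row = res.table.set_index("bin").loc["<0.1%"]
        assert row["OR"] == pytest.approx(burden["OR"], rel=1e-6)

    def test_log_scale_slope_is_reparameterised_two_group_contrast(self):
        # with exactly two distinct frequencies the continuous-in-log fit is a
        # linear reparameterisation of the two-group indicator fit
        vrows = [variant_row("lo", frequency=1e-4),
                 variant_row("hi", frequency=1e-3)]
        rng = np.random.default_rng(6)
        srows = []
        i = 0
        for vid, n_case, n_ctrl in [("lo", 60, 40), ("hi", 45, 55)]:
            for _ in range(n_case):
                srows.append(subject_row(f"s{i}", "case", (vid,))); i += 1
            for _ in range(n_ctrl):
                srows.append(subject_row(f"s{i}", "control", (vid,))); i += 1
        for _ in range(500):
            srows.append(subject_row(f"s{i}", "case")); i += 1
            srows.append(subject_row(f"s{i}", "control")); i += 1
        cohort = make_cohort(vrows, srows)
        res = mm.frequency_burden(cohort, "G")
        b_log = np.log(res.carrier_tests["log"].odds_ratio)
        b_two = np.log(res.carrier_tests["two_group"].odds_ratio)
        assert b_log * (np.log(1e-3) - np.log(1e-4)) == pytest.approx(b_two,
                                                                      rel=1e-5)

    def test_empty_bins_reported_as_na(self):
        cohort = counts_cohort("G", {"v1": (50, 30)}, 800, 900)
        tab = mm.frequency_burden(cohort, "G").table.set_index("bin")
        assert np.isnan(tab.loc["1–5%", "OR"])


class TestSingleVariant:
    def test_crude_or_from_published_brca1_counts(self):
        cohort = counts_cohort("BRCA1", {"v": (29, 2)}, 34191 - 29, 37996 - 2)
        res = mm.single_variant_or(cohort, "v")
        assert res.odds_ratio == pytest.approx(
            (29 * 37996) / (2 * 34191), rel=0.02)

    def test_case_only_carriers_flagged_unbounded(self):
        cohort = counts_cohort("G", {"v": (5, 0)}, 100, 120)
        res = mm.single_variant_or(cohort, "v")
        assert res.unbounded and res.odds_ratio == np.inf

    def test_balanced_single_carriers_give_or_near_one(self):
        cohort = counts_cohort("G", {"v": (1, 1)}, 500, 500)
        res = mm.single_variant_or(cohort, "v")
        assert res.odds_ratio == pytest.approx(1.0, rel=0.01)


class TestCaseOnlyAgeTrend:
    @staticmethod
    def _age_cohort(beta_age, n=10_000, seed=7, permute=False):
        rng = np.random.default_rng(seed)
        age = rng.uniform(30, 80, size=n)
        p_top = 1 / (1 + np.exp(-(1.0 + beta_age * age)))
        top = rng.random(n) < p_top
        vrows = [variant_row("v_top", helix=0.9), variant_row("v_low", helix=0.1)]
        if permute:
            age = rng.permutation(age)
        srows = [subject_row(f"s{i}", "case", ("v_top",) if top[i] else ("v_low",),
                             age=float(age[i])) for i in range(n)]
        srows.append(subject_row("ctrl", "control", ()))
        return make_cohort(vrows, srows)

    @pytest.fixture(scope="class")
    def scheme(self):
        return mm.builtin_scheme("CHEK2")

    def test_recovers_age_coefficient(self):
        cohort = self._age_cohort(-0.02)
        asg = mm.GroupAssignment("G", {"v_top": "Helix-high", "v_low": "Helix-low"},
                                 mm.builtin_scheme("CHEK2"))
        res = mm.case_only_age_trend(cohort, asg, "Helix-high")
        assert res.ci_low <= np.exp(-0.02) <= res.ci_high

    def test_permuted_age_gives_null(self):
        ors = []
        for seed in range(5):
            cohort = self._age_cohort(-0.02, n=4000, seed=seed, permute=True)
            asg = mm.GroupAssignment(
                "G", {"v_top": "Helix-high", "v_low": "Helix-low"},
                mm.builtin_scheme("CHEK2"))
            ors.append(mm.case_only_age_trend(cohort, asg, "Helix-high").odds_ratio)
        assert np.mean(ors) == pytest.approx(1.0, abs=0.01)

    def test_single_category_rejected(self):
        vrows = [variant_row("v_top", helix=0.9)]
        srows = [subject_row(f"s{i}", "case", ("v_top",), age=50.0 + i)
                 for i in range(5)]
        cohort = make_cohort(vrows, srows)
        asg = mm.GroupAssignment("G", {"v_top": "Helix-high"},
                                 mm.builtin_scheme("CHEK2"))
        with pytest.raises(ValueError, match="categories"):
            mm.case_only_age_trend(cohort, asg, "Helix-high")


def test_gene_exposure_drops_multi_missense_carriers(tiny_cohort):
    asg = mm.GroupAssignment("G", {"G:m1": "all", "G:m2": "all"},
                             single_category_scheme())
    labels, dropped = gene_exposure(tiny_cohort, asg)
    assert dropped == 1          # s5 carries both missense variants
    assert labels[0] == "all"    # s1 carries exactly one
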