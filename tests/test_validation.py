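"""Frozen-parameter validation: nuisance refits, GOF, predicted ORs, composite."""

import numpy as np
import pandas as pd
import pytest

import missensemix as mm
from missensemix.mixture import MixtureSpec
from missensemix.validation import gof_chisq

from conftest import (counts_cohort, make_cohort, single_category_scheme,
                      small_two_gene_config, subject_row, variant_row)


class TestAdjustedAlpha:
    @pytest.mark.parametrize("ca,co,f,expect", [
        (0.7, 0.7, 0.3, 0.7),       # equal inputs pass through
        (0.4, 0.2, 0.5, 0.3),       # plain weighted average
        (0.4, 0.2, 0.0, 0.2),       # f=0 returns the control side
        (0.4, 0.2, 1.0, 0.4),
    ])
    def test_weighted_average(self, ca, co, f, expect):
        assert mm.adjusted_alpha(ca, co, f) == pytest.approx(expect)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mm.adjusted_alpha(1.2, 0.5, 0.5)


class TestGofChisq:
    def test_hand_arithmetic(self):
        assert gof_chisq([10, 20], [15, 15]) == pytest.approx(25 / 15 + 25 / 15)

    def test_zero_when_observed_equals_expected(self):
        assert gof_chisq([3, 4, 5], [3, 4, 5]) == 0.0

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            gof_chisq([1], [0])


@pytest.fixture(scope="module")
def burden_cohort():
    cohort = counts_cohort("CHEK2", {"v_low": (120, 100), "v_hi": (90, 50)},
                           4000, 4200)
    cohort.variants.loc[cohort.variants["variant_id"] == "v_hi", "helix"] = 0.9
    asg = mm.assign_groups(cohort.variants, mm.builtin_scheme("CHEK2"))
    return cohort, asg


class TestRefitNuisance:
    def test_zero_betas_reduce_to_stratum_only_fit(self, burden_cohort):
        cohort, asg = burden_cohort
        fit = mm.refit_nuisance(cohort, asg, {c: 0.0 for c in asg.labels})
        ref = mm.fit_logistic(cohort.subjects["status"],
                              mm.stratum_design(cohort.subjects["stratum"]))
        assert fit.params["intercept"] == pytest.approx(ref.params["intercept"],
                                                        abs=1e-8)

    def test_empty_validation_rejected(self, burden_cohort):
        cohort, asg = burden_cohort
        empty = mm.Cohort(cohort.variants, cohort.subjects.iloc[:0])
        with pytest.raises(ValueError, match="empty"):
            mm.refit_nuisance(empty, asg, {})

    def test_single_class_stratum_rejected(self, burden_cohort):
        cohort, asg = burden_cohort
        subj = cohort.subjects.copy()
        extra = subj.iloc[[0]].assign(subject_id="odd", stratum="LONELY")
        bad = mm.Cohort(cohort.variants,
                        pd.concat([subj, extra], ignore_index=True))
        with pytest.raises(ValueError, match="LONELY"):
            mm.refit_nuisance(bad, asg, {})

    def test_intercept_consistent_under_shared_generative_model(self):
        cfg = small_two_gene_config(target=4000, pool=60_000)
        c1, _ = mm.simulate(cfg, seed=21)
        c2, _ = mm.simulate(cfg, seed=22)
        asg = mm.assign_groups(c1.variants, mm.builtin_scheme("CHEK2"))
        betas = {c: 0.0 for c in asg.labels}
        f1 = mm.refit_nuisance(c1, asg, betas)
        asg2 = mm.assign_groups(c2.variants, mm.builtin_scheme("CHEK2"))
        f2 = mm.refit_nuisance(c2, asg2, {c: 0.0 for c in asg2.labels})
        se = f1.se()["intercept"] + f2.se()["intercept"]
        assert abs(f1.params["intercept"] - f2.params["intercept"]) < 3 * se


class TestCalibrationGof:
    def test_expected_counts_conserve_totals(self, burden_cohort):
        cohort, asg = burden_cohort
        report = mm.calibration_gof(cohort, asg,
                                    {"Helix-low": 0.1, "Helix-high": 0.5})
        subj = cohort.subjects
        total_cases = float((subj["status"] == "case").sum())
        carriers_cases = report.table["obs_cases"].sum()
        # the intercept MLE balances predicted and observed case totals, so
        # the baseline expectation absorbs exactly the remainder
        assert report.table["obs_cases"].sum() == carriers_cases
        assert report.chi_sq >= 0
        assert report.df == len(asg.labels) - 1

    def test_stratum_relabelling_invariance(self, small_cohort):
        cohort, _ = small_cohort
        asg = mm.assign_groups(cohort.variants, mm.builtin_scheme("CHEK2"))
        logor = {"Helix-low": 0.2, "Helix-high": 0.5}
        r1 = mm.calibration_gof(cohort, asg, logor)
        renamed = cohort.subjects.copy()
        renamed["stratum"] = renamed["stratum"].map({"A": "q", "B": "r", "F": "s"})
        r2 = mm.calibration_gof(mm.Cohort(cohort.variants, renamed), asg, logor)
        assert r1.chi_sq == pytest.approx(r2.chi_sq, rel=1e-8)


class TestPPWeightedOr:
    def _validation(self):
        cohort = counts_cohort("G", {"va": (30, 30), "vb": (20, 20)}, 500, 500)
        asg = mm.assign_groups(cohort.variants, single_category_scheme())
        return cohort, asg

    def test_pp_one_returns_full_or(self):
        cohort, asg = self._validation()
        pp = pd.Series({"va": 1.0, "vb": 1.0})
        out = mm.pp_weighted_or(cohort, pp, np.log(3.0), asg)
        assert out.loc["all", "pred_OR"] == pytest.approx(3.0)

    def test_pp_zero_returns_null_or(self):
        cohort, asg = self._validation()
        pp = pd.Series({"va": 0.0, "vb": 0.0})
        assert mm.pp_weighted_or(cohort, pp, np.log(3.0), asg).loc[
            "all", "pred_OR"] == pytest.approx(1.0)

    def test_linear_odds_mixing(self):
        cohort, asg = self._validation()
        pp = pd.Series({"va": 0.5, "vb": 0.5})
        assert mm.pp_weighted_or(cohort, pp, np.log(3.0), asg).loc[
            "all", "pred_OR"] == pytest.approx(2.0)

    def test_unseen_variants_dropped(self):
        cohort, asg = self._validation()
        pp = pd.Series({"va": 1.0})       # vb unseen in training
        out = mm.pp_weighted_or(cohort, pp, np.log(3.0), asg)
        assert out.loc["all", "n_dropped"] == 40
        assert out.loc["all", "pred_OR"] == pytest.approx(3.0)


class TestComposite:
    def test_multi_gene_carrier_excluded_and_counted(self):
        vrows = [variant_row("g1v", gene="G1"), variant_row("g2v", gene="G2")]
        srows = [subject_row("dual", "case", ("g1v", "g2v"))]
        srows += [subject_row(f"c{i}", "case" if i % 3 else "control", ("g1v",))
                  for i in range(12)]
        srows += [subject_row(f"d{i}", "control" if i % 3 else "case", ("g2v",))
                  for i in range(12)]
        srows += [subject_row(f"n{i}", "case" if i % 2 else "control")
                  for i in range(400)]
        cohort = make_cohort(vrows, srows)
        a1 = mm.GroupAssignment("G1", {"g1v": "all"}, single_category_scheme("G1"))
        a2 = mm.GroupAssignment("G2", {"g2v": "all"}, single_category_scheme("G2"))
        res = mm.composite_fit(cohort, [a1, a2])
        assert res.excluded_multigene == 1
        assert res.fit.n == len(srows) - 1

    def test_single_gene_composite_equals_group_burden(self):
        cohort = counts_cohort("G", {"va": (60, 40), "vb": (25, 30)}, 900, 1000)
        asg = mm.assign_groups(cohort.variants, single_category_scheme())
        comp = mm.composite_fit(cohort, [asg])
        burden = mm.group_burden(cohort, asg)
        assert comp.table["OR"].iloc[0] == pytest.approx(
            burden.table["OR"].iloc[0], rel=1e-8)

    def test_recovers_generating_or_with_known_truth(self, small_cohort):
        cohort, truth = small_cohort
        cohort_f = mm.filter_subjects(cohort,
                                      drop_ptv_carriers_in=["ATM", "CHEK2"])
        asgs = [mm.assign_groups(cohort.variants, mm.builtin_scheme("ATM")),
                mm.assign_groups(cohort.variants, mm.builtin_scheme("CHEK2"))]
        res = mm.composite_fit(cohort_f, asgs)
        # CHEK2 Helix-high: alpha 0.9, OR 1.8 -> carrier OR ~ 0.9*1.8 + 0.1
        row = res.table[(res.table["gene"] == "CHEK2")
                        & (res.table["category"] == "Helix-high")].iloc[0]
        expected = 0.9 * 1.8 + 0.1
        assert row["ci_low"] < expected < row["ci_high"]
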