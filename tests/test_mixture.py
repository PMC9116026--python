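"""EM mixture model: component likelihoods, E-step, fits and profile CIs."""

import numpy as np
import pandas as pd
import pytest

import missensemix as mm
from missensemix.mixture import (MixtureSpec, VariantLikelihoods,
                                 component_likelihoods, e_step)

from conftest import (make_cohort, single_category_scheme, small_two_gene_config,
                      subject_row, variant_row)


def micro_cohort(carried_status, extra_variants=()):
    """Single-stratum cohort from (variant_or_None, status) pairs."""
    vids = sorted({v for v, _ in carried_status if v} | set(extra_variants))
    vrows = [variant_row(v) for v in vids]
    srows = [subject_row(f"s{i}", st, (v,) if v else ())
             for i, (v, st) in enumerate(carried_status)]
    return make_cohort(vrows, srows)


class TestComponentLikelihoods:
    def test_single_case_carrier_hand_values(self):
        cohort = micro_cohort([("v1", "case"), (None, "control")])
        lik = component_likelihoods(cohort, "v1", {"intercept": 0.0}, np.log(2))
        assert lik.L1 == pytest.approx(2 / 3)
        assert lik.L0 == pytest.approx(1 / 2)

    def test_zero_carrier_variant_is_uninformative(self):
        cohort = micro_cohort([("v1", "case"), (None, "control")],
                              extra_variants=["v2"])
        lik = component_likelihoods(cohort, "v2", {"intercept": 0.0}, 1.0)
        assert lik.L1 == lik.L0 == 1.0

    def test_zero_beta_collapses_states(self):
        cohort = micro_cohort([("v1", "case"), ("v1", "control")])
        lik = component_likelihoods(cohort, "v1", {"intercept": 0.3}, 0.0)
        assert lik.L1 == pytest.approx(lik.L0)

    def test_stratum_terms_enter_linear_predictor(self):
        cohort = micro_cohort([("v1", "case")])
        base = component_likelihoods(cohort, "v1", {"intercept": 0.0}, 0.5)
        shifted = component_likelihoods(
            cohort, "v1", {"intercept": 0.0, "stratum[X]": 1.0}, 0.5)
        assert shifted.L1 > base.L1

    def test_unknown_variant_rejected(self):
        cohort = micro_cohort([("v1", "case")])
        with pytest.raises(Exception, match="unknown"):
            component_likelihoods(cohort, "zzz", {"intercept": 0.0}, 0.5)


class TestEStep:
    def test_zero_alpha_gives_zero_posterior(self):
        assert e_step(VariantLikelihoods("v", 0.9, 0.5), 0.0) == 0.0

    def test_equal_likelihoods_return_alpha(self):
        assert e_step(VariantLikelihoods("v", 0.4, 0.4), 0.3) == pytest.approx(0.3)

    def test_hand_arithmetic(self):
        assert e_step(VariantLikelihoods("v", 2 / 3, 1 / 2), 0.5) == \
            pytest.approx(4 / 7)

    def test_posterior_monotone_in_case_evidence(self):
        # adding a case carrier to a variant never decreases its posterior
        # when the risk log-OR is positive
        base = micro_cohort([("v1", "case"), ("v1", "control"), (None, "control")])
        more = micro_cohort([("v1", "case"), ("v1", "control"), ("v1", "case"),
                             (None, "control")])
        nuis = {"intercept": -0.2}
        for alpha in (0.1, 0.5, 0.9):
            p0 = e_step(component_likelihoods(base, "v1", nuis, 0.8), alpha)
            p1 = e_step(component_likelihoods(more, "v1", nuis, 0.8), alpha)
            assert p1 >= p0


@pytest.fixture(scope="module")
def fitted_small():
    cohort, truth = mm.simulate(small_two_gene_config(target=4000, pool=60_000),
                                seed=3)
    asg = mm.assign_groups(cohort.variants, mm.builtin_scheme("CHEK2"))
    spec = MixtureSpec("CHEK2", mode="unconstrained", max_iter=1500)
    res = mm.MissenseMixtureModel(cohort, asg, spec=spec).fit(n_starts=1)
    return cohort, asg, res


class TestFit:
    def test_loglik_trace_non_decreasing(self, fitted_small):
        _, _, res = fitted_small
        assert np.all(np.diff(res.loglik_trace) > -1e-8)

    def test_posteriors_lie_in_unit_interval(self, fitted_small):
        _, _, res = fitted_small
        p = res.posteriors.to_numpy()
        assert ((p >= 0) & (p <= 1)).all()

    def test_alpha_fixed_at_one_reproduces_carrier_logistic_fit(self):
        cohort, _ = mm.simulate(small_two_gene_config(target=3000, pool=40_000),
                                seed=8)
        asg = mm.assign_groups(cohort.variants, mm.builtin_scheme("CHEK2"))
        spec = MixtureSpec("CHEK2", mode="unconstrained", tol=1e-10)
        model = mm.MissenseMixtureModel(cohort, asg, spec=spec)
        res = model.fit(n_starts=1, fix_alpha=1.0)

        # reference: plain logistic fit with missense-carrier and PTV
        # indicators on the same subject set
        from missensemix.association import gene_exposure, ptv_carrier_mask
        sub = cohort.subjects
        keep_model = mm.Cohort(cohort.variants, sub)
        exposure, _ = gene_exposure(keep_model, asg)
        ptv = ptv_carrier_mask(keep_model, "CHEK2")
        carrier = np.array([lab is not None for lab in exposure]) & ~ptv
        multi = np.array([
            lab is None and sum(v in asg.mapping for v in c) > 1
            for lab, c in zip(exposure, sub["carried"])]) & ~ptv
        keep = ~multi
        X = mm.stratum_design(sub.loc[keep, "stratum"])
        X["mis"] = carrier[keep].astype(float)
        X["ptv"] = ptv[keep].astype(float)
        ref = mm.fit_logistic(sub.loc[keep, "status"], X)
        assert res.beta_mis == pytest.approx(ref.params["mis"], abs=1e-6)
        assert res.beta_ptv == pytest.approx(ref.params["ptv"], abs=1e-6)
        assert res.loglik == pytest.approx(ref.loglik, abs=1e-4)

    def test_constrained_ties_missense_to_ptv(self, fitted_small):
        cohort, asg, _ = fitted_small
        res = mm.MissenseMixtureModel(
            cohort, asg, spec=MixtureSpec("CHEK2", mode="constrained",
                                          max_iter=800)).fit(n_starts=1)
        assert res.beta_mis == res.beta_ptv

    def test_multi_missense_subjects_excluded_with_count(self):
        vrows = [variant_row("v1"), variant_row("v2")]
        srows = [subject_row("s0", "case", ("v1", "v2")),
                 subject_row("s1", "case", ("v1",)),
                 subject_row("s2", "control", ("v2",)),
                 subject_row("s3", "case"), subject_row("s4", "control")]
        cohort = make_cohort(vrows, srows)
        asg = mm.assign_groups(cohort.variants, single_category_scheme())
        model = mm.MissenseMixtureModel(cohort, asg, mode="constrained")
        assert model.n_excluded_multi == 1
        assert model.n_subjects == 4

    def test_no_carriers_rejected(self):
        vrows = [variant_row("v1")]
        srows = [subject_row("s0", "case"), subject_row("s1", "control")]
        cohort = make_cohort(vrows, srows)
        asg = mm.GroupAssignment("G", {"v1": "all"}, single_category_scheme())
        with pytest.raises(ValueError, match="no carriers"):
            mm.MissenseMixtureModel(cohort, asg, mode="constrained")

    def test_two_level_nests_constrained(self, fitted_small):
        cohort, asg, _ = fitted_small
        con = mm.MissenseMixtureModel(
            cohort, asg, spec=MixtureSpec("CHEK2", mode="constrained",
                                          max_iter=800)).fit(n_starts=1)
        two = mm.MissenseMixtureModel(
            cohort, asg, spec=MixtureSpec("CHEK2", mode="two_level",
                                          max_iter=800)).fit(
            n_starts=1, init=(None, None) if False else None)
        assert two.loglik >= con.loglik - 1e-4
        a = two.alpha
        assert ((a >= 0) & (a <= 1)).all().all()
        assert (a.sum(axis=1) <= 1 + 1e-9).all()


class TestAlphaSummaries:
    def test_control_only_alpha_uses_control_seen_variants_only(self):
        cohort = micro_cohort([("v1", "case"), ("v1", "control"),
                               ("v2", "case"), (None, "case"),
                               (None, "control"), (None, "control")])
        asg = mm.assign_groups(cohort.variants, single_category_scheme())
        res = mm.MissenseMixtureModel(cohort, asg, mode="constrained").fit(
            n_starts=1)
        post = res.posteriors
        manual = post["v1"]          # v2 has no control carrier
        assert float(res.control_only_alpha().iloc[0]) == pytest.approx(manual)

    def test_no_control_variants_warns_and_gives_na(self):
        cohort = micro_cohort([("v1", "case"), (None, "case"),
                               (None, "control")])
        asg = mm.assign_groups(cohort.variants, single_category_scheme())
        res = mm.MissenseMixtureModel(cohort, asg, mode="constrained").fit(
            n_starts=1)
        with pytest.warns(UserWarning, match="control"):
            out = res.control_only_alpha()
        assert np.isnan(float(out.iloc[0]))

    def test_control_only_never_exceeds_naive_under_case_enrichment(
            self, fitted_small):
        _, _, res = fitted_small
        naive = res.alpha["Helix-high"]
        ctrl = res.control_only_alpha()["Helix-high"]
        assert ctrl <= naive + 1e-9


class TestProfileCI:
    def test_interval_contains_point_estimate(self, fitted_small):
        _, _, res = fitted_small
        lo, hi = res.alpha_profile_ci("Helix-high", tol=5e-3)
        assert lo <= res.alpha["Helix-high"] <= hi
        assert 0 <= lo < hi <= 1

    def test_no_signal_category_has_zero_lower_bound(self):
        cohort = micro_cohort([("v1", "case"), ("v1", "control"),
                               ("v2", "control"), (None, "case"),
                               (None, "control")])
        asg = mm.assign_groups(cohort.variants, single_category_scheme())
        res = mm.MissenseMixtureModel(cohort, asg, mode="constrained").fit(
            n_starts=1)
        with pytest.warns(UserWarning):
            lo, hi = res.alpha_profile_ci("all")
        assert lo == 0.0


class TestBootstrapCI:
    def test_interval_sane_deterministic_and_state_restoring(self, fitted_small):
        cohort, asg, res = fitted_small
        lo, hi = res.alpha_bootstrap_ci("Helix-high", B=8, seed=2)
        lo2, hi2 = res.alpha_bootstrap_ci("Helix-high", B=8, seed=2)
        assert (lo, hi) == (lo2, hi2)
        assert 0 <= lo <= hi <= 1
        # resampling must leave the fitted model untouched
        refit = mm.MissenseMixtureModel(
            cohort, asg, spec=MixtureSpec("CHEK2", mode="unconstrained",
                                          max_iter=1500)).fit(n_starts=1)
        assert refit.loglik == pytest.approx(res.loglik, abs=1e-6)


class TestCompareLoglik:
    def test_identical_fits_give_zero(self, fitted_small):
        _, _, res = fitted_small
        assert mm.compare_loglik(res, res) == 0.0

    def test_signed_arithmetic(self):
        class Stub:
            def __init__(self, ll):
                self.loglik = ll
                self.data_key = "k"
        assert mm.compare_loglik(Stub(-100.0), Stub(-101.0)) == pytest.approx(2.0)

    def test_different_subject_sets_rejected(self, fitted_small):
        cohort, asg, res = fitted_small
        other = mm.Cohort(cohort.variants,
                          cohort.subjects.iloc[:-10].reset_index(drop=True))
        res2 = mm.MissenseMixtureModel(
            other, asg, spec=MixtureSpec("CHEK2", mode="unconstrained",
                                         max_iter=50)).fit(n_starts=1)
        with pytest.raises(ValueError, match="different"):
            mm.compare_loglik(res, res2)

    def test_nested_alpha_restriction_never_improves(self, fitted_small):
        cohort, asg, res = fitted_small
        fixed = mm.MissenseMixtureModel(
            cohort, asg, spec=MixtureSpec("CHEK2", mode="unconstrained",
                                          max_iter=1500)).fit(
            n_starts=1, fix_alpha={"Helix-high": 0.5})
        assert mm.compare_loglik(res, fixed) >= -1e-6
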