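"""Observation likelihoods: concentrated CPUE, multinomial CAA, binomial
otolith, negative-binomial tags, mixture weights, total objective."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import binom, multinomial, nbinom, poisson

from mast.config import default_config
from mast.dynamics import Trajectory
from mast.io import (CAARecord, IndexSeries, ObservationBundle, OtolithRecord,
                     TagCohort)
from mast.likelihoods import (LikelihoodError, caa_loglik,
                              conventional_tag_loglik, cpue_catchability,
                              cpue_loglik, otolith_loglik,
                              reporting_rate_prior_nll, stock_mixture_weights,
                              total_objective)


def make_series(values, **kw):
    years = np.arange(2000, 2000 + len(values))
    return IndexSeries(kw.pop("name", "s"), kw.pop("area", "WAtl"),
                       kw.pop("quarter", 2), kw.pop("fleet", "LL"),
                       years, np.asarray(values, float))


class TestCpueLoglik:
    def test_exact_proportionality_minimizes_rss(self):
        v = np.array([1.0, 2.0, 5.0])
        s = make_series(3.7 * v)
        nll = cpue_loglik(s, v)
        # zero residual sum of squares -> NLL at its floor
        assert nll == 0.5 * 3 * np.log(1e-12)

    def test_scale_invariance_in_q(self):
        v = np.array([1.0, 2.0, 5.0, 4.0])
        s1 = make_series([2.0, 3.0, 9.0, 9.0])
        s2 = make_series([20.0, 30.0, 90.0, 90.0])
        assert cpue_loglik(s1, v) == pytest.approx(cpue_loglik(s2, v),
                                                   rel=1e-14)

    def test_three_point_series_against_numeric_q_profile(self):
        # I=(2,4,8), V=(1,2,5): ln q_hat = mean(ln2, ln2, ln1.6)
        s = make_series([2.0, 4.0, 8.0])
        v = np.array([1.0, 2.0, 5.0])
        z = np.log(s.values) - np.log(v)
        assert np.log(cpue_catchability(s, v)) == pytest.approx(z.mean())

        def profile(lnq):
            return 0.5 * 3 * np.log(np.sum((z - lnq) ** 2))

        res = minimize_scalar(profile, bounds=(z.min(), z.max()),
                              method="bounded", options={"xatol": 1e-10})
        assert cpue_loglik(s, v) == pytest.approx(profile(res.x), abs=1e-6)
        assert res.x == pytest.approx(z.mean(), abs=1e-6)

    def test_nonpositive_prediction_rejected(self):
        s = make_series([1.0, 2.0])
        with pytest.raises(LikelihoodError):
            cpue_loglik(s, np.array([1.0, 0.0]))


class TestCaaLoglik:
    def rec(self, props):
        props = np.asarray(props, float)
        return CAARecord("west", 2000, props, age_lo=1, age_hi=len(props))

    def test_minimum_at_observed_equals_entropy(self):
        obs = np.array([0.5, 0.3, 0.2])
        nll = caa_loglik(self.rec(obs), obs, effective_n=100)
        assert nll == pytest.approx(-100 * np.sum(obs * np.log(obs)))
        # any other prediction is worse
        assert caa_loglik(self.rec(obs), np.array([0.4, 0.4, 0.2]),
                          effective_n=100) > nll

    def test_linear_in_effective_n(self):
        obs = np.array([0.5, 0.3, 0.2])
        p1, p2 = np.array([0.4, 0.4, 0.2]), np.array([0.3, 0.4, 0.3])
        d50 = (caa_loglik(self.rec(obs), p1, 50)
               - caa_loglik(self.rec(obs), p2, 50))
        d100 = (caa_loglik(self.rec(obs), p1, 100)
                - caa_loglik(self.rec(obs), p2, 100))
        assert d100 == pytest.approx(2 * d50, rel=1e-12)

    def test_against_multinomial_logpmf_differences(self):
        # NLL differences equal multinomial log-pmf differences at integer
        # counts (the composition-independent constant cancels)
        obs = np.array([0.5, 0.3, 0.2])
        n_eff = 100
        counts = (obs * n_eff).astype(int)
        p1, p2 = np.array([0.4, 0.4, 0.2]), np.array([0.25, 0.5, 0.25])
        ours = (caa_loglik(self.rec(obs), p1, n_eff)
                - caa_loglik(self.rec(obs), p2, n_eff))
        scipy_diff = (multinomial.logpmf(counts, n_eff, p2)
                      - multinomial.logpmf(counts, n_eff, p1))
        assert ours == pytest.approx(scipy_diff, rel=1e-10)

    def test_record_not_summing_to_one_rejected(self):
        from mast.io import DataError

        with pytest.raises(DataError):
            CAARecord("west", 2000, np.array([0.5, 0.6]), 1, 2)


class TestOtolithLoglik:
    def test_all_west_with_p_near_one(self):
        rec = OtolithRecord("WAtl", "giant", 2000, 3, 10, 10)
        assert otolith_loglik(rec, 1.0 - 1e-12) == pytest.approx(
            -10 * np.log(1 - 1e-6), abs=1e-4)

    def test_direct_pmf(self):
        rec = OtolithRecord("WAtl", "medium", 2000, 3, 5, 10)
        expected = -binom.logpmf(5, 10, 0.5)
        assert otolith_loglik(rec, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_clamping_keeps_nll_finite(self):
        rec = OtolithRecord("WAtl", "school", 2000, 3, 0, 10)
        nll = otolith_loglik(rec, 1.0)  # clamped to 1 - 1e-6
        assert np.isfinite(nll)
        nll2 = otolith_loglik(rec, 0.0)
        assert np.isfinite(nll2) and nll2 < nll


def hand_trajectory(n_west, n_east, area="WAtl", n_years=2):
    """Minimal trajectory with specified constant numbers in one area."""
    cfg = default_config()
    st = cfg.structure
    T = 4 * n_years
    N = np.zeros((T + 1, st.n_stocks, st.n_ages, st.n_areas))
    j = st.area_index(area)
    N[:, 0, 8, j] = n_west
    N[:, 1, 8, j] = n_east
    return Trajectory(cfg, {}, N, np.zeros((T, st.n_fleets, st.n_areas)),
                      np.full((T, st.n_stocks, st.n_ages, st.n_areas), 0.035),
                      np.zeros((T, st.n_stocks)))


class TestStockMixtureWeights:
    def test_single_stock_area_gets_weight_one(self):
        traj = hand_trajectory(500.0, 300.0, area="WAtl")
        # GoM is inaccessible to east; put western fish there
        traj.N[:, 0, 8, 0] = 100.0
        w = stock_mixture_weights(traj, 0, "GoM", 8)
        assert w["west"] == pytest.approx(1.0)

    def test_equal_numbers_equal_weights(self):
        traj = hand_trajectory(400.0, 400.0)
        w = stock_mixture_weights(traj, 0, "WAtl", 8)
        assert w["west"] == pytest.approx(0.5)

    def test_ratio(self):
        traj = hand_trajectory(900.0, 100.0)
        w = stock_mixture_weights(traj, 0, "WAtl", 8)
        assert w["west"] == pytest.approx(0.9)
        assert w["east"] == pytest.approx(0.1)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_zero_total_gives_uniform_with_warning(self):
        traj = hand_trajectory(0.0, 0.0)
        with pytest.warns(UserWarning, match="uniform"):
            w = stock_mixture_weights(traj, 0, "WAtl", 8)
        assert w["west"] == 0.5


class TestNegativeBinomial:
    def test_poisson_limit(self):
        from mast.likelihoods import _nb_logpmf

        k = np.arange(0, 12)
        mean = np.full(k.shape, 3.3)
        big = 1e8
        np.testing.assert_allclose(_nb_logpmf(k, mean, big),
                                   poisson.logpmf(k, 3.3), atol=1e-6)

    def test_matches_scipy_parameterization(self):
        from mast.likelihoods import _nb_logpmf

        r, m = 2.0, 4.0
        k = np.arange(0, 15)
        np.testing.assert_allclose(
            _nb_logpmf(k, np.full(k.shape, m), r),
            nbinom.logpmf(k, r, r / (r + m)), rtol=1e-12)


class TestConventionalTagLoglik:
    def _setup(self, reduced_truth, reduced_dataset):
        from mast.model import MASTModel

        catches, bundle, _ = reduced_dataset
        model = MASTModel(catches, ObservationBundle(), reduced_truth.config)
        traj, matrices, _ = model.evaluate(reduced_truth.params)
        return traj, matrices, reduced_truth

    def test_zero_reporting_rate_prediction_zero(self, reduced_truth,
                                                 reduced_dataset):
        traj, matrices, truth = self._setup(reduced_truth, reduced_dataset)
        cohort = TagCohort("c", "GoM", 1995, 2, 6, 100, stock="west")
        nll0 = conventional_tag_loglik(
            cohort, traj, matrices, np.zeros(4), 2.0, 0.02)
        # observing zero recaptures is the NB pmf maximum: better than any
        # positive reporting rate that predicts recaptures
        nll_pos = conventional_tag_loglik(
            cohort, traj, matrices, np.full(4, 0.5), 2.0, 0.02)
        assert nll0 < nll_pos

    def test_structural_zero_heavily_penalized(self, reduced_truth,
                                               reduced_dataset):
        traj, matrices, truth = self._setup(reduced_truth, reduced_dataset)
        clean = TagCohort("c", "WAtl", 1995, 2, 6, 100, stock="west")
        dirty = TagCohort(
            "c", "WAtl", 1995, 2, 6, 100, stock="west",
            recaptures=[("Med", 1996, 2, "PS", 2)])  # west cannot reach Med
        rr = np.full(4, 0.2)
        nll_clean = conventional_tag_loglik(clean, traj, matrices, rr, 2.0,
                                            0.02)
        nll_dirty = conventional_tag_loglik(dirty, traj, matrices, rr, 2.0,
                                            0.02)
        assert np.isfinite(nll_dirty)
        assert nll_dirty - nll_clean > 20.0

    def test_unknown_stock_mixture_between_components(self, reduced_truth,
                                                      reduced_dataset):
        traj, matrices, truth = self._setup(reduced_truth, reduced_dataset)
        rr = np.full(4, 0.2)
        base = dict(area="WAtl", year=1995, quarter=2, age=6, count=100,
                    recaptures=[("WAtl", 1995, 4, "LL", 1)])
        nll_w = conventional_tag_loglik(
            TagCohort("w", stock="west", **base), traj, matrices, rr, 2.0,
            0.02)
        nll_e = conventional_tag_loglik(
            TagCohort("e", stock="east", **base), traj, matrices, rr, 2.0,
            0.02)
        nll_u = conventional_tag_loglik(
            TagCohort("u", stock="unknown", **base), traj, matrices, rr, 2.0,
            0.02)
        assert min(nll_w, nll_e) - 1e-9 <= nll_u <= max(nll_w, nll_e) + 1e-9


class TestTotalObjective:
    def test_empty_bundle_gives_prior_terms_only(self, reduced_truth,
                                                 reduced_dataset):
        from mast.model import MASTModel

        catches, _, _ = reduced_dataset
        model = MASTModel(catches, ObservationBundle(), reduced_truth.config)
        traj, matrices, _ = model.evaluate(reduced_truth.params)
        rr = np.full(4, 0.3)
        val, brk = total_objective(traj, matrices, ObservationBundle(), rr,
                                   2.0, 0.9)
        assert val == pytest.approx(brk["priors"][1])
        prior = reduced_truth.config.reporting_prior
        expected = np.sum(0.5 * ((rr - prior.mean) / prior.sd) ** 2)
        assert brk["priors"][1] == pytest.approx(expected)

    def test_duplicating_series_doubles_its_component(self, reduced_truth,
                                                      reduced_dataset):
        from mast.model import MASTModel

        catches, bundle, _ = reduced_dataset
        model = MASTModel(catches, ObservationBundle(), reduced_truth.config)
        traj, matrices, _ = model.evaluate(reduced_truth.params)
        rr = reduced_truth.params.reporting
        one = ObservationBundle(cpue=[bundle.cpue[0]])
        two = ObservationBundle(cpue=[bundle.cpue[0], bundle.cpue[0]])
        _, brk1 = total_objective(traj, matrices, one, rr, 2.0, 0.9)
        _, brk2 = total_objective(traj, matrices, two, rr, 2.0, 0.9)
        assert brk2["cpue"][1] == pytest.approx(2 * brk1["cpue"][1], rel=1e-12)

    def test_component_isolation(self, reduced_truth, reduced_dataset):
        from mast.model import MASTModel

        catches, bundle, _ = reduced_dataset
        model = MASTModel(catches, ObservationBundle(), reduced_truth.config)
        traj, matrices, _ = model.evaluate(reduced_truth.params)
        rr = reduced_truth.params.reporting
        _, full = total_objective(traj, matrices, bundle, rr, 2.0, 0.9)
        no_oto = ObservationBundle(cpue=bundle.cpue, caa=bundle.caa,
                                   tag_cohorts=bundle.tag_cohorts,
                                   tag_tracks=bundle.tag_tracks)
        _, brk = total_objective(traj, matrices, no_oto, rr, 2.0, 0.9)
        for key in ("cpue", "caa", "conventional_tags", "electronic_tags",
                    "priors"):
            assert brk[key][1] == pytest.approx(full[key][1], rel=1e-12)
        assert brk["otolith"] == (0, 0.0)

    def test_beta_prior_alternative(self):
        from mast.config import ReportingPrior

        prior = ReportingPrior(family="beta", alpha=3.0, beta=3.0)
        rates = np.array([0.2, 0.5])
        expected = -np.sum(2 * np.log(rates) + 2 * np.log1p(-rates))
        assert reporting_rate_prior_nll(rates, prior) == pytest.approx(
            expected)
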