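"""ROI statistics: peaks, Bayes factors, SRP extraction and shapes."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import norm

from somabms.roi import (bayes_association_bf, classify_evidence, classify_srp_shape,
                         extract_srp, find_subject_peak, fit_ten_level_glm,
                         jzs_onesample_bf, sphere_mask)


def jzs_double_integration_oracle(values, r=0.707):
    """BF10 by direct numerical integration of both marginal likelihoods.

    H0: x_i ~ N(0, s^2) with Jeffreys prior on s; H1 additionally places a
    Cauchy(0, r) prior on the standardised effect d = mu/s.  Both marginals
    are evaluated by quadrature over (d, log s) — independent of the
    g-mixture formula used by the implementation.
    """
    x = np.asarray(values, float)
    n = x.size
    scale = float(np.sum(norm.logpdf(x, loc=x.mean(), scale=x.std(ddof=0) + 1e-12)))

    def loglik(mu, s):
        return np.sum(norm.logpdf(x, loc=mu, scale=s))

    def m0_integrand(ls):
        s = np.exp(ls)
        return np.exp(loglik(0.0, s) - scale)      # Jeffreys: ds/s -> d(log s)

    m0, _ = quad(m0_integrand, -8, 8, limit=300)

    def m1_inner(d):
        def f(ls):
            s = np.exp(ls)
            return np.exp(loglik(d * s, s) - scale)
        val, _ = quad(f, -8, 8, limit=300)
        cauchy = 1.0 / (np.pi * r * (1.0 + (d / r) ** 2))
        return val * cauchy

    m1, _ = quad(m1_inner, -30, 30, limit=300)
    return m1 / m0


def contingency_mc_oracle(table, a=1.0, n_draws=400_000, seed=0):
    """Monte-Carlo marginal likelihoods for the independent-multinomial test.

    Under association each row's column distribution has its own Dir(a) prior;
    under independence a common column distribution has a Dir(R*a) prior (the
    column margins of the prior matrix).  Both marginals are plain prior
    averages of the multinomial likelihood over prior draws.
    """
    from scipy.special import logsumexp
    rng = np.random.default_rng(seed)
    y = np.asarray(table, float)
    R, C = y.shape
    # m1: each row's likelihood averaged over its own Dirichlet prior draws
    ln1 = np.zeros(n_draws)
    for i in range(R):
        th = rng.dirichlet(np.full(C, a), size=n_draws)      # (n_draws, C)
        ln1 += np.log(th) @ y[i]
    # m0: common column distribution
    th0 = rng.dirichlet(np.full(C, a * R), size=n_draws)
    ln0 = np.log(th0) @ y.sum(axis=0)
    lm1 = logsumexp(ln1) - np.log(n_draws)
    lm0 = logsumexp(ln0) - np.log(n_draws)
    return float(np.exp(lm1 - lm0))


class TestSubjectPeak:
    def test_single_voxel_roi(self, rng):
        lnE = rng.normal(size=(3, 4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[2, 1, 3] = True
        pk = find_subject_peak(lnE, mask, model=1)
        assert pk.index == (2, 1, 3)
        assert 0 < pk.probability < 1

    def test_probabilities_sum_to_one(self, rng):
        lnE = rng.normal(size=(5, 3, 3, 3))
        from scipy.special import logsumexp
        probs = np.exp(lnE - logsumexp(lnE, axis=0))
        assert np.allclose(probs.sum(axis=0), 1.0)

    def test_tie_break_lowest_linear_index(self):
        lnE = np.zeros((2, 2, 2, 2))
        mask = np.ones((2, 2, 2), bool)
        pk = find_subject_peak(lnE, mask, model=0)
        assert pk.index == (0, 0, 0)

    def test_empty_roi_raises(self, rng):
        with pytest.raises(ValueError):
            find_subject_peak(rng.normal(size=(2, 3, 3, 3)),
                              np.zeros((3, 3, 3), bool), 0)


class TestJzs:
    def test_zero_mean_favours_null(self, rng):
        x = rng.normal(size=40)
        x -= x.mean()
        assert jzs_onesample_bf(x) < 1

    def test_matches_double_integration_oracle(self):
        """g-mixture formula agrees with direct (d, log s) quadrature."""
        rng = np.random.default_rng(7)
        fixtures = [rng.normal(loc=m, scale=s, size=n)
                    for m, s, n in [(0.0, 1.0, 12), (0.5, 1.0, 15), (0.3, 2.0, 10),
                                    (-0.8, 0.7, 20), (0.1, 0.2, 8)]]
        for x in fixtures:
            bf = jzs_onesample_bf(x)
            oracle = jzs_double_integration_oracle(x)
            assert bf == pytest.approx(oracle, rel=1e-3)

    def test_matches_pingouin(self, rng):
        """Agreement with an established JZS implementation."""
        pingouin = pytest.importorskip("pingouin")
        from scipy import stats as _st
        for loc in (0.0, 0.4, -0.9):
            x = rng.normal(loc, 1.0, 18)
            t = x.mean() / (x.std(ddof=1) / np.sqrt(x.size))
            ref = float(pingouin.bayesfactor_ttest(t, x.size, paired=True))
            assert jzs_onesample_bf(x) == pytest.approx(ref, rel=1e-6)

    def test_scale_invariance(self, rng):
        x = rng.normal(loc=0.4, size=25)
        assert jzs_onesample_bf(3.7 * x) == pytest.approx(jzs_onesample_bf(x), rel=1e-9)

    def test_monotone_in_effect_size(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        base = (base - base.mean()) / base.std(ddof=1)
        bfs = [jzs_onesample_bf(base + shift) for shift in (0.0, 0.3, 0.6, 1.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_reciprocal_identity(self, rng):
        x = rng.normal(loc=0.3, size=15)
        bf10 = jzs_onesample_bf(x)
        assert bf10 * (1.0 / bf10) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            jzs_onesample_bf([1.0])
        with pytest.raises(ValueError):
            jzs_onesample_bf([2.0, 2.0, 2.0])


class TestAssociation:
    def test_proportional_table_favours_independence(self):
        bf10, bf01 = bayes_association_bf([[50, 50], [50, 50]])
        assert bf01 > 1 and bf10 * bf01 == pytest.approx(1.0, abs=1e-12)

    def test_matches_mc_oracle(self):
        """Closed-form marginals agree with Monte-Carlo prior averaging."""
        fixtures = [[[20, 5], [6, 18]], [[12, 11], [10, 13]], [[40, 2], [3, 45]],
                    [[7, 3], [2, 9]], [[30, 30], [28, 32]]]
        for tbl in fixtures:
            bf10, _ = bayes_association_bf(tbl)
            oracle = contingency_mc_oracle(tbl, seed=1)
            assert bf10 == pytest.approx(oracle, rel=0.05)

    def test_transpose_invariance(self):
        t = np.array([[20, 5], [6, 18]])
        for sampling in ("independent", "joint"):
            b1, _ = bayes_association_bf(t, sampling=sampling)
            b2, _ = bayes_association_bf(t.T, sampling=sampling)
            assert b1 == pytest.approx(b2, rel=1e-12)

    def test_strong_association_detected(self):
        bf10, _ = bayes_association_bf([[45, 5], [4, 46]])
        assert bf10 > 150

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            bayes_association_bf([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            bayes_association_bf([[1.5, 2], [3, 4]])


@pytest.mark.parametrize("bf,expected", [
    (2.0, "negligible"),
    (88.01, "strong"),        # the RT effect's Bayes factor falls in 20-150
    (6114.09, "very strong"),
    (5.0, "positive"),
])
def test_classify_evidence_bands(bf, expected):
    assert classify_evidence(bf) == expected


class TestSrp:
    def test_small_radius_is_centre_voxel(self):
        mask = sphere_mask((5, 5, 5), (2, 2, 2), radius_mm=2.0, voxel_size=3.0)
        assert mask.sum() == 1 and mask[2, 2, 2]

    def test_four_mm_sphere_on_three_mm_grid(self):
        # centre + six face neighbours (3 mm <= 4 mm), edge neighbours excluded
        mask = sphere_mask((5, 5, 5), (2, 2, 2), radius_mm=4.0, voxel_size=3.0)
        assert mask.sum() == 7

    def test_constant_volume_gives_constant_srp(self):
        vols = np.full((10, 6, 6, 6), 2.5)
        out = extract_srp([vols, vols], [(3, 3, 3), (2, 2, 2)])
        assert np.allclose(out["mean"], 2.5)
        assert np.allclose(out["sem"], 0.0)

    def test_shape_classification_of_canonical_profiles(self, rng):
        lv = np.arange(1, 11, dtype=float)
        sem = np.full(10, 0.02)
        profiles = {
            "linear": 0.1 * lv,
            "sigmoid": 1.0 / (1.0 + np.exp(-(lv - 5.5) / 0.8)),
            "inverse_u": np.exp(-((lv - 5.5) ** 2) / 4.0),
            "flat": np.full(10, 0.3),
        }
        for name, y in profiles.items():
            noisy = y + rng.normal(0, 0.02, 10)
            assert classify_srp_shape(noisy, sem) == name


class TestTenLevelGlm:
    @staticmethod
    def _setup():
        from somabms.design import (allocate_trials, assign_cues, build_regressors,
                                    build_trial_table, generate_onsets)
        from somabms.psychometric import PsychometricFit, derive_intensity_grid
        from somabms.synth import SimulationConfig, simulate_behaviour
        fit = PsychometricFit(2.40, 2.05)
        grid = derive_intensity_grid(fit)
        rng = np.random.default_rng(21)
        levels = allocate_trials(seed=rng)[0]
        onsets = generate_onsets(levels.size, 756.0, seed=rng)
        tab = build_trial_table(levels, onsets, grid, assign_cues(levels, seed=rng))
        tab = simulate_behaviour(fit, tab, seed=rng, config=SimulationConfig())
        reg = build_regressors(tab, fit)
        return tab, reg

    def test_linearity_against_single_onset_model(self):
        """With one shared amplitude the ten-level fit equals the onset fit."""
        from somabms.glm import GLMPrior, build_design_matrix, fit_bayesian_glm, hrf_regressor
        tab, reg = self._setup()
        ft = np.arange(378) * 2.0
        onset_course = hrf_regressor(reg.onsets, np.ones_like(reg.onsets), ft)[:, 0]
        y = 0.7 * onset_course          # noise-free, equal amplitude at all levels
        flat = GLMPrior(g=np.inf)
        betas, cols = fit_ten_level_glm(tab, reg, y[None, :], 378, 2.0, prior=flat)
        X1 = build_design_matrix(tab, None, reg, 378, 2.0)
        res1 = fit_bayesian_glm(y, X1, prior=flat)
        ten_fit = np.zeros(378)
        from somabms.glm import hrf_regressor as hr
        t = tab[tab["trial_type"] == "stim"]
        for lv in range(1, 11):
            ons = t.loc[t["level"] == lv, "onset"].to_numpy(float)
            ten_fit += betas[lv - 1, 0] * hr(ons, np.ones_like(ons), ft)[:, 0]
        onset_fit = res1.beta("onset")[0] * onset_course
        assert np.max(np.abs(ten_fit - onset_fit)) < 1e-6

    def test_missing_level_raises(self):
        tab, reg = self._setup()
        tab2 = tab[tab["level"] != 3]
        with pytest.raises(ValueError, match="3"):
            fit_ten_level_glm(tab2, reg, np.zeros((1, 378)), 378, 2.0)
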