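"""ZINB regression: recoding, weights, likelihood, fitting, term tests."""

import warnings

import numpy as np
import pytest
from scipy import stats

from inv17q import zinb
from inv17q.simulate import simulate_zinb_response
from inv17q.zinb import ModelSpec, ZinbParams


def small_dataset(seed=3, n=200, theta=5.0):
    """Fixed-seed dataset with genotype, age and sex covariates."""
    rng = np.random.default_rng(seed)
    age = rng.integers(45, 91, n).astype(float)
    sex = rng.integers(1, 3, n).astype(float)
    dip = rng.binomial(2, 0.35, n)
    X = np.column_stack([np.ones(n), dip == 1, dip == 2, age, sex]).astype(float)
    beta = np.array([1.9, -0.5, -0.55, 0.001, 0.03])
    gamma = np.array([2.5, -0.9, -0.7, -0.027, 0.1])
    y = simulate_zinb_response(X, X, beta, gamma, theta=theta, rng=rng)
    names = ["(Intercept)", "SNP:het", "SNP:hom2", "Age", "Sex"]
    spec = ModelSpec(
        y=y, X=X, Z=X.copy(),
        count_names=names, zero_names=names,
        term_blocks={"SNP": [1, 2], "Age": [3], "Sex": [4]},
    )
    return spec, beta, gamma


def sm_zinb(spec):
    """statsmodels reference model for the same design (NB2, logit inflation)."""
    from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

    return ZeroInflatedNegativeBinomialP(spec.y, spec.X, exog_infl=spec.Z, p=2)


def to_sm_params(params: ZinbParams) -> np.ndarray:
    """[gamma, beta, alpha=1/theta] ordering used by the reference."""
    return np.concatenate([params.gamma, params.beta, [1.0 / params.theta]])


class TestRecodeNonevents:
    def test_small_counts_zeroed(self):
        assert list(zinb.recode_nonevents(np.array([0, 1, 2, 3]))) == [0, 0, 0, 0]

    def test_large_counts_pass_through_unshifted(self):
        assert list(zinb.recode_nonevents(np.array([4, 13]))) == [4, 13]

    def test_zero_threshold_is_identity_on_positives(self):
        y = np.array([0, 1, 5])
        assert list(zinb.recode_nonevents(y, threshold=0)) == [0, 1, 5]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            zinb.recode_nonevents(np.array([-1]))


class TestAgeBinWeights:
    def test_hand_computed_example(self):
        w = zinb.age_bin_weights(np.array([60, 60, 70]))
        assert w == pytest.approx([0.75, 0.75, 1.5])

    def test_single_bin_gives_unit_weights(self):
        assert zinb.age_bin_weights(np.array([55] * 7)) == pytest.approx([1.0] * 7)

    def test_sum_equals_subject_count(self, rng):
        for _ in range(5):
            ages = rng.integers(45, 91, size=rng.integers(1, 200))
            assert zinb.age_bin_weights(ages).sum() == pytest.approx(len(ages))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zinb.age_bin_weights(np.array([]))


class TestLoglik:
    def test_matches_reference_at_fixed_params(self):
        spec, beta, gamma = small_dataset()
        params = ZinbParams(beta=beta * 0.9, gamma=gamma * 1.1, log_theta=0.7)
        mine = zinb.zinb_loglik(params, spec)
        ref = sm_zinb(spec).loglike(to_sm_params(params))
        assert mine == pytest.approx(ref, abs=1e-8)

    def test_zero_inflation_shutdown_reduces_to_nb(self):
        spec, beta, gamma = small_dataset()
        # gamma -> -inf makes pi = 0: weighted NB log-likelihood remains
        params = ZinbParams(beta=beta, gamma=np.array([-40.0, 0, 0, 0, 0]), log_theta=1.0)
        theta = np.exp(1.0)
        mu = np.exp(spec.X @ beta)
        y = spec.y
        from scipy.special import gammaln

        lognb = (
            gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu)) + y * np.log(mu / (theta + mu))
        )
        assert zinb.zinb_loglik(params, spec) == pytest.approx(lognb.sum(), abs=1e-6)

    def test_poisson_limit_at_huge_theta(self):
        # NB -> Poisson as theta -> inf; the residual gap is O(1/theta)
        spec, beta, gamma = small_dataset()
        params = ZinbParams(beta=beta, gamma=np.array([-40.0, 0, 0, 0, 0]), log_theta=np.log(1e10))
        mu = np.exp(spec.X @ beta)
        pois = stats.poisson.logpmf(spec.y, mu).sum()
        assert zinb.zinb_loglik(params, spec) == pytest.approx(pois, abs=1e-6)

    def test_analytic_score_matches_central_differences(self):
        spec, beta, gamma = small_dataset()
        params = ZinbParams(beta=beta * 0.95, gamma=gamma * 0.9, log_theta=0.3)
        g = zinb.zinb_score(params, spec)
        x0 = params.pack()
        num = np.empty_like(x0)
        for i in range(len(x0)):
            h = 1e-6 * max(1.0, abs(x0[i]))
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (
                zinb.zinb_loglik(ZinbParams.unpack(xp, 5, 5), spec)
                - zinb.zinb_loglik(ZinbParams.unpack(xm, 5, 5), spec)
            ) / (2 * h)
        assert np.max(np.abs(g - num) / np.maximum(1.0, np.abs(num))) < 1e-6


class TestFitZinb:
    def test_matches_reference_fit(self):
        spec, _, _ = small_dataset()
        fit = zinb.fit_zinb(spec)
        assert fit.converged
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm_zinb(spec).fit(
                start_params=to_sm_params(fit.params) * 0.95,
                method="bfgs", maxiter=2000, disp=0,
            )
        k = spec.X.shape[1]
        ref_gamma, ref_beta = ref.params[:k], ref.params[k : 2 * k]
        assert np.max(np.abs((fit.params.beta - ref_beta) / ref_beta)) < 1e-4
        assert np.max(np.abs((fit.params.gamma - ref_gamma) / ref_gamma)) < 1e-4
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_loglik_no_worse_than_start(self):
        spec, _, _ = small_dataset(seed=9)
        start = ZinbParams(
            beta=np.array([1.0, 0, 0, 0, 0]), gamma=np.zeros(5), log_theta=0.0
        )
        fit = zinb.fit_zinb(spec, start=start)
        assert fit.loglik >= zinb.zinb_loglik(start, spec)

    def test_single_response_level_not_formed(self):
        spec, _, _ = small_dataset()
        bad = ModelSpec(y=np.zeros_like(spec.y), X=spec.X, Z=spec.Z)
        with pytest.raises(zinb.ModelNotFormedError):
            zinb.fit_zinb(bad)

    def test_singular_design_not_formed(self):
        spec, _, _ = small_dataset()
        X = np.column_stack([spec.X, spec.X[:, 1]])
        bad = ModelSpec(y=spec.y, X=X, Z=spec.Z)
        with pytest.raises(zinb.ModelNotFormedError, match="rank"):
            zinb.fit_zinb(bad)

    def test_weight_scaling_leaves_estimates_unchanged(self):
        spec, _, _ = small_dataset()
        w = zinb.age_bin_weights(spec.X[:, 3])
        s1 = ModelSpec(y=spec.y, X=spec.X, Z=spec.Z, weights=w)
        s2 = ModelSpec(y=spec.y, X=spec.X, Z=spec.Z, weights=3.0 * w)
        f1, f2 = zinb.fit_zinb(s1), zinb.fit_zinb(s2)
        assert f2.loglik == pytest.approx(3.0 * f1.loglik, rel=1e-6)
        assert np.allclose(f1.params.pack(), f2.params.pack(), atol=2e-4)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(101)
        n = 50_000
        age = rng.integers(45, 91, n).astype(float)
        dip = rng.binomial(2, 0.3, n)
        X = np.column_stack([np.ones(n), dip == 1, dip == 2, age]).astype(float)
        beta = np.array([1.98, -0.5, -0.55, 0.001])
        gamma = np.array([3.9, -0.9, -0.7, -0.027])
        y = simulate_zinb_response(X, X, beta, gamma, theta=1e6, rng=rng)
        spec = ModelSpec(y=y, X=X, Z=X.copy())
        fit = zinb.fit_zinb(spec)
        assert abs(fit.params.beta[2] - beta[2]) < 3 * fit.se[2]


class TestTermTests:
    def test_single_df_equals_z_squared(self):
        spec, _, _ = small_dataset()
        fit = zinb.fit_zinb(spec)
        table = zinb.term_tests(fit)
        age = table[table["term"] == "Age"].iloc[0]
        j = 3  # count-part Age column
        assert age["chisq"] == pytest.approx(fit.z[j] ** 2, rel=1e-9)
        assert age["p"] == pytest.approx(fit.p[j], rel=1e-9)

    def test_two_df_matches_explicit_inverse(self):
        spec, _, _ = small_dataset()
        fit = zinb.fit_zinb(spec)
        table = zinb.term_tests(fit)
        snp = table[table["term"] == "SNP"].iloc[0]
        b = fit.params.beta[[1, 2]]
        V = fit.vcov[np.ix_([1, 2], [1, 2])]
        w_expected = float(b @ np.linalg.inv(V) @ b)
        assert snp["df"] == 2
        assert snp["chisq"] == pytest.approx(w_expected, rel=1e-9)

    def test_zero_coefficient_gives_null_result(self):
        spec, _, _ = small_dataset()
        fit = zinb.fit_zinb(spec)
        fit.params.beta[3] = 0.0
        table = zinb.term_tests(fit, terms={"Age": [3]})
        assert table["chisq"].iloc[0] == pytest.approx(0.0)
        assert table["p"].iloc[0] == pytest.approx(1.0)


class TestPruneInteractions:
    @staticmethod
    def _data(seed, n=4000, interaction=0.0):
        """Genotype/age/sex data; ``interaction`` is a per-year SNP x age
        count-part effect, age-centered at 65 so group means stay realistic."""
        rng = np.random.default_rng(seed)
        age = rng.integers(45, 91, n).astype(float)
        sex = rng.integers(1, 3, n).astype(float)
        dip = rng.binomial(2, 0.3, n)
        geno = np.array(["CC", "CT", "TT"])[2 - dip]
        het = (dip == 1).astype(float)
        hom1 = (dip == 0).astype(float)
        snp_main = -0.5 - 65.0 * interaction
        X = np.column_stack([np.ones(n), het, hom1, age, sex, het * age, hom1 * age])
        beta = np.array([1.98, snp_main, snp_main, 0.001, 0.0, interaction, interaction])
        gamma = np.array([3.9, -0.9, -0.7, -0.027, 0.0, 0.0, 0.0])
        y = simulate_zinb_response(X, X, beta, gamma, theta=1e6, rng=rng)
        return geno, age, sex, y

    def test_null_interactions_removed(self):
        geno, age, sex, y = self._data(seed=5)
        fit, kept = zinb.prune_interactions(geno, age, sex, y, threshold=0)
        if not kept:  # expected path under the null
            assert "SNP:CT:Age" not in [n for n in fit.spec.count_names]
        # main effects retained regardless of significance
        assert "Age" in fit.spec.count_names
        assert "Sex" in fit.spec.count_names

    def test_planted_interaction_retained(self):
        geno, age, sex, y = self._data(seed=6, n=20_000, interaction=0.025)
        fit, kept = zinb.prune_interactions(geno, age, sex, y, threshold=0)
        assert kept
        assert any("SNP" in n and "Age" in n for n in fit.spec.count_names)


class TestOverdispersion:
    def test_overdispersed_data_flagged(self):
        rng = np.random.default_rng(11)
        n = 10_000
        X = np.column_stack([np.ones(n), rng.integers(45, 91, n)]).astype(float)
        y = simulate_zinb_response(
            X, X, np.array([1.5, 0.0]), np.array([0.5, 0.0]), theta=0.5, rng=rng
        )
        spec = ModelSpec(y=y, X=X, Z=X.copy())
        flag, p, note = zinb.overdispersion_check(zinb.fit_zinb(spec))
        assert flag and p < 0.05

    def test_poisson_data_not_flagged(self):
        rng = np.random.default_rng(12)
        n = 5_000
        X = np.column_stack([np.ones(n), rng.integers(45, 91, n)]).astype(float)
        y = simulate_zinb_response(
            X, X, np.array([1.5, 0.0]), np.array([0.5, 0.0]), theta=1e8, rng=rng
        )
        spec = ModelSpec(y=y, X=X, Z=X.copy())
        fit = zinb.fit_zinb(spec)
        flag, p, note = zinb.overdispersion_check(fit)
        assert not flag

    def test_wald_z_from_published_dispersion(self):
        # log(theta) 15.48 with SE 35.49 -> z = 0.436, clearly non-significant
        z = 15.476737 / 35.489470
        p = 2 * stats.norm.sf(abs(z))
        assert z == pytest.approx(0.436, abs=5e-4)
        assert p == pytest.approx(0.66277, abs=5e-4)


class TestBonferroni:
    def test_seven_test_menu(self):
        assert zinb.bonferroni([0.004], m=7) == [True]
        assert zinb.bonferroni([0.009], m=7) == [False]

    def test_single_test_uses_raw_level(self):
        assert zinb.bonferroni([0.049], m=1) == [True]
        assert zinb.bonferroni([0.051], m=1) == [False]


class TestBuildDesign:
    def test_reference_is_minor_homozygote_dummies_het_first(self):
        geno = np.array(["TT"] * 60 + ["CT"] * 30 + ["CC"] * 10)
        age = np.full(100, 60.0)
        sex = np.ones(100)
        nci = np.zeros(100, dtype=int)
        nci[:20] = 5
        spec = zinb.build_design(geno, age, sex, nci)
        assert spec.count_names == ["(Intercept)", "SNP:CT", "SNP:TT", "Age", "Sex"]
        assert spec.term_blocks["SNP"] == [1, 2]

    def test_two_classes_allowed_one_rejected(self):
        age = np.full(10, 60.0)
        sex = np.ones(10)
        nci = np.array([0, 5, 0, 5, 0, 5, 0, 5, 0, 5])
        # with only one homozygote class it becomes the reference
        spec = zinb.build_design(np.array(["TT"] * 5 + ["CT"] * 5), age, sex, nci)
        assert "SNP:CT" in spec.count_names
        with pytest.raises(zinb.ModelNotFormedError):
            zinb.build_design(np.array(["TT"] * 10), age, sex, nci)
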