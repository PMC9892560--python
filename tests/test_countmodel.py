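import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichefx import countmodel

from conftest import make_group_counts


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def median_of_ratios_oracle(counts: np.ndarray) -> np.ndarray:
    """Literal median-of-ratios definition, computed row by row."""
    keep = [g for g in range(counts.shape[0]) if np.all(counts[g] > 0)]
    loggeo = [np.exp(np.mean(np.log(counts[g]))) for g in keep]
    sf = []
    for j in range(counts.shape[1]):
        ratios = [counts[g][j] / loggeo[i] for i, g in enumerate(keep)]
        sf.append(np.median(ratios))
    sf = np.array(sf)
    return sf / stats.gmean(sf)


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Naive O(n^2) Benjamini-Hochberg step-up."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return np.clip(adj, 0, 1)


def grid_search_mle(y, X, alpha, offset, lo=-5.0, hi=15.0):
    """Nested-refinement grid search of the NB log-likelihood (<=2 coefs)."""
    p = X.shape[1]
    centers = np.zeros(p)
    width = hi - lo
    centers[:] = (hi + lo) / 2
    for _ in range(12):
        grids = [np.linspace(c - width / 2, c + width / 2, 21) for c in centers]
        best, best_ll = None, -np.inf
        if p == 1:
            for b0 in grids[0]:
                mu = np.exp(X @ [b0] + offset)
                ll = countmodel.nb_loglik(y, mu, alpha)
                if ll > best_ll:
                    best, best_ll = np.array([b0]), ll
        else:
            for b0 in grids[0]:
                for b1 in grids[1]:
                    mu = np.exp(X @ [b0, b1] + offset)
                    ll = countmodel.nb_loglik(y, mu, alpha)
                    if ll > best_ll:
                        best, best_ll = np.array([b0, b1]), ll
        centers = best
        width = width / 5
    return centers / np.log(2)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(
            np.tile([[10], [40], [7]], (1, 4)), columns=list("abcd")
        )
        sf = countmodel.estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_column(self):
        counts = pd.DataFrame({"s1": [10, 100, 30], "s2": [20, 200, 60]})
        sf = countmodel.estimate_size_factors(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_median_of_ratios_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(50, 6)), columns=[f"s{j}" for j in range(6)]
        )
        sf = countmodel.estimate_size_factors(counts)
        assert np.allclose(sf, median_of_ratios_oracle(counts.to_numpy()), atol=1e-12)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 300, size=(80, 5)))
        sf = countmodel.estimate_size_factors(counts)
        assert np.isclose(stats.gmean(sf), 1.0)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    def _design(self, n_per_group=6):
        return pd.DataFrame(
            {"condition": ["a"] * n_per_group + ["b"] * n_per_group}
        )

    def test_poisson_limit(self, rng):
        mu = rng.uniform(50, 500, size=300)
        counts = pd.DataFrame(rng.poisson(mu[:, None], size=(300, 12)))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = countmodel.estimate_dispersions(counts, self._design(), sf)
        assert np.nanmedian(alpha) <= 0.01

    def test_nb_alpha_recovery(self, rng):
        alpha_true = 0.5
        mu = rng.uniform(50, 800, size=400)
        shape = 1 / alpha_true
        lam = rng.gamma(shape, (mu / shape)[:, None], size=(400, 12))
        counts = pd.DataFrame(rng.poisson(lam))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = countmodel.estimate_dispersions(counts, self._design(), sf)
        assert 0.3 <= np.nanmedian(alpha) <= 0.8

    def test_constant_gene_at_floor(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(60, 12)))
        counts.iloc[0] = 42  # zero variance everywhere
        sf = pd.Series(1.0, index=counts.columns)
        alpha = countmodel.estimate_dispersions(counts, self._design(), sf)
        assert alpha.iloc[0] == countmodel.DISPERSION_FLOOR

    def test_all_zero_gene_flagged_nan(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(60, 12)))
        counts.iloc[1] = 0
        sf = pd.Series(1.0, index=counts.columns)
        alpha = countmodel.estimate_dispersions(counts, self._design(), sf)
        assert np.isnan(alpha.iloc[1])


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------

class TestNbGlm:
    def test_intercept_only_closed_form(self):
        counts = pd.DataFrame([[64] * 8], index=["g"], columns=[f"s{j}" for j in range(8)])
        X = pd.DataFrame({"intercept": np.ones(8)}, index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        fit = countmodel.fit_nb_glm(counts, X, sf, disp)
        assert np.isclose(fit.coef[0, 0], 6.0, atol=1e-6)

    def test_saturated_design_equals_group_mean_contrasts(self):
        counts, design = make_group_counts((100, 200, 150, 600), reps=2)
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "time": (design["time"] == "T21").astype(float).to_numpy(),
                "age": (design["age"] == "aged").astype(float).to_numpy(),
                "age:time": (
                    (design["age"] == "aged") & (design["time"] == "T21")
                ).astype(float).to_numpy(),
            },
            index=design["sample_id"],
        )
        sf = pd.Series(1.0, index=X.index)
        disp = pd.Series(0.05, index=counts.index)
        fit = countmodel.fit_nb_glm(counts, X, sf, disp)
        beta = dict(zip(fit.coef_names, fit.coef[0]))
        assert np.isclose(beta["age"], np.log2(1.5), atol=1e-5)
        assert np.isclose(beta["time"], 1.0, atol=1e-5)
        assert np.isclose(beta["age:time"], 1.0, atol=1e-5)

    def test_matches_grid_search_oracle(self, rng):
        y = rng.negative_binomial(5, 0.3, size=8).astype(float)
        X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        offset = np.log(rng.uniform(0.8, 1.2, size=8))
        alpha = 0.2
        counts = pd.DataFrame([y], index=["g"], columns=[f"s{j}" for j in range(8)])
        Xd = pd.DataFrame(X, index=counts.columns, columns=["intercept", "grp"])
        sf = pd.Series(np.exp(offset), index=counts.columns)
        disp = pd.Series(alpha, index=counts.index)
        fit = countmodel.fit_nb_glm(counts, Xd, sf, disp)
        oracle = grid_search_mle(y, X, alpha, offset)
        assert np.allclose(fit.coef[0], oracle, atol=1e-4)

    def test_collinear_design_rejected(self):
        counts = pd.DataFrame([[1, 2, 3, 4]], index=["g"], columns=list("abcd"))
        X = pd.DataFrame(
            {"intercept": [1.0] * 4, "x": [0, 1, 0, 1], "y": [0, 2, 0, 2]},
            index=counts.columns,
        )
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match="collinear.*y"):
            countmodel.fit_nb_glm(counts, X, sf, pd.Series(0.1, index=counts.index))


# ---------------------------------------------------------------------------
# shrinkage / s-values
# ---------------------------------------------------------------------------

class TestShrinkage:
    def test_conjugate_closed_form(self):
        m, s, lfsr = countmodel.shrink_with_prior(
            np.array([2.0]), np.array([1.0]), prior_sd=1.0
        )
        assert np.isclose(m[0], 1.0)
        assert np.isclose(s[0], np.sqrt(0.5))
        assert np.isclose(lfsr[0], stats.norm.sf(np.sqrt(2)), atol=1e-6)

    def test_flat_prior_limit_recovers_mle(self, rng):
        beta = rng.normal(0, 2, size=50)
        se = rng.uniform(0.2, 1.0, size=50)
        m, _, _ = countmodel.shrink_with_prior(beta, se, prior_sd=1e6)
        assert np.allclose(m, beta, atol=1e-6)

    def test_zero_estimate_gives_half_lfsr(self):
        _, _, lfsr = countmodel.shrink_with_prior(
            np.array([0.0]), np.array([0.5]), prior_sd=1.0
        )
        assert lfsr[0] == 0.5

    def test_shrinkage_never_exceeds_mle(self, rng):
        beta = rng.normal(0, 3, size=200)
        se = rng.uniform(0.1, 2.0, size=200)
        for tau in (0.1, 1.0, 5.0):
            m, _, _ = countmodel.shrink_with_prior(beta, se, tau)
            assert np.all(np.abs(m) <= np.abs(beta) + 1e-12)

    def test_svalues_in_unit_interval_and_monotone(self, rng):
        lfsr = rng.uniform(0, 0.6, size=500)
        s = countmodel.svalues_from_lfsr(lfsr)
        assert np.all((s >= 0) & (s <= 1))
        order = np.argsort(lfsr)
        assert np.all(np.diff(s[order]) >= -1e-12)
        assert np.all(s <= lfsr + 1e-12)  # running mean of smaller values

    def test_prior_scale_recovered_on_synthetic_mixture(self, rng):
        tau = 1.5
        beta_true = rng.normal(0, tau, size=2000)
        se = rng.uniform(0.1, 0.5, size=2000)
        beta_hat = beta_true + rng.normal(0, se)
        est = countmodel.estimate_prior_scale(beta_hat, se)
        assert 1.2 <= est <= 1.8


# ---------------------------------------------------------------------------
# Wald / BH
# ---------------------------------------------------------------------------

class TestWaldBH:
    def _fit(self, beta, se):
        n = len(beta)
        return countmodel.NBFit(
            gene_ids=pd.Index([f"g{i}" for i in range(n)]),
            coef_names=["effect"],
            coef=np.asarray(beta, dtype=float).reshape(-1, 1),
            se=np.asarray(se, dtype=float).reshape(-1, 1),
            dispersion=np.full(n, 0.1),
            converged=np.ones(n, dtype=bool),
            loglik=np.zeros(n),
        )

    def test_zero_effect_p_one(self):
        out = countmodel.wald_test(self._fit([0.0], [0.5]), "effect")
        assert np.isclose(out["pvalue"].iloc[0], 1.0)

    def test_z_1_96_p_05(self):
        out = countmodel.wald_test(self._fit([1.96], [1.0]), "effect")
        assert np.isclose(out["pvalue"].iloc[0], 0.05, atol=1e-3)

    def test_bh_equals_stepup_oracle(self, rng):
        for _ in range(5):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 200)))
            assert np.allclose(countmodel.bh_adjust(p), bh_stepup_oracle(p))

    def test_bh_handles_nan(self):
        p = np.array([0.01, np.nan, 0.5])
        adj = countmodel.bh_adjust(p)
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], bh_stepup_oracle(np.array([0.01, 0.5])))
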