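"""Negative-binomial count modelling shared by every differential stage.

The model for a gene (or peak, or peak/background pair) is

    K_gj ~ NB(mean = s_j * q_gj,  dispersion = alpha_g)
    log q_gj = x_j' beta_g

with per-sample size factors ``s_j`` entering as offsets and a gene-wise
dispersion ``alpha_g`` (variance = mu + alpha * mu^2) held fixed during GLM
fitting (two-stage estimation).  Coefficients are reported in log2 units —
the natural-log internals of the GLM are converted at the boundary.

Moderated effects follow the empirical-Bayes recipe of apeglm-style
shrinkage with a zero-centred normal prior: the prior scale is estimated by
marginal maximum likelihood across genes, the moderated LFC is the posterior
mean, the local false-sign rate (lfsr) is the posterior probability that the
reported sign is wrong, and the s-value of a gene is the running mean of
lfsr over all genes at least as confidently signed.  Exact numerical
agreement with apeglm/ashr is not a goal; the qualitative semantics
(|moderated| <= |MLE|, s-values in [0,1] monotone in lfsr rank) are the
contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

logger = logging.getLogger("nichefx.countmodel")

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8
MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8
DEFAULT_PRIOR_SCALE = 1.0  # log2; used when too few genes to estimate
MIN_GENES_FOR_PRIOR = 50


@dataclass
class NBFit:
    """Per-gene NB GLM fits: coefficients (log2), SEs, dispersion, status."""

    gene_ids: pd.Index
    coef_names: list[str]
    coef: np.ndarray          # genes x p, log2
    se: np.ndarray            # genes x p, log2
    dispersion: np.ndarray    # genes
    converged: np.ndarray     # genes, bool
    loglik: np.ndarray        # genes
    design_matrix: pd.DataFrame = field(repr=False, default=None)

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coef, index=self.gene_ids, columns=self.coef_names)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Falls back to total-count scaling (with a logged warning) when no gene is
    expressed in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    all_pos = np.all(arr > 0, axis=1)
    if all_pos.any():
        loggeo = np.mean(np.log(arr[all_pos]), axis=1)
        ratios = arr[all_pos] / np.exp(loggeo)[:, None]
        logsf = np.log(np.median(ratios, axis=0))
    else:
        logger.warning(
            "no gene with nonzero counts in all samples; "
            "falling back to total-count size factors"
        )
        totals = arr.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total counts: size factors undefined")
        logsf = np.log(totals)
    logsf = logsf - np.mean(logsf)  # geometric mean 1
    return pd.Series(np.exp(logsf), index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series,
    trend_a0: float = 0.05,
    trend_a1: float = 5.0,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene dispersion: method-of-moments shrunk toward a mean trend.

    Samples are grouped by the unique rows of ``design`` (the design cells);
    a pooled within-cell moment estimator of alpha (Var = mu + alpha mu^2 on
    the normalized scale) is shrunk toward a fitted 1/mu trend
    (alpha = a0 + a1 / mu) by geometric averaging in log space.  All-zero
    genes get NaN and are excluded downstream.
    """
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    cells = design.astype(str).agg("|".join, axis=1).to_numpy()
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    resid_df = 0
    for cell in np.unique(cells):
        idx = cells == cell
        n_c = int(idx.sum())
        if n_c < 2:
            continue
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += (var - mu) * (n_c - 1)
        den += mu**2 * (n_c - 1)
        resid_df += n_c - 1
    if resid_df < 2:
        raise ValueError("fewer than 2 residual degrees of freedom for dispersion")
    mean_norm = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(den > 0, num / den, np.nan)
    mom = np.clip(mom, 0.0, 50.0)
    # fit the trend alpha = a0 + a1/mu on genes with informative estimates
    ok = (mean_norm > 0) & np.isfinite(mom) & (mom > 0)
    a0, a1 = trend_a0, trend_a1
    if ok.sum() >= 20:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mean_norm[ok]])
        coef, *_ = np.linalg.lstsq(X, mom[ok], rcond=None)
        a0 = float(np.clip(coef[0], 1e-6, 10.0))
        a1 = float(np.clip(coef[1], 0.0, 1e4))
    with np.errstate(divide="ignore"):
        trend = np.where(mean_norm > 0, a0 + a1 / np.maximum(mean_norm, 1e-12), np.nan)
    trend = np.clip(trend, DISPERSION_FLOOR, 50.0)
    alpha = np.clip(
        shrink_weight * trend + (1.0 - shrink_weight) * mom, DISPERSION_FLOOR, 50.0
    )
    # degenerate genes with zero within-cell variance everywhere: floor
    alpha[_pooled_zero_variance(norm, cells)] = DISPERSION_FLOOR
    alpha[mean_norm <= 0] = np.nan  # all-zero genes: undefined, flagged
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

def _pooled_zero_variance(norm: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Genes whose counts are constant within every design cell."""
    flat = np.ones(norm.shape[0], dtype=bool)
    for cell in np.unique(cells):
        idx = cells == cell
        if idx.sum() < 2:
            continue
        sub = norm[:, idx]
        flat &= np.all(sub == sub[:, [0]], axis=1)
    return flat


def fit_nb_glm(
    counts: pd.DataFrame,
    design_matrix: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
) -> NBFit:
    """Fit one NB GLM (log link, size-factor offsets) per gene.

    ``design_matrix`` is samples x coefficients (including the intercept) and
    must be full rank — collinear columns are named in the error.  Coefficients
    and SEs are returned in log2.  Non-converged genes keep their last iterate
    and are flagged (they are excluded from shrinkage downstream).
    """
    X = design_matrix.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(design_matrix)
        raise ValueError(f"design matrix not full rank; collinear columns: {bad}")
    offset = np.log(size_factors.loc[design_matrix.index].to_numpy(dtype=float))
    n_genes = counts.shape[0]
    p = X.shape[1]
    coef = np.full((n_genes, p), np.nan)
    se = np.full((n_genes, p), np.nan)
    conv = np.zeros(n_genes, dtype=bool)
    llf = np.full(n_genes, np.nan)
    alpha_all = dispersions.loc[counts.index].to_numpy(dtype=float)
    y_all = counts.loc[:, design_matrix.index].to_numpy(dtype=float)
    for g in range(n_genes):
        alpha = alpha_all[g]
        if not np.isfinite(alpha):
            continue  # flagged gene (e.g. all-zero): left NaN / unconverged
        y = y_all[g]
        fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=fam, offset=offset).fit(
                    maxiter=MAX_IRLS_ITER, tol=IRLS_TOL
                )
            except Exception:
                continue
        coef[g] = res.params / LN2
        se[g] = res.bse / LN2
        conv[g] = bool(getattr(res, "converged", True)) and np.all(np.isfinite(res.bse))
        llf[g] = res.llf
    n_bad = int((~conv).sum())
    if n_bad:
        logger.info("fit_nb_glm: %d/%d genes flagged unconverged/degenerate", n_bad, n_genes)
    return NBFit(
        gene_ids=counts.index,
        coef_names=list(design_matrix.columns),
        coef=coef,
        se=se,
        dispersion=alpha_all,
        converged=conv,
        loglik=llf,
        design_matrix=design_matrix,
    )


def _collinear_columns(design_matrix: pd.DataFrame) -> list[str]:
    X = design_matrix.to_numpy(dtype=float)
    bad = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            bad.append(design_matrix.columns[j])
        else:
            keep.append(j)
    return bad


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (used by the grid-search oracles in the tests too)."""
    r = 1.0 / alpha
    return float(
        np.sum(
            stats.nbinom.logpmf(y, r, r / (r + np.maximum(mu, 1e-300)))
        )
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation and s-values
# ---------------------------------------------------------------------------

def shrink_with_prior(
    beta: np.ndarray, se: np.ndarray, prior_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conjugate normal-normal posterior for beta_hat ~ N(beta, se^2), beta ~ N(0, tau^2).

    Returns (posterior mean, posterior sd, lfsr).  As prior_sd -> inf the
    posterior mean tends to the MLE.
    """
    tau2 = prior_sd**2
    w = tau2 / (tau2 + se**2)
    post_mean = w * beta
    post_sd = np.sqrt(w) * se
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(post_sd > 0, np.abs(post_mean) / post_sd, np.inf)
    lfsr = stats.norm.sf(z)  # P(sign wrong) under the symmetric posterior
    lfsr = np.where(post_sd > 0, lfsr, 0.0)
    lfsr = np.where(np.abs(post_mean) > 0, lfsr, 0.5)
    return post_mean, post_sd, lfsr


def estimate_prior_scale(beta: np.ndarray, se: np.ndarray) -> float:
    """Marginal-ML estimate of the zero-centred normal prior scale.

    Under the prior, beta_hat_i ~ N(0, se_i^2 + tau^2); tau maximizes the
    marginal likelihood.  Falls back to a fixed default with a warning when
    fewer than MIN_GENES_FOR_PRIOR genes are available.
    """
    ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    if ok.sum() < MIN_GENES_FOR_PRIOR:
        logger.warning(
            "only %d genes for prior-scale estimation (<%d); using default scale %.2f",
            ok.sum(), MIN_GENES_FOR_PRIOR, DEFAULT_PRIOR_SCALE,
        )
        return DEFAULT_PRIOR_SCALE
    b, s = beta[ok], se[ok]

    def neg_marginal(log_tau: float) -> float:
        v = s**2 + np.exp(2 * log_tau)
        return 0.5 * np.sum(np.log(v) + b**2 / v)

    res = optimize.minimize_scalar(
        neg_marginal, bounds=(np.log(1e-3), np.log(100.0)), method="bounded"
    )
    return float(np.exp(res.x))


def svalues_from_lfsr(lfsr: np.ndarray) -> np.ndarray:
    """s-value: mean lfsr over all genes with lfsr <= the gene's own lfsr."""
    order = np.argsort(lfsr, kind="stable")
    sorted_lfsr = lfsr[order]
    cummean = np.cumsum(sorted_lfsr) / np.arange(1, lfsr.size + 1)
    # ties share the cumulative mean at the last tied position
    cummean = (
        pd.Series(cummean).groupby(sorted_lfsr, sort=False).transform("max").to_numpy()
    )
    out = np.empty_like(lfsr)
    out[order] = cummean
    return np.clip(out, 0.0, 1.0)


def moderate_effects(fit: NBFit, contrast: str) -> pd.DataFrame:
    """Moderated LFCs, lfsr, s-values and Wald/BH stats for one coefficient.

    Only converged fits contribute; non-converged genes carry NaN statistics.
    Output columns: lfc_mle, lfc_moderated, se, posterior_sd, lfsr, svalue,
    pvalue, padj (all LFC units log2).
    """
    j = fit.coef_names.index(contrast)
    beta = fit.coef[:, j].copy()
    se = fit.se[:, j].copy()
    usable = fit.converged & np.isfinite(beta) & np.isfinite(se) & (se > 0)
    prior_sd = estimate_prior_scale(beta[usable], se[usable])
    post_mean = np.full_like(beta, np.nan)
    post_sd = np.full_like(beta, np.nan)
    lfsr = np.full_like(beta, np.nan)
    pm, ps, lf = shrink_with_prior(beta[usable], se[usable], prior_sd)
    post_mean[usable], post_sd[usable], lfsr[usable] = pm, ps, lf
    sval = np.full_like(beta, np.nan)
    sval[usable] = svalues_from_lfsr(lf)
    pval = np.full_like(beta, np.nan)
    pval[usable] = 2.0 * stats.norm.sf(np.abs(beta[usable] / se[usable]))
    padj = np.full_like(beta, np.nan)
    padj[usable] = bh_adjust(pval[usable])
    return pd.DataFrame(
        {
            "lfc_mle": beta,
            "lfc_moderated": post_mean,
            "se": se,
            "posterior_sd": post_sd,
            "lfsr": lfsr,
            "svalue": sval,
            "pvalue": pval,
            "padj": padj,
        },
        index=fit.gene_ids,
    )


# ---------------------------------------------------------------------------
# Wald tests and BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-aware)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(ranked, 0.0, 1.0)
    out[ok] = adj
    return out


def wald_test(fit: NBFit, contrast: str) -> pd.DataFrame:
    """Two-sided normal Wald p per gene for one coefficient, plus BH padj."""
    j = fit.coef_names.index(contrast)
    beta, se = fit.coef[:, j], fit.se[:, j]
    ok = fit.converged & np.isfinite(beta) & np.isfinite(se) & (se > 0)
    p = np.full(beta.shape, np.nan)
    p[ok] = 2.0 * stats.norm.sf(np.abs(beta[ok] / se[ok]))
    return pd.DataFrame(
        {"pvalue": p, "padj": bh_adjust(p)}, index=fit.gene_ids
    )


# ---------------------------------------------------------------------------
# stacked two-layer fits (exon/intron, peak/background)
# ---------------------------------------------------------------------------

def fit_stacked_interaction(
    counts_base: pd.DataFrame,
    counts_alt: pd.DataFrame,
    design_matrix: pd.DataFrame,
    base_label: str = "base",
    alt_label: str = "alt",
) -> NBFit:
    """Fit NB GLMs on two stacked count layers with layer x condition interactions.

    Rows of both frames must share an index (genes/peaks); columns are the same
    samples.  The stacked design is [X | X * 1(alt)]: coefficients of the first
    block are condition effects on the base layer, those of the second block
    (named ``{alt_label}:{col}``) are the layer-differential effects — the
    deconvolved component of interest.  Size factors are estimated separately
    per layer (median-of-ratios within each layer), absorbing global capture
    differences between layers; dispersions come from the stacked matrix.
    """
    if not counts_base.index.equals(counts_alt.index):
        raise ValueError("base and alt layers must share the same row index")
    if list(counts_base.columns) != list(counts_alt.columns):
        raise ValueError("base and alt layers must share the same samples")
    sf_base = estimate_size_factors(counts_base)
    sf_alt = estimate_size_factors(counts_alt)
    samples = list(counts_base.columns)
    stacked = pd.concat(
        [
            counts_base.set_axis([f"{s}__{base_label}" for s in samples], axis=1),
            counts_alt.set_axis([f"{s}__{alt_label}" for s in samples], axis=1),
        ],
        axis=1,
    )
    X = design_matrix.loc[samples]
    block_base = X.set_axis([f"{s}__{base_label}" for s in samples], axis=0)
    block_alt = X.set_axis([f"{s}__{alt_label}" for s in samples], axis=0)
    zeros = block_base * 0.0
    top = pd.concat([block_base, zeros.set_axis(block_base.index)], axis=1)
    bottom = pd.concat([block_alt, block_alt.set_axis(block_alt.index)], axis=1)
    names = list(X.columns) + [f"{alt_label}:{c}" for c in X.columns]
    stacked_X = pd.concat([top, bottom])
    stacked_X.columns = names
    sf = pd.concat(
        [
            sf_base.set_axis([f"{s}__{base_label}" for s in samples]),
            sf_alt.set_axis([f"{s}__{alt_label}" for s in samples]),
        ]
    )
    layer_design = pd.DataFrame(
        {
            "cell": list(design_matrix.loc[samples].astype(str).agg("|".join, axis=1)) * 2,
            "layer": [base_label] * len(samples) + [alt_label] * len(samples),
        },
        index=stacked_X.index,
    )
    disp = estimate_dispersions(stacked[stacked_X.index], layer_design, sf)
    return fit_nb_glm(stacked[stacked_X.index], stacked_X, sf, disp)
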