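"""Negative-binomial two-group differential expression (Wald test).

The engine follows the standard bulk RNA-seq contract:

* per-sample size factors by the median-of-ratios rule,
* per-unit dispersion ``alpha`` in the NB variance model
  ``Var(K) = mu + alpha mu^2``, estimated by method of moments on normalized
  counts pooled within groups and (by default) shrunk toward a fitted
  mean-dispersion trend ``alpha(mu) = a0 + a1 / mu`` -- with a handful of
  replicates the gene-wise moment estimate is far too noisy to use raw,
* a two-sided Wald test on the log ratio of group mean normalized counts,
  with the standard error from the NB Fisher information
  ``I_g = sum_j mu_gj / (1 + alpha mu_gj)`` (delta method on the log scale),
* Benjamini-Hochberg adjustment over all tested units, and a DEG call at
  ``padj < alpha`` with no additional fold-change threshold.

A pseudocount of 0.5 (normalized-count units) enters only when a group mean
is exactly zero; for non-degenerate genes the p-value is untouched by it.

Two front ends share the same core: :class:`NegativeBinomialDE` contrasts two
sample groups over genes, and :func:`copy_contrast` contrasts the A copy
against the D copy of each homoeolog pair over the same samples (the two
copies' count vectors act as the two "groups"; the 10% transcript-length
filter upstream justifies skipping length normalization).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError, EstimationError, NormalizationError

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0


# ---------------------------------------------------------------------------
# normalization


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    ``factor_s = median over genes g (with nonzero geometric mean) of
    count_{g,s} / geometric_mean_g(count)``.  Only factor ratios are
    identifiable; the factors are reported exactly as this formula returns
    them (no rescaling).
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; size factors undefined"
        )
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion


def _moment_dispersions(
    groups_counts: list[np.ndarray], groups_sf: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Gene-wise method-of-moments dispersion from >= 2 groups of normalized
    counts (units x samples arrays per group).

    Returns (alpha_hat, overall normalized mean, residual df).  ``alpha_hat``
    solves pooled-within-group ``E[s^2] = mean_term + alpha * meansq_term``.
    """
    df = sum(k.shape[1] - 1 for k in groups_counts)
    if df <= 0:
        raise EstimationError("dispersion estimation needs replication (>= 2 per group)")
    n_units = groups_counts[0].shape[0]
    ss = np.zeros(n_units)
    mean_term = np.zeros(n_units)
    meansq_term = np.zeros(n_units)
    total = np.zeros(n_units)
    n_samples = 0
    for k, sf in zip(groups_counts, groups_sf):
        y = k / sf[None, :]
        n_g = y.shape[1]
        m = y.mean(axis=1)
        ss += ((y - m[:, None]) ** 2).sum(axis=1)
        inv_s = np.mean(1.0 / sf)
        mean_term += (n_g - 1) * m * inv_s
        meansq_term += (n_g - 1) * m**2
        total += y.sum(axis=1)
        n_samples += n_g
    v = ss / df
    mean_term /= df
    meansq_term /= df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - mean_term) / meansq_term
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.clip(alpha, 0.0, DISPERSION_CEIL)
    return alpha, total / n_samples, df


def _fit_trend(alpha_hat: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha(mu) = a0 + a1/mu (coefficients clipped to be
    non-negative), evaluated at every unit's mean.  Falls back to the median
    moment estimate when the fit is degenerate."""
    ok = (mu > 0) & np.isfinite(alpha_hat)
    if ok.sum() < 10:
        level = float(np.median(alpha_hat[ok])) if ok.any() else 0.0
        return np.full_like(alpha_hat, max(level, DISPERSION_FLOOR))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_hat[ok], rcond=None)
    coef = np.clip(coef, 0.0, None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.nan)
    trend = np.where(np.isfinite(trend), trend, np.nanmedian(alpha_hat[ok]))
    return np.clip(trend, DISPERSION_FLOOR, DISPERSION_CEIL)


def estimate_dispersions(
    groups_counts: list[np.ndarray],
    groups_sf: list[np.ndarray],
    shrink: bool = True,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Final per-unit dispersions: moment estimates, optionally shrunk toward
    the fitted mean-dispersion trend with weight df / (df + prior_df)."""
    alpha_hat, mu, df = _moment_dispersions(groups_counts, groups_sf)
    if not shrink:
        return np.clip(alpha_hat, DISPERSION_FLOOR, DISPERSION_CEIL)
    trend = _fit_trend(alpha_hat, mu)
    w = df / (df + prior_df)
    final = w * alpha_hat + (1.0 - w) * trend
    return np.clip(final, DISPERSION_FLOOR, DISPERSION_CEIL)


# ---------------------------------------------------------------------------
# Wald core


def _wald_two_group(
    k1: np.ndarray,
    k2: np.ndarray,
    sf1: np.ndarray,
    sf2: np.ndarray,
    dispersion: np.ndarray,
) -> pd.DataFrame:
    """Vectorized two-group NB Wald test.

    ``k1``/``k2`` are units x samples count arrays for group 1 and group 2;
    the log2 fold change is group2 over group1.
    """
    q1 = (k1 / sf1[None, :]).mean(axis=1)
    q2 = (k2 / sf2[None, :]).mean(axis=1)

    # pseudocount only where a group mean is exactly zero
    eps1 = 0.5 / sf1.mean()
    eps2 = 0.5 / sf2.mean()
    degenerate = (q1 == 0) | (q2 == 0)
    q1w = np.where(degenerate, q1 + eps1, q1)
    q2w = np.where(degenerate, q2 + eps2, q2)

    mu1 = q1w[:, None] * sf1[None, :]
    mu2 = q2w[:, None] * sf2[None, :]
    info1 = (mu1 / (1.0 + dispersion[:, None] * mu1)).sum(axis=1)
    info2 = (mu2 / (1.0 + dispersion[:, None] * mu2)).sum(axis=1)
    var_ln = 1.0 / info1 + 1.0 / info2

    lfc = np.log2(q2w / q1w)
    se = np.sqrt(var_ln) / LN2
    z = np.where(se > 0, lfc / se, 0.0)
    both_zero = (q1 == 0) & (q2 == 0)
    z = np.where(both_zero, 0.0, z)
    lfc = np.where(both_zero, 0.0, lfc)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = (np.concatenate([k1 / sf1[None, :], k2 / sf2[None, :]], axis=1)).mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": z,
            "pvalue": np.clip(pvalue, 0.0, 1.0),
        }
    )


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ContractError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class NegativeBinomialDE(BaseEstimator):
    """Two-group NB differential expression over genes, sklearn-style.

    Parameters
    ----------
    alpha : float
        Significance threshold on the BH-adjusted p-value for DEG calls.
    shrink_dispersion : bool
        Shrink gene-wise moment dispersions toward the fitted trend.
    prior_df : float
        Strength of the trend prior (pseudo-degrees of freedom).

    Attributes (after ``fit``)
    --------------------------
    size_factors_ : pd.Series
        Per-sample median-of-ratios factors (over the fitted columns).
    dispersions_ : pd.Series
        Final per-gene dispersion.
    results_ : pd.DataFrame
        baseMean, log2FoldChange (group2/group1), lfcSE, stat, pvalue, padj.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        shrink_dispersion: bool = True,
        prior_df: float = 10.0,
    ):
        self.alpha = alpha
        self.shrink_dispersion = shrink_dispersion
        self.prior_df = prior_df

    def fit(
        self,
        counts: pd.DataFrame,
        groups: pd.Series,
        contrast: tuple[str, str],
        size_factors: pd.Series | None = None,
    ) -> "NegativeBinomialDE":
        """Test ``contrast = (group1, group2)``; log2FC is group2 over group1.

        ``groups`` labels each count column; columns with other labels are
        ignored.  ``size_factors`` may be supplied (e.g. computed once on the
        full experiment); otherwise they are estimated from the contrast
        columns.
        """
        g1, g2 = contrast
        groups = pd.Series(groups)
        cols1 = [c for c in counts.columns if groups.get(c) == g1]
        cols2 = [c for c in counts.columns if groups.get(c) == g2]
        if not cols1 or not cols2:
            raise ContractError(f"contrast groups {contrast} not both present/non-empty")
        if set(cols1) & set(cols2):
            raise ContractError("contrast groups must be disjoint")
        sub = counts[cols1 + cols2]
        if size_factors is None:
            size_factors = estimate_size_factors(sub)
        self.size_factors_ = size_factors.loc[sub.columns]
        sf1 = size_factors.loc[cols1].to_numpy(dtype=float)
        sf2 = size_factors.loc[cols2].to_numpy(dtype=float)
        k1 = counts[cols1].to_numpy(dtype=float)
        k2 = counts[cols2].to_numpy(dtype=float)
        disp = estimate_dispersions(
            [k1, k2], [sf1, sf2], shrink=self.shrink_dispersion, prior_df=self.prior_df
        )
        self.dispersions_ = pd.Series(disp, index=counts.index, name="dispersion")
        res = _wald_two_group(k1, k2, sf1, sf2, disp)
        res.index = counts.index
        res["padj"] = bh_adjust(res["pvalue"].to_numpy())
        self.results_ = res
        self.contrast_ = contrast
        return self

    def call_degs(self, alpha: float | None = None) -> pd.DataFrame:
        """DEGs at ``padj < alpha`` with direction (up/down in group2 vs
        group1); no fold-change threshold."""
        alpha = self.alpha if alpha is None else alpha
        res = self.results_
        hits = res[res["padj"] < alpha].copy()
        hits["direction"] = np.where(hits["log2FoldChange"] > 0, "up", "down")
        return hits


def wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    group_column: str = "genotype",
    size_factors: pd.Series | None = None,
    alpha: float = 0.05,
    shrink_dispersion: bool = True,
) -> pd.DataFrame:
    """Functional wrapper over :class:`NegativeBinomialDE` keyed on a design
    sheet column."""
    model = NegativeBinomialDE(alpha=alpha, shrink_dispersion=shrink_dispersion)
    model.fit(counts, design[group_column], contrast, size_factors=size_factors)
    return model.results_


def call_degs(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """DEG call on a finished results table: padj < alpha, direction by the
    sign of the log2 fold change."""
    hits = results[results["padj"] < alpha].copy()
    hits["direction"] = np.where(hits["log2FoldChange"] > 0, "up", "down")
    return hits


# ---------------------------------------------------------------------------
# homoeolog copy contrast


def copy_contrast(
    counts: pd.DataFrame,
    pairs: pd.DataFrame,
    samples: list[str],
    size_factors: pd.Series,
    shrink_dispersion: bool = True,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """A-copy vs D-copy Wald test within one sample group.

    For every pair the D-copy counts over ``samples`` form group 1 and the
    A-copy counts form group 2, both normalized with those samples' size
    factors, so ``log2FoldChange > 0`` means A > D.  BH adjustment is applied
    across the analyzed pairs of this contrast.
    """
    if len(samples) < 2:
        raise ContractError("copy contrast needs >= 2 samples")
    missing = [g for g in pd.concat([pairs["a_gene"], pairs["d_gene"]]) if g not in counts.index]
    if missing:
        raise ContractError(f"pair genes missing from count matrix: {missing[:3]}")
    sf = size_factors.loc[samples].to_numpy(dtype=float)
    ka = counts.loc[pairs["a_gene"], samples].to_numpy(dtype=float)
    kd = counts.loc[pairs["d_gene"], samples].to_numpy(dtype=float)
    disp = estimate_dispersions([kd, ka], [sf, sf], shrink=shrink_dispersion, prior_df=prior_df)
    res = _wald_two_group(kd, ka, sf, sf, disp)
    index = pairs["pair_id"] if "pair_id" in pairs.columns else pairs.index
    res.index = pd.Index(index, name="pair_id")
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res
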