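"""Negative-binomial differential expression for digital count data.

Counts y[g,i] per feature g and library i are modelled NB(mu_gi, phi):
Var = mu + phi mu^2, with a common dispersion phi shared by all features
and optional tagwise shrinkage.  Libraries are normalised by
trimmed-mean-of-M-values (TMM) factors, equalised to a geometric-mean
pseudo-library, and each feature is tested with a conditional exact test:
conditioning the group-1 sum on the two-group total (possible because the
sum of n iid NB(mu, phi) variables is NB(n mu, phi/n) at equal effective
library sizes) yields an exact two-sided p-value by doubling the smaller
tail.  Features are ranked by an empirical-Bayes log posterior odds of
differential expression (the B statistic) computed on log-CPM values with
moderated variances, and called at B >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .smallrna_quant import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DispersionModel",
    "norm_factors",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersion",
    "exact_test",
    "b_statistic",
    "de_table",
]

_PHI_BOUNDS = (0.0, 10.0)
_POISSON_PHI = 1e-10  # below this the exact test uses its binomial limit


@dataclass
class DispersionModel:
    common_phi: float
    tagwise_phi: pd.Series | None = None
    prior_df: float = 10.0

    def __post_init__(self) -> None:
        if self.common_phi < 0:
            raise ValueError("common_phi must be >= 0")
        if self.prior_df <= 0:
            raise ValueError("prior_df must be > 0")
        if self.tagwise_phi is not None and (self.tagwise_phi < 0).any():
            raise ValueError("tagwise dispersions must be >= 0")

    def phi_for(self, features: pd.Index) -> np.ndarray:
        if self.tagwise_phi is None:
            return np.full(len(features), self.common_phi)
        return self.tagwise_phi.reindex(features).fillna(self.common_phi).to_numpy()


def _as_counts(matrix, lib_sizes=None) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(matrix, CountMatrix):
        df = matrix.counts
        eff = matrix.library_sizes * matrix.norm_factors
    else:
        df = pd.DataFrame(matrix)
        eff = df.sum(axis=0).astype(float)
    if lib_sizes is not None:
        eff = pd.Series(lib_sizes, index=df.columns, dtype=float)
    if (eff <= 0).any():
        raise ValueError(
            "non-positive effective library size; pass explicit lib_sizes "
            "for degenerate fixtures"
        )
    return df, eff


def norm_factors(matrix) -> pd.Series:
    """TMM normalization factors against a reference library.

    Log-ratios of proportions against the library whose upper quartile is
    closest to the mean are doubly trimmed (30% by M, 5% by A) and
    averaged; factors are rescaled so their product is 1.
    """
    counts, _ = _as_counts(matrix)
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 libraries")
    y = counts.to_numpy(dtype=float)
    n = y.sum(axis=0)
    if (n <= 0).any():
        raise ValueError("library with all-zero counts")
    uq = np.array([np.quantile(y[:, i][y[:, i] > 0], 0.75) / n[i] if (y[:, i] > 0).any() else 0
                   for i in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(y.shape[1])
    for i in range(y.shape[1]):
        if i == ref:
            continue
        ok = (y[:, i] > 0) & (y[:, ref] > 0)
        if ok.sum() == 0:
            continue
        p_i = y[ok, i] / n[i]
        p_r = y[ok, ref] / n[ref]
        m = np.log2(p_i / p_r)
        a = 0.5 * np.log2(p_i * p_r)
        if np.allclose(m, m[0]):
            factors[i] = 2.0 ** m[0]
            continue
        lo_m, hi_m = np.quantile(m, [0.30, 0.70])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            keep = np.ones_like(m, dtype=bool)
        factors[i] = 2.0 ** m[keep].mean()
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def _pseudo_counts(counts: pd.DataFrame, eff_sizes: pd.Series) -> tuple[np.ndarray, float]:
    """Scale counts to a common geometric-mean effective library size."""
    eff = eff_sizes.to_numpy(dtype=float)
    n_star = float(np.exp(np.mean(np.log(eff))))
    return counts.to_numpy(dtype=float) * (n_star / eff), n_star


def _group_arrays(
    counts: pd.DataFrame, groups, contrast=None
) -> tuple[np.ndarray, list[np.ndarray]]:
    g = pd.Series(groups)
    g = g.reindex(counts.columns)
    if g.isna().any():
        raise ValueError("every library needs a group label")
    if contrast is not None:
        levels = list(contrast)
        extra = set(g) - set(levels)
        if extra:
            raise ValueError(f"libraries outside the contrast {contrast}: {sorted(extra)}")
    else:
        levels = list(pd.unique(g))
    cols = [np.flatnonzero((g == lev).to_numpy()) for lev in levels]
    if any(len(c) == 0 for c in cols):
        raise ValueError(f"empty group among {levels}")
    return np.array(levels, dtype=object), cols


def _cond_loglik(pseudo: np.ndarray, group_cols: list[np.ndarray], phi: float) -> np.ndarray:
    """Per-feature conditional NB log-likelihood summed over groups.

    For a group of n libraries at equal effective sizes, the likelihood of
    the within-group split conditional on the group total z is
      sum_i lgamma(y_i + r) + lgamma(n r) - lgamma(z + n r)
      - n lgamma(r) + lgamma(z + 1) - sum_i lgamma(y_i + 1),   r = 1/phi.
    The phi -> 0 limit (multinomial) is evaluated directly.
    """
    G = pseudo.shape[0]
    total = np.zeros(G)
    if phi < 1e-12:
        # Poisson limit: log multinomial coefficient with equal cell probs
        for cols in group_cols:
            y = pseudo[:, cols]
            z = y.sum(axis=1)
            n = len(cols)
            total += (
                special.gammaln(z + 1)
                - special.gammaln(y + 1).sum(axis=1)
                - z * np.log(n)
            )
        return total
    r = 1.0 / phi
    for cols in group_cols:
        y = pseudo[:, cols]
        z = y.sum(axis=1)
        n = len(cols)
        total += (
            special.gammaln(y + r).sum(axis=1)
            + special.gammaln(n * r)
            - special.gammaln(z + n * r)
            - n * special.gammaln(r)
            + special.gammaln(z + 1)
            - special.gammaln(y + 1).sum(axis=1)
        )
    return total


def _golden_max(fun, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section maximizer of a unimodal function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


def _prep(matrix, groups, lib_sizes=None, contrast=None):
    counts, eff = _as_counts(matrix, lib_sizes)
    levels, cols = _group_arrays(counts, groups, contrast)
    pseudo, n_star = _pseudo_counts(counts, eff)
    return counts, pseudo, n_star, levels, cols


def estimate_common_dispersion(matrix, groups, tol: float = 1e-6, lib_sizes=None) -> float:
    """Maximize the summed conditional NB log-likelihood over phi in [0, 10]."""
    _counts, pseudo, _n_star, _levels, cols = _prep(matrix, groups, lib_sizes)
    if max(len(c) for c in cols) < 2:
        raise ValueError("need >= 2 samples in at least one group")
    cols = [c for c in cols if len(c) >= 2]

    def objective(phi: float) -> float:
        return float(_cond_loglik(pseudo, cols, phi).sum())

    return _golden_max(objective, *_PHI_BOUNDS, tol=tol)


def estimate_tagwise_dispersion(
    matrix, groups, common_phi: float, prior_df: float = 10.0, tol: float = 1e-6,
    lib_sizes=None,
) -> pd.Series:
    """Per-feature dispersion shrunk toward the common value.

    Maximizes the weighted conditional likelihood l_g(phi) +
    prior_df * lbar(phi), where lbar is the per-feature mean conditional
    log-likelihood across all features.  prior_df -> infinity recovers the
    common dispersion for every feature.  O(G^2) in the number of
    features; intended for matrices of moderate size.
    """
    counts, pseudo, _n_star, _levels, cols = _prep(matrix, groups, lib_sizes)
    if max(len(c) for c in cols) < 2:
        raise ValueError("need >= 2 samples in at least one group")
    cols = [c for c in cols if len(c) >= 2]
    G = pseudo.shape[0]

    def lbar(phi: float) -> float:
        return float(_cond_loglik(pseudo, cols, phi).mean())

    out = np.empty(G)
    for g in range(G):
        row = pseudo[g : g + 1]

        def objective(phi: float) -> float:
            return float(_cond_loglik(row, cols, phi)[0]) + prior_df * lbar(phi)

        out[g] = _golden_max(objective, *_PHI_BOUNDS, tol=tol)
    return pd.Series(out, index=counts.index, name="tagwise_phi")


def _exact_p_nb(z1: float, z2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p for group sums z1, z2 (equal sizes)."""
    s = int(round(z1 + z2))
    if s <= 0:
        return 1.0
    k_obs = int(round(z1))
    k_obs = min(max(k_obs, 0), s)
    if phi < _POISSON_PHI:
        # Binomial (Poisson) limit: S1 | S ~ Bin(s, n1/(n1+n2))
        p_lo = float(stats.binom.cdf(k_obs, s, n1 / (n1 + n2)))
        p_hi = float(stats.binom.sf(k_obs - 1, s, n1 / (n1 + n2)))
        return float(min(1.0, 2.0 * min(p_lo, p_hi)))
    r1, r2 = n1 / phi, n2 / phi
    k = np.arange(s + 1)
    logw = (
        special.gammaln(k + r1)
        - special.gammaln(k + 1)
        + special.gammaln(s - k + r2)
        - special.gammaln(s - k + 1)
    )
    logw -= special.logsumexp(logw)
    w = np.exp(logw)
    p_lo = float(w[: k_obs + 1].sum())
    p_hi = float(w[k_obs:].sum())
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def exact_test(
    matrix, groups, dispersion: DispersionModel | float, lib_sizes=None, contrast=None
) -> pd.DataFrame:
    """Conditional NB exact test between exactly two groups.

    Returns per-feature ``p_value``, ``log2_fc`` (second group over first)
    and ``log_cpm``.  Fold changes use a 0.5 pseudo-count on the
    per-library average scale for display; testing never uses the offset.
    """
    counts, pseudo, n_star, levels, cols = _prep(matrix, groups, lib_sizes, contrast)
    if len(levels) != 2:
        raise ValueError(
            f"exact test requires exactly two groups, got {len(levels)}: "
            "run pairwise contrasts instead"
        )
    if isinstance(dispersion, (int, float)):
        dispersion = DispersionModel(common_phi=float(dispersion))
    phis = dispersion.phi_for(counts.index)
    (c1, c2) = cols
    n1, n2 = len(c1), len(c2)
    z1 = pseudo[:, c1].sum(axis=1)
    z2 = pseudo[:, c2].sum(axis=1)
    p = np.array(
        [_exact_p_nb(z1[g], z2[g], n1, n2, phis[g]) for g in range(len(z1))]
    )
    m1 = z1 / n1
    m2 = z2 / n2
    log2_fc = np.log2((m2 + 0.5) / (m1 + 0.5))
    log_cpm = np.log2(((z1 + z2) / (n1 + n2) + 0.5) / n_star * 1e6)
    return pd.DataFrame(
        {"log2_fc": log2_fc, "log_cpm": log_cpm, "p_value": p}, index=counts.index
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/y asymptotics)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def b_statistic(
    matrix,
    groups,
    pi0: float = 0.9,
    b_threshold: float = 1.0,
    lib_sizes=None,
    contrast=None,
) -> pd.DataFrame:
    """Empirical-Bayes log posterior odds of differential expression.

    Works on log-CPM values: per-feature two-group mean difference with a
    moderated (shrunken) variance.  Hyperparameters d0 and s0^2 come from
    the marginal moments of the log residual variances; the alternative's
    variance inflation r = (v + v0)/v is method-of-moments matched to the
    mean squared moderated t with prior non-DE proportion ``pi0``.
    Features with b >= ``b_threshold`` are flagged ``called``.
    """
    counts, pseudo, n_star, levels, cols = _prep(matrix, groups, lib_sizes, contrast)
    if len(levels) != 2:
        raise ValueError("b_statistic requires exactly two groups")
    (c1, c2) = cols
    n1, n2 = len(c1), len(c2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    logcpm = np.log2((pseudo + 0.5) / (n_star + 1.0) * 1e6)
    x1, x2 = logcpm[:, c1], logcpm[:, c2]
    beta = x2.mean(axis=1) - x1.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = np.maximum(ss / df_resid, 1e-12)
    v = 1.0 / n1 + 1.0 / n2

    # Smyth-style moment fit of the scaled inverse-chi-square variance prior
    e = np.log(s2)
    z = e - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    var_z = float(np.var(z, ddof=1)) if len(z) > 1 else 0.0
    excess = var_z - float(special.polygamma(1, df_resid / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
    else:
        d0 = np.inf
    if np.isfinite(d0):
        s0_sq = float(np.exp(np.mean(z) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = min(d0 + df_resid, 1e6)
    else:
        s0_sq = float(np.exp(np.mean(z)))
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e6
    t_mod = beta / np.sqrt(s2_post * v)

    pi1 = 1.0 - pi0
    m2 = float(np.mean(t_mod**2))
    scale = df_total / (df_total - 2.0) if df_total > 2 else 1.0
    r = max(1.0, (m2 / scale - pi0) / pi1)

    b = (
        np.log(pi1 / pi0)
        - 0.5 * np.log(r)
        + stats.t.logpdf(t_mod / np.sqrt(r), df_total)
        - stats.t.logpdf(t_mod, df_total)
    )
    return pd.DataFrame(
        {
            "b_statistic": b,
            "t_moderated": t_mod,
            "called": b >= b_threshold,
        },
        index=counts.index,
    )


def de_table(
    matrix,
    groups,
    dispersion: DispersionModel | float | None = None,
    pi0: float = 0.9,
    b_threshold: float = 1.0,
    contrast=None,
) -> pd.DataFrame:
    """Full two-group differential-expression table.

    Estimates the common dispersion when none is supplied, runs the exact
    test and the B ranking, and gates calls at ``b >= b_threshold``.  No
    multiple-testing correction is applied to the exact-test p-values: the
    calling gate is the posterior-odds threshold.
    """
    if dispersion is None:
        dispersion = DispersionModel(estimate_common_dispersion(matrix, groups))
    res = exact_test(matrix, groups, dispersion, contrast=contrast)
    bres = b_statistic(matrix, groups, pi0=pi0, b_threshold=b_threshold, contrast=contrast)
    out = res.join(bres[["b_statistic", "called"]])
    return out.sort_values("b_statistic", ascending=False)
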