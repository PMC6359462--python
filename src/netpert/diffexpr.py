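"""Two-group differential expression from raw counts.

Classic count-based testing: trimmed-mean-of-M-values (TMM) library
normalization, a single common negative-binomial dispersion estimated by
maximizing the conditional log-likelihood on library-size-equalized
pseudo-counts, and an exact test that enumerates the conditional
distribution of one group's count sum given the pair total.

The test models gene counts as NB(mean, phi) with a shared dispersion
phi.  After equalizing effective library sizes, the per-group sums are
NB distributed (size n_g / phi) and the two-sided p-value for a gene is
the total conditional probability of all splits of the observed total
that are no more likely than the observed split.  phi -> 0 recovers the
Poisson/binomial split test.

Genes are called up/down by BH-adjusted FDR and an absolute log2
fold-change threshold; users may instead supply an externally computed
table and skip this module entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import binom

from .preprocess import ExpressionMatrix
from .stats import bh_adjust

__all__ = [
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "call_degs",
    "de_table",
]

_PRIOR_COUNT = 0.125  # per-group prior for finite log fold changes


def tmm_factors(
    counts: ExpressionMatrix,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean forced to 1.

    The reference is the sample whose upper-quartile expression fraction
    is closest to the mean upper quartile.  Per sample, log-ratios M and
    average abundances A against the reference are computed over genes
    expressed in both; M is trimmed ``m_trim`` two-sided and A ``a_trim``
    two-sided; the factor is 2 to the inverse-variance-weighted mean of
    the surviving M values.
    """
    x = counts.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[counts.samples[j] for j in zero]}")
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")

    frac = x / lib
    uq = np.array([np.quantile(frac[:, j][frac[:, j] > 0], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(x.shape[1])
    yr, lr = x[:, ref], lib[ref]
    for j in range(x.shape[1]):
        if j == ref:
            continue
        y, l = x[:, j], lib[j]
        ok = (y > 0) & (yr > 0)
        if ok.sum() < 10:
            continue
        m = np.log2((y[ok] / l) / (yr[ok] / lr))
        a = 0.5 * np.log2((y[ok] / l) * (yr[ok] / lr))
        # asymptotic variance of M (delta method on two binomial proportions)
        w = (l - y[ok]) / (l * y[ok]) + (lr - yr[ok]) / (lr * yr[ok])
        keep = (
            (m >= np.quantile(m, m_trim))
            & (m <= np.quantile(m, 1 - m_trim))
            & (a >= np.quantile(a, a_trim))
            & (a <= np.quantile(a, 1 - a_trim))
        )
        if keep.any():
            log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.samples, name="tmm_factor")


def _pseudo_counts(counts: ExpressionMatrix, factors: pd.Series):
    """Scale counts to a common effective library size (geometric mean)."""
    x = counts.values.to_numpy(dtype=float)
    eff = x.sum(axis=0) * factors.loc[counts.samples].to_numpy()
    common = float(np.exp(np.mean(np.log(eff))))
    return x * (common / eff), common


def _group_cond_loglik(y: np.ndarray, log_phi: float) -> float:
    """Conditional NB log-likelihood of one group's counts given their sum."""
    r = np.exp(-log_phi)  # 1/phi
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    counts: ExpressionMatrix,
    factors: pd.Series | None = None,
    max_genes: int = 2000,
    seed: int = 0,
) -> float:
    """Single shared NB dispersion phi by conditional maximum likelihood.

    Computed on library-size-equalized pseudo-counts; phi -> 0 recovers
    Poisson behavior.  With more than ``max_genes`` genes a seeded random
    subset is used.
    """
    for cond in ("normal", "tumor"):
        if len(counts.condition_samples(cond)) < 2:
            raise ValueError(f"need >= 2 samples in condition '{cond}'")
    if factors is None:
        factors = tmm_factors(counts)
    pseudo, _ = _pseudo_counts(counts, factors)
    if pseudo.shape[0] > max_genes:
        idx = np.random.default_rng(seed).choice(pseudo.shape[0], max_genes, replace=False)
        pseudo = pseudo[np.sort(idx)]
    groups = [
        [counts.samples.index(s) for s in counts.condition_samples(c)]
        for c in ("normal", "tumor")
    ]

    def neg_ll(log_phi: float) -> float:
        return -sum(_group_cond_loglik(pseudo[:, g], log_phi) for g in groups)

    res = minimize_scalar(neg_ll, bounds=(np.log(1e-6), np.log(10.0)), method="bounded")
    phi = float(np.exp(res.x))
    return 0.0 if phi <= 2e-6 else phi


def _split_pvalue(za: int, zb: int, na: int, nb_: int, phi: float) -> float:
    """Two-sided exact p for the observed split of a pair of group sums.

    Enumerates the conditional distribution of the group-A sum given the
    total; the p-value sums the probability of every split at most as
    likely as the observed one.
    """
    total = za + zb
    if total == 0:
        return 1.0
    s = np.arange(total + 1)
    if phi <= 0:
        logf = binom.logpmf(s, total, na / (na + nb_))
    else:
        ra, rb = na / phi, nb_ / phi
        # equal per-sample means after library equalization => shared NB
        # success probability; it cancels in the conditional distribution
        logf = (
            gammaln(s + ra) - gammaln(s + 1)
            + gammaln(total - s + rb) - gammaln(total - s + 1)
        )
        logf -= logf.max()
        logf -= np.log(np.exp(logf).sum())
    obs = logf[za]
    mask = logf <= obs + 1e-10
    if phi <= 0:
        return float(min(1.0, np.exp(logf[mask]).sum() if mask.any() else 1.0))
    return float(min(1.0, np.exp(logf[mask]).sum()))


def nb_exact_test(
    counts: ExpressionMatrix,
    factors: pd.Series | None = None,
    phi: float | None = None,
) -> pd.DataFrame:
    """Per-gene exact-test p-values and log2 fold changes (tumor/normal).

    Returns a DataFrame indexed by gene with columns ``logFC`` and
    ``pvalue``.  logFC uses normalized group means with a 0.125 prior
    count per group.
    """
    if factors is None:
        factors = tmm_factors(counts)
    if phi is None:
        phi = estimate_common_dispersion(counts, factors)
    pseudo, _ = _pseudo_counts(counts, factors)
    idx_n = [counts.samples.index(s) for s in counts.condition_samples("normal")]
    idx_t = [counts.samples.index(s) for s in counts.condition_samples("tumor")]
    n_n, n_t = len(idx_n), len(idx_t)

    zn = np.rint(pseudo[:, idx_n].sum(axis=1)).astype(int)
    zt = np.rint(pseudo[:, idx_t].sum(axis=1)).astype(int)
    logfc = np.log2(((zt + _PRIOR_COUNT) / n_t) / ((zn + _PRIOR_COUNT) / n_n))
    pvals = np.array(
        [_split_pvalue(int(a), int(b), n_n, n_t, phi) for a, b in zip(zn, zt)]
    )
    return pd.DataFrame({"logFC": logfc, "pvalue": pvals}, index=counts.values.index)


def call_degs(
    results: pd.DataFrame,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Split a DE table into (up, down) gene sets by FDR and |logFC|.

    up = {q <= fdr and logFC >= lfc}; down = {q <= fdr and logFC <= -lfc}.
    """
    if len(results) == 0:
        return set(), set()
    q = results["qvalue"] if "qvalue" in results else pd.Series(
        bh_adjust(results["pvalue"].to_numpy()), index=results.index
    )
    sig = q <= fdr_threshold
    up = set(results.index[sig & (results["logFC"] >= lfc_threshold)])
    down = set(results.index[sig & (results["logFC"] <= -lfc_threshold)])
    return up, down


def de_table(
    counts: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Full DE pipeline: TMM -> dispersion -> exact test -> calls.

    Columns: logFC, pvalue, qvalue, direction ('up' | 'down' | 'ns').
    """
    factors = tmm_factors(counts)
    phi = estimate_common_dispersion(counts, factors)
    res = nb_exact_test(counts, factors, phi)
    res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
    up, down = call_degs(res, fdr_threshold, lfc_threshold)
    res["direction"] = "ns"
    res.loc[res.index.isin(up), "direction"] = "up"
    res.loc[res.index.isin(down), "direction"] = "down"
    res.index.name = "gene"
    return res
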