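"""Differential co-expression between two conditions.

For each gene pair the Pearson correlation is estimated separately in
normal and tumor samples, the correlations are Fisher-z transformed and
their standardized difference dz is tested, asymptotically (normal) and
empirically (pooled label-permutation null).  Pairs are classified into
the nine-class taxonomy {-,0,+} x {-,0,+} of per-condition correlation
states and into the (r_normal, r_tumor) sign quadrants; quadrant II
(negative -> positive) and IV (positive -> negative) pairs are the
"sign-flip" rewired pairs whose genes feed the network-refined disease
signature.

Because extreme dz values are unreachable by direct permutation counting,
empirical p-values that hit the permutation floor 1/(1+n_null) fall back
to the asymptotic normal p-value and are flagged ``tail_extrapolated``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import ExpressionMatrix

__all__ = [
    "RewiredPairSet",
    "condition_correlations",
    "empirical_null",
    "empirical_pvalue",
    "classify_states",
    "classify_pairs",
    "quadrant_of",
    "add_quadrants",
    "significant_pairs",
    "sign_change_genes",
]

_CLAMP = 1.0 - 1e-12  # |r| = 1 clamped here before atanh

QUADRANTS = ("I", "II", "III", "IV", "axis")


def _corr_and_pvals(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full Pearson correlation matrix and t-based two-sided p-values."""
    n = x.shape[1]
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def _pair_indices(genes: list[str], pairs) -> tuple[np.ndarray, np.ndarray]:
    pairs = list(pairs)
    pos = {g: i for i, g in enumerate(genes)}
    i1 = np.array([pos[a] for a, _ in pairs], dtype=int)
    i2 = np.array([pos[b] for _, b in pairs], dtype=int)
    return i1, i2


def _dz(r1: np.ndarray, n1: int, r2: np.ndarray, n2: int) -> np.ndarray:
    z1 = np.arctanh(np.clip(r1, -_CLAMP, _CLAMP))
    z2 = np.arctanh(np.clip(r2, -_CLAMP, _CLAMP))
    return (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))


def condition_correlations(
    expr: ExpressionMatrix,
    pairs="all",
    max_genes: int = 5000,
    preselect_top: int | None = 2000,
) -> pd.DataFrame:
    """Per-condition correlations and the z-difference for gene pairs.

    Parameters
    ----------
    expr : ExpressionMatrix
        Normalized (log-scale) expression with both conditions present.
    pairs : "all" or list of (gene1, gene2)
        "all" enumerates every unordered distinct pair.  When the gene
        count exceeds ``max_genes``, the ``preselect_top`` most variable
        genes are used instead (set to None to make that an error).

    Returns
    -------
    DataFrame with columns gene1, gene2, r_normal, p_normal, r_tumor,
    p_tumor, dz, p_diff_asymptotic.  Pairs involving a gene that is
    constant in either condition are excluded (with a warning), never
    reported as r = 0.
    """
    cols_n = expr.condition_samples("normal")
    cols_t = expr.condition_samples("tumor")
    if len(cols_n) < 4 or len(cols_t) < 4:
        raise ValueError("need at least 4 samples per condition")

    genes = expr.genes
    if pairs == "all" and len(genes) > max_genes:
        if preselect_top is None:
            raise ValueError(
                f"{len(genes)} genes exceeds max_genes={max_genes}; "
                "supply an explicit pair list or enable preselect_top"
            )
        var = expr.values.var(axis=1)
        genes = var.nlargest(preselect_top).index.tolist()

    sub = expr.values.loc[genes]
    xn = sub[cols_n].to_numpy(dtype=float)
    xt = sub[cols_t].to_numpy(dtype=float)

    const = (np.ptp(xn, axis=1) == 0) | (np.ptp(xt, axis=1) == 0)
    if const.any():
        dropped = [g for g, c in zip(genes, const) if c]
        warnings.warn(
            f"excluding {len(dropped)} gene(s) constant in a condition "
            f"(e.g. {dropped[:3]})",
            stacklevel=2,
        )
        genes = [g for g, c in zip(genes, const) if not c]
        xn, xt = xn[~const], xt[~const]

    rn, pn = _corr_and_pvals(xn)
    rt, pt = _corr_and_pvals(xt)

    if pairs == "all":
        i1, i2 = np.triu_indices(len(genes), k=1)
    else:
        keep = set(genes)
        pairs = [(a, b) for a, b in pairs if a in keep and b in keep]
        i1, i2 = _pair_indices(genes, pairs)

    n1, n2 = len(cols_n), len(cols_t)
    dz = _dz(rn[i1, i2], n1, rt[i1, i2], n2)
    garr = np.asarray(genes, dtype=object)
    return pd.DataFrame(
        {
            "gene1": garr[i1],
            "gene2": garr[i2],
            "r_normal": rn[i1, i2],
            "p_normal": pn[i1, i2],
            "r_tumor": rt[i1, i2],
            "p_tumor": pt[i1, i2],
            "dz": dz,
            "p_diff_asymptotic": 2.0 * sps.norm.sf(np.abs(dz)),
        }
    )


def empirical_null(
    expr: ExpressionMatrix,
    records: pd.DataFrame,
    n_perm: int,
    seed: int = 0,
) -> np.ndarray:
    """Pooled permutation null of dz over all pairs.

    Condition labels are permuted ``n_perm`` times; dz is recomputed for
    every pair each round and all values pooled into one null sample of
    size n_pairs x n_perm.  Bit-reproducible for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1; use the asymptotic p-value instead")
    rng = np.random.default_rng(seed)
    genes = sorted(set(records["gene1"]) | set(records["gene2"]))
    x = expr.values.loc[genes].to_numpy(dtype=float)
    i1, i2 = _pair_indices(genes, records[["gene1", "gene2"]].itertuples(index=False))
    is_normal = (expr.design == "normal").to_numpy()
    n1, n2 = int(is_normal.sum()), int((~is_normal).sum())

    out = np.empty((n_perm, len(i1)))
    for b in range(n_perm):
        perm = rng.permutation(is_normal)
        rn = np.corrcoef(x[:, perm])
        rt = np.corrcoef(x[:, ~perm])
        out[b] = _dz(rn[i1, i2], n1, rt[i1, i2], n2)
    return out.ravel()


def empirical_pvalue(
    dz, null_sample: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided empirical p from a pooled null, with tail extrapolation.

    p = (1 + #{|null| >= |dz|}) / (1 + n_null).  Where p hits the floor
    1/(1 + n_null) the asymptotic normal p-value is substituted and the
    pair is flagged tail-extrapolated — how values far below the
    permutation resolution (e.g. a 1e-20 significance threshold) are
    adjudicated.

    Returns (p, tail_extrapolated) arrays.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty permutation null")
    dz = np.atleast_1d(np.asarray(dz, dtype=float))
    sorted_abs = np.sort(np.abs(null_sample))
    n_ge = null_sample.size - np.searchsorted(sorted_abs, np.abs(dz), side="left")
    p = (1.0 + n_ge) / (1.0 + null_sample.size)
    floor = n_ge == 0
    p[floor] = 2.0 * sps.norm.sf(np.abs(dz[floor]))
    return p, floor


def classify_states(r: float, p: float, class_alpha: float = 0.05) -> str:
    """Correlation state in one condition: '+', '-', or '0'."""
    if p <= class_alpha and r > 0:
        return "+"
    if p <= class_alpha and r < 0:
        return "-"
    return "0"


def classify_pairs(records: pd.DataFrame, class_alpha: float = 0.05) -> pd.Series:
    """Nine-class label "normal_state/tumor_state" per pair."""
    out = [
        classify_states(rn, pn, class_alpha) + "/" + classify_states(rt, pt, class_alpha)
        for rn, pn, rt, pt in zip(
            records["r_normal"], records["p_normal"],
            records["r_tumor"], records["p_tumor"],
        )
    ]
    return pd.Series(out, index=records.index, name="class9")


def quadrant_of(r_normal: float, r_tumor: float) -> str:
    """Sign quadrant of (r_normal, r_tumor); zero on either axis -> 'axis'.

    II = negative in normal, positive in tumor; IV = the reverse.
    """
    if r_normal == 0 or r_tumor == 0:
        return "axis"
    if r_normal > 0:
        return "I" if r_tumor > 0 else "IV"
    return "II" if r_tumor > 0 else "III"


def add_quadrants(records: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [quadrant_of(a, b) for a, b in zip(records["r_normal"], records["r_tumor"])],
        index=records.index,
        name="quadrant",
    )


@dataclass
class RewiredPairSet:
    """Significant differentially co-expressed pairs and their genes."""

    records: pd.DataFrame
    unique_genes: list[str] = field(init=False)
    quadrant_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.unique_genes = sorted(
            set(self.records["gene1"]) | set(self.records["gene2"])
        )
        quad = (
            self.records["quadrant"]
            if "quadrant" in self.records
            else add_quadrants(self.records)
        )
        counts = quad.value_counts().to_dict()
        self.quadrant_counts = {q: int(counts.get(q, 0)) for q in QUADRANTS}


def significant_pairs(
    records: pd.DataFrame,
    threshold: float = 1e-20,
    use: str = "empirical",
) -> RewiredPairSet:
    """Filter pairs at a differential-correlation p-value threshold.

    ``use`` selects the p-value field: "empirical" (p_diff_empirical,
    with its tail-extrapolation convention) or "asymptotic".
    """
    col = {"empirical": "p_diff_empirical", "asymptotic": "p_diff_asymptotic"}[use]
    kept = records[records[col] <= threshold].copy()
    if "class9" not in kept:
        kept["class9"] = classify_pairs(kept)
    if "quadrant" not in kept:
        kept["quadrant"] = add_quadrants(kept)
    return RewiredPairSet(kept.reset_index(drop=True))


def sign_change_genes(pairset: RewiredPairSet) -> set[str]:
    """Genes in quadrant II or IV pairs — those flipping correlation sign."""
    rec = pairset.records
    flip = rec[rec["quadrant"].isin(["II", "IV"])]
    return set(flip["gene1"]) | set(flip["gene2"])
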