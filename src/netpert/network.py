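"""Weighted co-expression networks, module detection and comparison.

Per condition: a soft-thresholded adjacency ``|cor|^beta`` (or the signed
variant), the topological overlap matrix (TOM) combining direct adjacency
with shared-neighbor similarity, average-linkage hierarchical clustering
on 1 - TOM with a static height cut, and size-ranked color-name module
labels ("grey" = unassigned).  The soft power is chosen by the scale-free
topology criterion: the smallest beta whose log-log degree-distribution
fit reaches the target R^2.  Cross-condition module comparison counts
gene overlaps and scores them hypergeometrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .preprocess import ExpressionMatrix
from .stats import ContingencyTable2x2, fisher_exact_over

__all__ = [
    "SoftPowerReport",
    "ModuleAssignment",
    "adjacency",
    "pick_soft_power",
    "tom_similarity",
    "cluster_modules",
    "module_overlap",
    "MODULE_COLORS",
]

# size-ranked module palette, the weighted-network community's color
# vocabulary; "grey" reserved for unassigned
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class SoftPowerReport:
    powers: list[int]
    scale_free_r2: dict[int, float]
    mean_connectivity: dict[int, float]
    chosen: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "scale_free_r2": [self.scale_free_r2[b] for b in self.powers],
                "mean_connectivity": [self.mean_connectivity[b] for b in self.powers],
                "chosen": [b == self.chosen for b in self.powers],
            }
        )


@dataclass
class ModuleAssignment:
    """gene -> module color label for one condition's network."""

    labels: pd.Series
    condition: str

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> set[str]:
        return set(self.labels.index[self.labels == module])

    @property
    def n_modules(self) -> int:
        return int((self.labels.unique() != "grey").sum())


def remove_outlier_samples(
    expr: ExpressionMatrix, mad_threshold: float = 2.5
) -> ExpressionMatrix:
    """Drop samples that join the sample dendrogram anomalously late.

    Samples are average-linkage clustered on Euclidean expression
    distance; a sample whose merge height exceeds the median leaf merge
    height by more than ``mad_threshold`` MADs is removed.  Off by
    default in the pipeline; intended for real cohorts with technical
    outliers.
    """
    x = expr.values.to_numpy(dtype=float).T
    n = x.shape[0]
    if n < 4:
        return expr
    from scipy.spatial.distance import pdist

    link = average(pdist(x))
    # height at which each original sample first merges into a cluster
    first = np.full(n, link[-1, 2] if len(link) else 0.0)
    for a, b, h, _ in link:
        for node in (int(a), int(b)):
            if node < n:
                first[node] = h
    med = np.median(first)
    mad = np.median(np.abs(first - med)) or 1e-12
    keep = first <= med + mad_threshold * mad * 1.4826
    if keep.all():
        return expr
    cols = [s for s, k in zip(expr.samples, keep) if k]
    warnings.warn(
        f"removing {int((~keep).sum())} outlier sample(s)", stacklevel=2
    )
    return ExpressionMatrix(expr.values[cols], expr.design.loc[cols], expr.unit)


def adjacency(
    expr_condition: ExpressionMatrix, beta: int, mode: str = "unsigned"
) -> pd.DataFrame:
    """Soft-thresholded adjacency: ``|cor|^beta`` or ``((1+cor)/2)^beta``.

    Genes constant across the condition's samples are excluded with a
    warning.  The diagonal is 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if mode not in ("unsigned", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    x = expr_condition.values.to_numpy(dtype=float)
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    genes = np.asarray(expr_condition.genes, dtype=object)
    const = np.ptp(x, axis=1) == 0
    if const.any():
        warnings.warn(f"excluding {const.sum()} constant gene(s)", stacklevel=2)
        x, genes = x[~const], genes[~const]
    r = np.clip(np.corrcoef(x), -1.0, 1.0)
    a = np.abs(r) ** beta if mode == "unsigned" else ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit of a connectivity vector.

    R^2 of log10 degree density vs log10 connectivity over
    equal-occupancy bins (quantile edges), which keeps every bin
    populated regardless of how skewed k is.  A fit with rising density
    contradicts scale-free topology and scores 0.
    """
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.unique(np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 4:
        return 0.0
    counts, edges = np.histogram(k, bins=edges)
    width = np.diff(edges)
    ok = counts > 0
    x = np.log10(0.5 * (edges[:-1] + edges[1:])[ok])
    y = np.log10(counts[ok] / k.size / width[ok])
    if x.size < 3:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r) or r > 0:
        return 0.0
    return float(r * r)


def pick_soft_power(
    expr_condition: ExpressionMatrix,
    powers=range(1, 21),
    target_r2: float = 0.8,
    mode: str = "unsigned",
) -> SoftPowerReport:
    """Scan candidate powers for scale-free topology fit.

    Chooses the smallest beta with R^2 >= ``target_r2``; if none reaches
    the target, the beta maximizing R^2.
    """
    if len(expr_condition.genes) < 30:
        raise ValueError("need at least 30 genes for a degree-distribution fit")
    powers = list(powers)
    a1 = adjacency(expr_condition, beta=1, mode=mode)
    base = a1.to_numpy().copy()
    np.fill_diagonal(base, 0.0)
    r2, meank = {}, {}
    for b in powers:
        k = (base ** b).sum(axis=1)
        r2[b] = _scale_free_r2(k)
        meank[b] = float(k.mean())
    reaching = [b for b in powers if r2[b] >= target_r2]
    chosen = reaching[0] if reaching else max(powers, key=lambda b: r2[b])
    return SoftPowerReport(powers, r2, meank, chosen)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    L_ij the shared-neighbor weight sum (excluding i and j) and k the
    connectivity; TOM_ii = 1.  Entries lie in [0, 1] for adjacency in
    [0, 1].
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # (A @ A)_ij = sum_u a_iu a_uj over all u; u in {i, j} contributes 0
    # because the diagonal is zeroed
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a) / denom
    tom[denom == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def cluster_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.995,
    condition: str = "",
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` are merged into "grey";
    surviving modules are labelled by decreasing size with the fixed
    color sequence.  Output is invariant to gene input order (genes are
    sorted internally; size ties break by smallest member symbol).
    """
    order = np.argsort(tom.index.to_numpy())
    genes = tom.index.to_numpy()[order]
    d = 1.0 - tom.to_numpy()[np.ix_(order, order)]
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    link = average(squareform(d, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size]
    # order by size desc, tie-break by the lexicographically smallest gene
    ranked = sorted(
        keep.index,
        key=lambda c: (-keep[c], min(genes[raw == c])),
    )
    color_of = {
        c: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, c in enumerate(ranked)
    }
    labels = pd.Series(
        [color_of.get(c, "grey") for c in raw], index=genes, name="module"
    )
    return ModuleAssignment(labels.loc[np.sort(genes)], condition)


def module_overlap(
    assign_a: ModuleAssignment,
    assign_b: ModuleAssignment,
    universe=None,
) -> pd.DataFrame:
    """Gene-overlap counts and hypergeometric p per module pair.

    The shared gene universe is the intersection of the two assignments
    (optionally further restricted).  Returns a long-format table with
    columns module_a, module_b, size_a, size_b, overlap, pvalue.
    """
    shared = set(assign_a.labels.index) & set(assign_b.labels.index)
    if universe is not None:
        shared &= set(universe)
    if not shared:
        raise ValueError("assignments share no genes")
    shared = sorted(shared)
    la = assign_a.labels.loc[shared]
    lb = assign_b.labels.loc[shared]
    N = len(shared)
    rows = []
    for ma in la.unique():
        ga = set(la.index[la == ma])
        for mb in lb.unique():
            gb = set(lb.index[lb == mb])
            k = len(ga & gb)
            p = fisher_exact_over(ContingencyTable2x2(k, len(ga), len(gb), N))
            rows.append((ma, mb, len(ga), len(gb), k, p))
    return pd.DataFrame(
        rows, columns=["module_a", "module_b", "size_a", "size_b", "overlap", "pvalue"]
    )
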