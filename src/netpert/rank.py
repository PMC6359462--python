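"""Disease signatures and perturbation-reversal ranking.

A perturbation signature is an (up, down) pair of gene sets; a candidate
reverser of a disease is one whose induced down-set over-represents the
disease's up-regulated genes and/or whose up-set over-represents the
disease's down-regulated genes.  Each direction is scored by a one-sided
hypergeometric (Fisher-exact over-representation) test on the shared
gene universe and the two directional p-values are pooled by Fisher's
method (chi-squared, 4 df); perturbations are ranked by ascending
combined p-value.

The network-refined disease signature intersects the up/down DEG sets
with the genes of sign-flip rewired pairs, restricting the query to
genes perturbed at both the expression and the co-expression level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import ContingencyTable2x2, bh_adjust, fisher_exact_over

__all__ = [
    "Signature",
    "SignatureDB",
    "DiseaseSignature",
    "refine_disease_signature",
    "reversal_score",
    "rank_perturbations",
    "collapse_by_name",
    "enrichment_over",
]


@dataclass(frozen=True)
class Signature:
    """One perturbation's up- and down-regulated gene sets."""

    id: str
    name: str
    kind: str  # "drug" | "gene"
    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(f"{self.id}: up and down sets overlap")
        if not self.up or not self.down:
            raise ValueError(f"{self.id}: empty up or down set")


@dataclass
class SignatureDB:
    signatures: list[Signature]

    def __len__(self) -> int:
        return len(self.signatures)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.signatures:
            out |= s.up | s.down
        return out

    def filter_kind(self, kind: str) -> list[Signature]:
        if kind == "all":
            return list(self.signatures)
        return [s for s in self.signatures if s.kind == kind]


@dataclass
class DiseaseSignature:
    """Disease up/down gene sets within an assayed-gene universe."""

    up: set
    down: set
    universe: set

    def __post_init__(self) -> None:
        if not self.up <= self.universe or not self.down <= self.universe:
            raise ValueError("signature genes must lie within the universe")
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def refine_disease_signature(
    deg_up: set, deg_down: set, rewired_genes: set, universe: set
) -> DiseaseSignature:
    """Restrict DEG sets to genes also rewired at the co-expression level."""
    up = set(deg_up) & set(rewired_genes)
    down = set(deg_down) & set(rewired_genes)
    if not up or not down:
        warnings.warn(
            "refined disease signature has an empty side "
            f"(up={len(up)}, down={len(down)})",
            stacklevel=2,
        )
    return DiseaseSignature(up, down, set(universe))


def _over_p(disease_side: set, sig_side: set, universe: set) -> tuple[float, int]:
    sig_in = sig_side & universe
    k = len(disease_side & sig_in)
    table = ContingencyTable2x2(k, len(disease_side), len(sig_in), len(universe))
    return fisher_exact_over(table), k


def reversal_score(disease: DiseaseSignature, sig: Signature) -> dict | None:
    """Directional reversal p-values and their Fisher combination.

    p_rev_up tests overlap(disease.up, sig.down); p_rev_down tests
    overlap(disease.down, sig.up); both on the disease universe.  Returns
    None for a signature with no genes in the universe (untestable).
    """
    uni = disease.universe
    if not ((sig.up | sig.down) & uni):
        return None
    p_up, k_up = (
        _over_p(disease.up, sig.down, uni) if disease.up else (None, 0)
    )
    p_down, k_down = (
        _over_p(disease.down, sig.up, uni) if disease.down else (None, 0)
    )
    avail = [p for p in (p_up, p_down) if p is not None]
    if not avail:
        return None
    if len(avail) == 2:
        # p can underflow to exactly 0 for overwhelming overlaps; floor it
        # at the smallest normal double before taking logs
        stat = -2.0 * sum(np.log(max(p, 2.3e-308)) for p in avail)
        p_comb = float(sps.chi2.sf(stat, df=4))
    else:
        p_comb = avail[0]
    return {
        "id": sig.id,
        "name": sig.name,
        "kind": sig.kind,
        "p_rev_up": p_up if p_up is not None else np.nan,
        "p_rev_down": p_down if p_down is not None else np.nan,
        "overlap_up_down": k_up,
        "overlap_down_up": k_down,
        "p_combined": p_comb,
    }


def rank_perturbations(
    disease: DiseaseSignature,
    db: SignatureDB,
    kind_filter: str = "all",
    adjust: bool = True,
) -> pd.DataFrame:
    """Score and rank every testable signature in the database.

    Sorted by ascending combined p; ties break by (p_rev_up, id), so the
    output is invariant to database input order.  A BH-adjusted column is
    reported, but the ranking uses the raw combined p-value.
    """
    if len(db) == 0:
        raise ValueError("empty signature database")
    rows = []
    for sig in db.filter_kind(kind_filter):
        rec = reversal_score(disease, sig)
        if rec is not None:
            rows.append(rec)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    key_up = out["p_rev_up"].fillna(np.inf)
    order = np.lexsort((out["id"].to_numpy(), key_up.to_numpy(), out["p_combined"].to_numpy()))
    out = out.iloc[order].reset_index(drop=True)
    if adjust:
        out["q_combined"] = bh_adjust(out["p_combined"].to_numpy())
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def collapse_by_name(ranked: pd.DataFrame) -> pd.DataFrame:
    """Best (lowest-p) signature per perturbation name — a secondary view
    for databases where one drug contributes several signatures."""
    if ranked.empty:
        return ranked
    return (
        ranked.sort_values("rank").groupby("name", sort=False).head(1).reset_index(drop=True)
    )


def enrichment_over(
    gene_set: set, term_sets: dict, universe: set
) -> pd.DataFrame:
    """Generic over-representation of one gene set against named terms.

    One-sided hypergeometric p per term, BH-adjusted across terms.  Users
    supply any named gene-set collection (e.g. read from GMT).
    """
    if not universe:
        raise ValueError("empty universe")
    gs = set(gene_set) & set(universe)
    rows = []
    for term, members in term_sets.items():
        mem = set(members) & set(universe)
        k = len(gs & mem)
        p = fisher_exact_over(ContingencyTable2x2(k, len(gs), len(mem), len(universe)))
        rows.append((term, len(mem), k, p))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "pvalue"])
    if not out.empty:
        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
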