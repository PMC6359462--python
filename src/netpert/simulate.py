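"""Synthetic two-condition RNA-seq study with known planted truth.

A single latent Gaussian layer encodes the per-condition correlation
structure (shared co-expression modules, condition-rewired gene pairs);
counts are produced gene-wise by pushing latent normal quantiles through
a negative-binomial quantile function whose mean carries the planted
tumor fold-change.  Because the NB quantile map is monotone, planted
latent correlations survive (approximately) into the count and
log-expression scales, so one generator serves the count-based DE stage
and the correlation-based stages simultaneously.

A companion generator builds a perturbation-signature database with
planted "reverser" signatures whose down-set is drawn from the disease
up-genes (and vice versa) at a configurable fidelity, plus size-matched
random decoys.

Every generator is a pure function of (config, seed).

Default scenario: 2000 genes, 60 normal / 200 tumor samples, three
shared co-expression modules of 50 genes at intra-correlation 0.7, two
rewired blocks of 10 gene pairs each (one sign-flipping negative to
positive, one positive to negative), 200 up- and 100 down-regulated
genes at |log2 fold change| 2, NB dispersion 0.1, and a 200-signature
database — small enough for a full pipeline run in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import ExpressionMatrix
from .rank import Signature, SignatureDB

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "generate_expression",
    "generate_signature_db",
    "nearest_psd",
]


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_normal: int = 60
    n_tumor: int = 200
    n_deg_up: int = 200
    n_deg_down: int = 100
    lfc: float = 2.0  # planted |log2 fold change|
    nb_dispersion: float = 0.1
    # (n_pairs, r_normal, r_tumor) per rewired block of disjoint pairs
    rewired_blocks: list = field(
        default_factory=lambda: [(10, -0.5, 0.9), (10, 0.7, -0.7)]
    )
    # (size, intra_correlation) per module, shared across conditions
    coexpr_modules: list = field(
        default_factory=lambda: [(50, 0.7), (50, 0.7), (50, 0.7)]
    )
    base_mean_log: float = np.log(60.0)
    base_mean_sigma: float = 0.8
    libsize_spread: float = 0.3  # sample depth factors in 1 +/- spread
    seed: int = 0

    def validate(self) -> None:
        for _, rn, rt in self.rewired_blocks:
            if not (-1 < rn < 1 and -1 < rt < 1):
                raise ValueError("rewired correlations must lie in (-1, 1)")
        for _, rho in self.coexpr_modules:
            if not -1 < rho < 1:
                raise ValueError("module correlations must lie in (-1, 1)")
        n_structured = 2 * sum(s for s, *_ in self.rewired_blocks) + sum(
            s for s, _ in self.coexpr_modules
        )
        if n_structured + self.n_deg_up + self.n_deg_down > self.n_genes + 2 * sum(
            s for s, *_ in self.rewired_blocks
        ):
            raise ValueError("planted structure does not fit into n_genes")


@dataclass
class SimulationTruth:
    deg_up: set
    deg_down: set
    rewired_pairs: list  # (gene1, gene2, r_normal, r_tumor)
    module_membership: dict  # gene -> module index
    reverser_ids: list = field(default_factory=list)

    def rewired_genes(self) -> set:
        out = set()
        for g1, g2, *_ in self.rewired_pairs:
            out |= {g1, g2}
        return out

    def to_dict(self) -> dict:
        return {
            "deg_up": sorted(self.deg_up),
            "deg_down": sorted(self.deg_down),
            "rewired_pairs": [list(p) for p in self.rewired_pairs],
            "module_membership": dict(sorted(self.module_membership.items())),
            "reverser_ids": list(self.reverser_ids),
        }


def nearest_psd(c: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping),
    restoring a unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    if w.min() >= min_eig:
        return c
    w = np.clip(w, min_eig, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    if np.linalg.eigvalsh(out).min() < 0:
        raise ValueError("correlation block not repairable to PSD")
    return out


def _sample_block(rng, corr: np.ndarray, n_samples: int) -> np.ndarray:
    corr = nearest_psd(corr)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))
    return chol @ rng.standard_normal((len(corr), n_samples))


def generate_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimulationTruth]:
    """Simulate (counts, normalized expression, truth) for one study.

    Gene layout: shared co-expression modules first, then rewired pairs,
    then unstructured genes.  Planted up-DEGs cover the first rewired
    block's genes (so expression- and rewiring-perturbed gene sets
    overlap, as in real tumors) and down-DEGs the second block's, each
    padded from the unstructured pool.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = [f"G{i:05d}" for i in range(G)]

    # --- latent correlation layout -------------------------------------
    module_membership: dict[str, int] = {}
    blocks_n: list[tuple[list[int], np.ndarray]] = []
    blocks_t: list[tuple[list[int], np.ndarray]] = []
    cursor = 0
    for mi, (size, rho) in enumerate(config.coexpr_modules):
        idx = list(range(cursor, cursor + size))
        cursor += size
        c = np.full((size, size), rho)
        np.fill_diagonal(c, 1.0)
        blocks_n.append((idx, c))
        blocks_t.append((idx, c))
        for i in idx:
            module_membership[genes[i]] = mi

    rewired_pairs: list[tuple[str, str, float, float]] = []
    block_gene_idx: list[list[int]] = []
    for n_pairs, rn, rt in config.rewired_blocks:
        bidx: list[int] = []
        for _ in range(n_pairs):
            i, j = cursor, cursor + 1
            cursor += 2
            bidx.extend((i, j))
            blocks_n.append(([i, j], np.array([[1.0, rn], [rn, 1.0]])))
            blocks_t.append(([i, j], np.array([[1.0, rt], [rt, 1.0]])))
            rewired_pairs.append((genes[i], genes[j], rn, rt))
        block_gene_idx.append(bidx)

    free = list(range(cursor, G))

    # --- planted DEGs ---------------------------------------------------
    up_idx = list(block_gene_idx[0]) if block_gene_idx else []
    up_idx += free[: max(0, config.n_deg_up - len(up_idx))]
    up_idx = up_idx[: config.n_deg_up]
    down_pool = [i for i in free if i not in set(up_idx)]
    down_idx = list(block_gene_idx[1]) if len(block_gene_idx) > 1 else []
    down_idx += down_pool[: max(0, config.n_deg_down - len(down_idx))]
    down_idx = down_idx[: config.n_deg_down]

    lfc_vec = np.zeros(G)
    lfc_vec[up_idx] = config.lfc
    lfc_vec[down_idx] = -config.lfc

    # --- latent draws ---------------------------------------------------
    def latent(blocks, n_samples):
        z = rng.standard_normal((G, n_samples))
        for idx, c in blocks:
            z[idx, :] = _sample_block(rng, c, n_samples)
        return z

    z_n = latent(blocks_n, config.n_normal)
    z_t = latent(blocks_t, config.n_tumor)

    # --- copula to counts ----------------------------------------------
    base = rng.lognormal(config.base_mean_log, config.base_mean_sigma, size=G)
    depth = rng.uniform(
        1.0 - config.libsize_spread, 1.0 + config.libsize_spread,
        size=config.n_normal + config.n_tumor,
    )
    mu = np.empty((G, config.n_normal + config.n_tumor))
    mu[:, : config.n_normal] = base[:, None]
    mu[:, config.n_normal:] = (base * 2.0 ** lfc_vec)[:, None]
    mu *= depth[None, :]

    u = sps.norm.cdf(np.hstack([z_n, z_t]))
    phi = config.nb_dispersion
    if phi <= 0:
        counts = sps.poisson.ppf(u, mu)
    else:
        r = 1.0 / phi
        counts = sps.nbinom.ppf(u, r, r / (r + mu))
    counts = counts.astype(np.int64)

    samples = [f"N{i:03d}" for i in range(config.n_normal)] + [
        f"T{i:03d}" for i in range(config.n_tumor)
    ]
    design = pd.Series(
        ["normal"] * config.n_normal + ["tumor"] * config.n_tumor,
        index=samples,
        name="condition",
    )
    cdf = pd.DataFrame(counts, index=genes, columns=samples)
    counts_m = ExpressionMatrix(cdf, design, unit="counts")

    # depth-normalized expression on an fpkm-like scale for the
    # filtering/correlation stages
    norm = cdf / cdf.sum(axis=0) * 1e4
    norm_m = ExpressionMatrix(norm, design, unit="fpkm")

    truth = SimulationTruth(
        deg_up={genes[i] for i in up_idx},
        deg_down={genes[i] for i in down_idx},
        rewired_pairs=rewired_pairs,
        module_membership=module_membership,
    )
    return counts_m, norm_m, truth


def generate_signature_db(
    truth: SimulationTruth,
    universe,
    n_decoys: int = 199,
    reverser_fidelity: float = 1.0,
    n_reversers: int = 1,
    seed: int = 0,
) -> SignatureDB:
    """Signature database with planted reversers among random decoys.

    A reverser takes a ``reverser_fidelity`` fraction of the disease
    up-genes into its down-set (and of the down-genes into its up-set),
    padded back to full size with random universe genes; decoys are
    size-matched random up/down sets.  Reverser ids are recorded in
    ``truth.reverser_ids``.
    """
    if not 0 < reverser_fidelity <= 1:
        raise ValueError("reverser_fidelity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    universe = sorted(universe)
    uni_arr = np.asarray(universe, dtype=object)
    deg_up = sorted(truth.deg_up)
    deg_down = sorted(truth.deg_down)

    def pad(seed_set: list, size: int, forbid: set) -> frozenset:
        chosen = set(seed_set)
        pool = [g for g in universe if g not in chosen and g not in forbid]
        extra = rng.choice(len(pool), size=max(0, size - len(chosen)), replace=False)
        chosen |= {pool[i] for i in extra}
        return frozenset(chosen)

    sigs: list[Signature] = []
    truth.reverser_ids = []
    for i in range(n_reversers):
        n_take_up = max(1, int(round(reverser_fidelity * len(deg_up))))
        n_take_down = max(1, int(round(reverser_fidelity * len(deg_down))))
        take_up = [deg_up[j] for j in rng.choice(len(deg_up), n_take_up, replace=False)]
        take_down = [
            deg_down[j] for j in rng.choice(len(deg_down), n_take_down, replace=False)
        ]
        down = pad(take_up, len(deg_up), forbid=set(take_down))
        up = pad(take_down, len(deg_down), forbid=set(down))
        sid = f"drug:R{i:04d}"
        sigs.append(Signature(sid, f"planted_reverser_{i}", "drug", up, down))
        truth.reverser_ids.append(sid)

    for i in range(n_decoys):
        down_i = rng.choice(len(uni_arr), size=len(deg_up), replace=False)
        down = frozenset(uni_arr[down_i])
        pool = [g for g in universe if g not in down]
        up_i = rng.choice(len(pool), size=len(deg_down), replace=False)
        up = frozenset(pool[j] for j in up_i)
        sigs.append(Signature(f"drug:D{i:04d}", f"decoy_{i}", "drug", up, down))
    return SignatureDB(sigs)
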