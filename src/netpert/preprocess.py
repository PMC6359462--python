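"""Expression-matrix container, gene filtering and normalization.

The :class:`ExpressionMatrix` wraps a genes x samples pandas DataFrame
together with the sample -> condition design and a unit label.  Filtering
follows the GTEx-style rule (keep genes with at least ``min_level``
expression in at least ``min_samples`` samples, pooled across conditions);
normalization is matrix-level quantile normalization (every sample column
is mapped onto the across-sample mean order-statistic distribution).
Correlation stages consume ``log2(quantile-normalized + 1)`` values; the
count-based differential-expression stage consumes raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "filter_low_expression",
    "quantile_normalize",
    "log_transform",
]

CONDITIONS = ("normal", "tumor")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus the condition design.

    Attributes
    ----------
    values : pandas.DataFrame
        Non-negative numeric matrix, index = unique gene symbols,
        columns = unique sample ids.
    design : pandas.Series
        sample id -> condition label ("normal" | "tumor"), covering
        every sample column.
    unit : str
        Free-text unit tag, e.g. "counts", "fpkm", "log2(qnorm+1)".
    """

    values: pd.DataFrame
    design: pd.Series
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene symbols: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:5].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing[:5]}")
        self.design = self.design.loc[self.values.columns]
        bad = sorted(set(self.design) - set(CONDITIONS))
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")
        # raw abundance units cannot go negative; derived (log/normalized)
        # scales may
        if self.unit in ("counts", "fpkm") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.unit} values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def condition_samples(self, condition: str) -> list[str]:
        return self.design.index[self.design == condition].tolist()

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        cols = self.condition_samples(condition)
        return ExpressionMatrix(self.values[cols], self.design.loc[cols], self.unit)

    def replace_values(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.design, unit if unit is not None else self.unit)


def filter_low_expression(
    m: ExpressionMatrix, min_level: float = 0.1, min_samples: int = 2
) -> ExpressionMatrix:
    """Keep genes with value >= ``min_level`` in >= ``min_samples`` samples.

    The count is pooled over all samples, not per condition.  Idempotent;
    an empty result only warns.
    """
    keep = (m.values >= min_level).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return m.replace_values(m.values.loc[keep])


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every sample column onto the mean order-statistic distribution.

    After normalization ``sorted(col_i) == sorted(col_j)`` for all i, j.
    Ties within a column receive the average of the reference values of
    the tied ranks.  Idempotent up to float tolerance.
    """
    if m.values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = m.values.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        # average-rank handling of ties against the reference distribution
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.replace_values(values, unit=f"qnorm({m.unit})")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """``log2(value + pseudocount)``, updating the unit label."""
    if (m.values.to_numpy() < 0).any():
        raise ValueError("log transform requires non-negative values")
    values = np.log2(m.values + pseudocount)
    return m.replace_values(values, unit=f"log2({m.unit}+{pseudocount:g})")
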