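"""Spearman rank correlations among the four topological parameters.

The coefficient is computed as the Pearson product-moment correlation of
tie-averaged ranks. This is deliberate: with tied values (ubiquitous in
rounded published tables and in integer degrees) the popular shortcut
1 - 6*sum(d^2)/(n(n^2-1)) is *not* the Spearman coefficient, and the two
can differ in the second decimal place. Parameters that are constant
across the gene set have no defined rank correlation; such entries are
flagged as undefined (NaN) rather than silently reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .metrics import PARAMETERS, NodeMetrics


def rank_with_ties(values: Sequence[float]) -> list[float]:
    """Ascending ranks 1..n; tied values share the average of their positions."""
    if len(values) == 0:
        raise ValueError("cannot rank an empty list")
    return [float(r) for r in stats.rankdata(values, method="average")]


def spearman_rho(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Spearman correlation: Pearson correlation of tie-averaged ranks."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("inputs must have equal length")
    if xs.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        raise ValueError("constant input has no defined rank correlation")
    rx = np.asarray(rank_with_ties(xs))
    ry = np.asarray(rank_with_ties(ys))
    # explicit product-moment form: exactly symmetric in its arguments
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    return float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))


@dataclass(frozen=True)
class CorrelationMatrix:
    """All-against-all Spearman coefficients over the four parameters.

    ``rho`` is a symmetric 4x4 array with unit diagonal; entries for pairs
    involving a constant parameter are NaN and listed in ``undefined``.
    """

    parameters: tuple[str, ...]
    rho: np.ndarray
    n: int
    undefined: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        k = len(self.parameters)
        if self.rho.shape != (k, k):
            raise ValueError("rho shape does not match parameters")

    def get(self, a: str, b: str) -> float:
        i, j = self.parameters.index(a), self.parameters.index(b)
        return float(self.rho[i, j])

    def pairs(self) -> dict[str, float]:
        """The C(4,2)=6 distinct off-diagonal entries, keyed 'a~b'."""
        out = {}
        for i, a in enumerate(self.parameters):
            for j in range(i + 1, len(self.parameters)):
                out[f"{a}~{self.parameters[j]}"] = float(self.rho[i, j])
        return out

    def to_dict(self) -> dict:
        """JSON-safe form; undefined (constant-parameter) entries become None."""
        pairs = {
            k: (v if np.isfinite(v) else None) for k, v in self.pairs().items()
        }
        return {"n": self.n, "pairs": pairs}


def pairwise_correlations(metrics: Sequence[NodeMetrics]) -> CorrelationMatrix:
    """Spearman rho for each parameter pair across a gene set's records."""
    records = list(metrics)
    if len(records) < 3:
        raise ValueError("need at least 3 gene records")
    columns = {
        p: np.array([r.value(p) for r in records], dtype=float) for p in PARAMETERS
    }
    k = len(PARAMETERS)
    rho = np.eye(k)
    undefined: set[tuple[str, str]] = set()
    for i, a in enumerate(PARAMETERS):
        for j in range(i + 1, k):
            b = PARAMETERS[j]
            if np.unique(columns[a]).size < 2 or np.unique(columns[b]).size < 2:
                rho[i, j] = rho[j, i] = np.nan
                undefined.add((a, b))
            else:
                rho[i, j] = rho[j, i] = spearman_rho(columns[a], columns[b])
    return CorrelationMatrix(
        parameters=PARAMETERS,
        rho=rho,
        n=len(records),
        undefined=frozenset(undefined),
    )
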