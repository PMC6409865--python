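"""Gene-set comparisons against random-set and first-order-neighbor nulls.

A disease gene set is contrasted with equal-size sets of genes sampled
uniformly from the same network (the random null), and with the union of
its first-order neighbors. For each of the four topological parameters the
module reports the raw value lists, per-replicate group summaries, and a
two-sided Mann-Whitney U test between the disease values and the pooled
null values, plus the direction of the median difference.

Sampling is driven entirely by an explicit seed; identical seeds give
byte-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .graphio import GeneSet, Interactome, first_order_neighbors
from .metrics import PARAMETERS, NodeMetrics, compute_all_metrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullConfig:
    """Configuration of the random-null comparison.

    replicates: number of independent random gene-set draws.
    group_size / group_count: grouping used when a large disease list is
    split for the grouped analysis.
    exclude_disease: whether the random pool excludes the disease genes
    (the null sets never overlap the disease set; they may overlap each
    other across replicates).
    """

    replicates: int = 10
    group_size: int = 10
    group_count: int = 10
    seed: int = 0
    exclude_disease: bool = True

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.group_size < 1 or self.group_count < 1:
            raise ValueError("group_size and group_count must be >= 1")


@dataclass(frozen=True)
class ComparisonResult:
    """Per-parameter outcome of a two-population comparison."""

    parameter: str
    disease_values: tuple[float, ...]
    null_values: tuple[float, ...]
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    per_group_p: tuple[float, ...]
    u_statistic: float
    p_value: float
    direction: str  # sign of (median disease - median null): '+', '-' or '0'

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if len(self.group_means) != len(self.group_sds):
            raise ValueError("group_means and group_sds length mismatch")


def sample_random_sets(
    net: Interactome,
    size: int,
    replicates: int,
    exclude: Sequence[str] = (),
    seed: int = 0,
) -> list[GeneSet]:
    """Draw ``replicates`` gene sets of ``size`` uniformly without replacement.

    Each set is drawn from the network's nodes minus ``exclude``; draws are
    independent across replicates (sets may overlap each other but never the
    excluded genes). Fully reproducible from ``seed``.
    """
    pool = sorted(net.nodes - set(exclude))
    if size > len(pool):
        raise ValueError(
            f"cannot sample {size} genes from a pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for i in range(replicates):
        picks = rng.choice(pool, size=size, replace=False)
        out.append(GeneSet(name=f"random_{i + 1}", members=tuple(picks)))
    return out


def partition_into_groups(
    genes: GeneSet, group_count: int, seed: int = 0
) -> list[GeneSet]:
    """Shuffle then split a gene set into near-equal groups.

    Group sizes differ by at most one (a list of 171 genes cannot split
    into 10 truly equal groups). Reproducible from ``seed``.
    """
    if group_count < 1:
        raise ValueError("group_count must be >= 1")
    if group_count > len(genes):
        raise ValueError(
            f"cannot split {len(genes)} genes into {group_count} groups"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(list(genes.members)))
    chunks = np.array_split(shuffled, group_count)
    return [
        GeneSet(name=f"{genes.name}_group{i + 1}", members=tuple(chunk))
        for i, chunk in enumerate(chunks)
    ]


def mann_whitney_u(
    xs: Sequence[float],
    ys: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U for xs, p-value).

    ``method='exact'`` enumerates the permutation null (exact only when
    both samples have <= 10 observations and no ties); ``'normal'`` uses
    the Gaussian approximation with tie-corrected variance and continuity
    correction. ``'auto'`` picks exact when both conditions hold, else
    normal.
    """
    xs = list(xs)
    ys = list(ys)
    if not xs or not ys:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method == "auto":
        tie_free = len(set(xs) | set(ys)) == len(xs) + len(ys)
        method = "exact" if (len(xs) <= 10 and len(ys) <= 10 and tie_free) else "normal"
    if method not in ("exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    scipy_method = "exact" if method == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        xs, ys, alternative=alternative, method=scipy_method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _direction(xs: Sequence[float], ys: Sequence[float]) -> str:
    diff = float(np.median(xs)) - float(np.median(ys))
    if diff > 0:
        return "+"
    if diff < 0:
        return "-"
    return "0"


def _metrics_lookup(
    net: Interactome,
    genes: Sequence[str],
    metrics: Optional[dict[str, NodeMetrics]],
) -> dict[str, NodeMetrics]:
    if metrics is not None:
        missing = [g for g in genes if g not in metrics]
        if missing:
            raise ValueError(f"precomputed metrics missing genes: {missing[:5]}")
        return metrics
    return {m.gene: m for m in compute_all_metrics(net, list(genes))}


def _compare_populations(
    disease_vals: dict[str, list[float]],
    group_vals: dict[str, list[list[float]]],
) -> list[ComparisonResult]:
    results = []
    for param in PARAMETERS:
        xs = disease_vals[param]
        groups = group_vals[param]
        pooled = [v for grp in groups for v in grp]
        u, p = mann_whitney_u(xs, pooled, alternative="two-sided")
        per_group_p = tuple(
            mann_whitney_u(xs, grp, alternative="two-sided")[1] for grp in groups
        )
        results.append(
            ComparisonResult(
                parameter=param,
                disease_values=tuple(xs),
                null_values=tuple(pooled),
                group_means=tuple(float(np.mean(g)) for g in groups),
                group_sds=tuple(
                    float(np.std(g, ddof=1)) if len(g) > 1 else 0.0 for g in groups
                ),
                per_group_p=per_group_p,
                u_statistic=u,
                p_value=p,
                direction=_direction(xs, pooled),
            )
        )
    return results


def _present_disease(net: Interactome, disease: GeneSet) -> list[str]:
    present = [g for g in disease if g in net]
    absent = [g for g in disease if g not in net]
    if absent:
        logger.warning(
            "%d disease gene(s) absent from network (e.g. %s)",
            len(absent),
            absent[:5],
        )
    if len(present) < 2:
        raise ValueError("fewer than 2 disease genes found in the network")
    return present


def compare_gene_set(
    net: Interactome,
    disease: GeneSet,
    config: NullConfig,
    metrics: Optional[dict[str, NodeMetrics]] = None,
) -> list[ComparisonResult]:
    """Disease set versus equal-size random gene sets, one result per parameter.

    Null sets are sampled from the network excluding the disease genes
    (configurable); the pooled null across replicates carries the single
    headline p-value, per-replicate p-values are kept for transparency.
    Pass ``metrics`` (gene -> NodeMetrics for every node involved) to avoid
    recomputation in simulation loops.
    """
    present = _present_disease(net, disease)
    null_sets = sample_random_sets(
        net,
        size=len(present),
        replicates=config.replicates,
        exclude=present if config.exclude_disease else (),
        seed=config.seed,
    )
    involved = list(dict.fromkeys(present + [g for s in null_sets for g in s]))
    lookup = _metrics_lookup(net, involved, metrics)
    disease_vals = {
        p: [lookup[g].value(p) for g in present] for p in PARAMETERS
    }
    group_vals = {
        p: [[lookup[g].value(p) for g in s] for s in null_sets] for p in PARAMETERS
    }
    return _compare_populations(disease_vals, group_vals)


def compare_neighbors(
    net: Interactome,
    disease: GeneSet,
    config: NullConfig,
    metrics: Optional[dict[str, NodeMetrics]] = None,
) -> list[ComparisonResult]:
    """Disease set versus its first-order neighbors (seeds excluded).

    Same result contract as :func:`compare_gene_set`, with the neighbor
    union as the single comparison population.
    """
    present = _present_disease(net, disease)
    neighbors = first_order_neighbors(
        net, GeneSet(name=disease.name, members=tuple(present)), include_seeds=False
    )
    if len(neighbors) == 0:
        raise ValueError("disease genes have no neighbors outside the set")
    involved = list(dict.fromkeys(present + list(neighbors.members)))
    lookup = _metrics_lookup(net, involved, metrics)
    disease_vals = {
        p: [lookup[g].value(p) for g in present] for p in PARAMETERS
    }
    group_vals = {
        p: [[lookup[g].value(p) for g in neighbors.members]] for p in PARAMETERS
    }
    return _compare_populations(disease_vals, group_vals)
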