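"""Alpha and beta diversity and their group-difference tests.

Shannon index (nats), bootstrap richness at a fixed read depth, Bray-Curtis
and weighted UniFrac distance matrices, PERMANOVA on either, and Wilcoxon
rank-sum comparisons with median [IQR] summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import permanova as _skbio_permanova

__all__ = [
    "DiversityResult",
    "PermanovaResult",
    "shannon",
    "bootstrap_richness",
    "richness_per_sample",
    "bray_curtis",
    "weighted_unifrac",
    "permanova",
    "wilcoxon_rank_sum",
]


@dataclass
class DiversityResult:
    per_sample: pd.Series
    metric_name: str
    depth: int | None = None


@dataclass
class PermanovaResult:
    f_statistic: float
    p_value: float
    n_permutations: int
    groups: pd.Series


def shannon(counts_row: np.ndarray | pd.Series) -> float:
    """Shannon diversity H = -sum p_i ln p_i in nats."""
    x = np.asarray(counts_row, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count row has no Shannon index")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bootstrap_richness(
    counts_row: np.ndarray | pd.Series,
    depth: int = 2000,
    n_resamples: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Median number of distinct OTUs among ``depth`` reads drawn with
    replacement from the sample's read-level distribution, over
    ``n_resamples`` resamples."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    x = np.asarray(counts_row, dtype=float)
    total = x.sum()
    if total < depth:
        raise ValueError(f"sample depth {total:.0f} below rarefaction depth {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = x / total
    draws = rng.multinomial(depth, p, size=n_resamples)
    richness = (draws > 0).sum(axis=1)
    return float(np.median(richness))


def richness_per_sample(
    table: pd.DataFrame,
    depth: int = 2000,
    n_resamples: int = 100,
    seed: int = 0,
) -> DiversityResult:
    """Bootstrap richness for every sample with at least ``depth`` reads.

    Shallower samples are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sid, row in table.iterrows():
        if row.sum() < depth:
            warnings.warn(f"sample {sid} below depth {depth}; skipped", stacklevel=2)
            continue
        out[sid] = bootstrap_richness(row.to_numpy(), depth, n_resamples, rng)
    return DiversityResult(pd.Series(out, name=f"richness@{depth}"), "bootstrap_richness", depth)


def bray_curtis(rel: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix of relative abundances."""
    vals = rel.to_numpy(dtype=float)
    if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must sum to 1 (relative abundances)")
    return DistanceMatrix(squareform(pdist(vals, metric="braycurtis")), ids=list(rel.index))


def weighted_unifrac(
    table: pd.DataFrame, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac distance matrix (normalized by default).

    ``table`` holds integer counts (samples x OTUs); per-sample proportions
    are taken internally.  Every taxon with nonzero abundance must be a
    leaf of ``tree``.
    """
    leaves = {t.name for t in tree.tips()}
    present = table.columns[(table > 0).any(axis=0)]
    missing = [t for t in present if t not in leaves]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}")
    return beta_diversity(
        "weighted_unifrac",
        table.to_numpy(),
        ids=list(table.index),
        taxa=list(table.columns),
        tree=tree,
        normalized=normalized,
        validate=False,
    )


def permanova(
    dist: DistanceMatrix,
    groups: pd.Series | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson pseudo-F, one-sided add-one permutation p)."""
    groups = pd.Series(np.asarray(groups), index=list(dist.ids))
    sizes = groups.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    res = _skbio_permanova(dist, groups.to_numpy(), permutations=n_perm, seed=seed)
    return PermanovaResult(
        f_statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_perm,
        groups=groups,
    )


def wilcoxon_rank_sum(
    values_a: np.ndarray | pd.Series, values_b: np.ndarray | pd.Series
) -> dict:
    """Two-sided Wilcoxon rank-sum test with median [IQR] group summaries.

    Uses the exact null distribution below 25 per group (no ties), the
    normal approximation with continuity correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 25 and not ties) else "asymptotic"
    stat = mannwhitneyu(a, b, alternative="two-sided", method=method)

    def _summary(x: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3))}

    return {
        "p": float(stat.pvalue),
        "u_statistic": float(stat.statistic),
        "a": _summary(a),
        "b": _summary(b),
    }
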