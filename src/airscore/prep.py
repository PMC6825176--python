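"""Abundance-table preparation.

Turns raw genus-level count tables into the filtered, log-transformed,
z-scaled matrices the downstream models consume.  The pipeline order is
fixed: depth exclusion -> relative abundance -> prevalence/abundance
filter -> log transform with a half-minimum pseudocount -> per-taxon
z-scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "PreparedMatrix",
    "exclude_low_depth",
    "to_relative",
    "filter_genera",
    "log_transform",
    "zscale",
    "prepare_abundance",
]


@dataclass
class AbundanceTable:
    """A samples x taxa count table with optional taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer counts, indexed by sample id (rows) and taxon
        name (columns).
    taxonomy
        Optional map taxon -> lineage tuple (phylum, ..., genus).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxa names: {dups}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Read depth (row sum) per sample."""
        return self.counts.sum(axis=1)


@dataclass
class PreparedMatrix:
    """Log-scale (optionally z-scaled) abundance matrix over retained taxa."""

    values: pd.DataFrame
    pseudocount: float
    retained_taxa: list[str]
    zscaled: bool = False
    transform_log: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("prepared matrix contains non-finite values")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def exclude_low_depth(
    table: AbundanceTable, min_reads: int = 2000
) -> tuple[AbundanceTable, list[str]]:
    """Drop samples whose total read count is below ``min_reads``.

    The boundary is inclusive: a sample with exactly ``min_reads`` reads is
    retained.  Returns the filtered table and the excluded sample ids.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if table.counts.empty:
        raise ValueError("empty abundance table")
    depths = table.depths
    keep = depths >= min_reads
    excluded = list(depths.index[~keep])
    return AbundanceTable(table.counts.loc[keep], table.taxonomy), excluded


def to_relative(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    counts = table.counts if isinstance(table, AbundanceTable) else table
    depths = counts.sum(axis=1)
    if (depths == 0).any():
        bad = list(depths.index[depths == 0])
        raise ValueError(f"zero-depth samples: {bad}")
    return counts.div(depths, axis=0)


def filter_genera(
    rel: pd.DataFrame,
    min_prevalence: float = 0.10,
    min_mean_abundance: float = 1e-4,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Keep taxa with prevalence >= ``min_prevalence`` AND mean relative
    abundance >= ``min_mean_abundance`` (both boundaries inclusive).

    Returns the filtered matrix and a per-taxon decision log.
    """
    prevalence = (rel > 0).mean(axis=0)
    mean_abund = rel.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (mean_abund >= min_mean_abundance)
    log = {
        str(t): {
            "prevalence": float(prevalence[t]),
            "mean_abundance": float(mean_abund[t]),
            "retained": bool(keep[t]),
        }
        for t in rel.columns
    }
    if not keep.any():
        raise ValueError(
            "no taxa survive filtering at "
            f"min_prevalence={min_prevalence}, min_mean_abundance={min_mean_abundance}"
        )
    return rel.loc[:, keep], log


def log_transform(
    rel_filtered: pd.DataFrame,
    pseudocount: float | None = None,
    per_taxon: bool = False,
) -> PreparedMatrix:
    """Natural-log transform with half the smallest nonzero value as pseudocount.

    The pseudocount is computed globally over the filtered matrix by default
    (``per_taxon=True`` computes one per column); zeros are replaced by the
    pseudocount before taking logs.
    """
    vals = rel_filtered.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("relative abundances must lie in [0, 1]")
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero matrix: cannot derive a pseudocount")
    if per_taxon:
        out = np.empty_like(vals)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            nz = col[col > 0]
            pc = 0.5 * nz.min() if nz.size else 0.5 * nonzero.min()
            out[:, j] = np.log(np.where(col > 0, col, pc))
        pseudo = float(0.5 * nonzero.min())
    else:
        pseudo = float(pseudocount) if pseudocount is not None else float(0.5 * nonzero.min())
        out = np.log(np.where(vals > 0, vals, pseudo))
    values = pd.DataFrame(out, index=rel_filtered.index, columns=rel_filtered.columns)
    return PreparedMatrix(
        values=values,
        pseudocount=pseudo,
        retained_taxa=list(rel_filtered.columns),
        zscaled=False,
    )


def zscale(
    matrix: PreparedMatrix | pd.DataFrame, ddof: int = 0
) -> PreparedMatrix | pd.DataFrame:
    """Center each column to mean 0 and scale to SD 1 (population SD by default)."""
    df = matrix.values if isinstance(matrix, PreparedMatrix) else matrix
    sd = df.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant columns cannot be z-scaled: {bad}")
    scaled = (df - df.mean(axis=0)) / sd
    if isinstance(matrix, PreparedMatrix):
        return PreparedMatrix(
            values=scaled,
            pseudocount=matrix.pseudocount,
            retained_taxa=matrix.retained_taxa,
            zscaled=True,
            transform_log=matrix.transform_log,
        )
    return scaled


def prepare_abundance(
    table: AbundanceTable,
    min_reads: int = 2000,
    min_prevalence: float = 0.10,
    min_mean_abundance: float = 1e-4,
    scale: bool = True,
) -> tuple[PreparedMatrix, list[str]]:
    """Full preparation pipeline: depth-exclude -> relative -> filter -> log -> z-scale.

    Returns the prepared matrix and the list of depth-excluded sample ids.
    """
    kept, excluded = exclude_low_depth(table, min_reads)
    rel = to_relative(kept)
    filtered, decisions = filter_genera(rel, min_prevalence, min_mean_abundance)
    prepared = log_transform(filtered)
    prepared.transform_log = decisions
    if scale:
        prepared = zscale(prepared)
    return prepared, excluded
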