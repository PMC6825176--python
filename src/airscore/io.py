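"""Readers and writers for the pipeline's plain-text formats.

Counts live in TSV (rows = samples, columns = taxa), trees in Newick,
per-child metadata and mediator panels in CSV (blank or ``NA`` mediator
cells mean missing).  Writers and readers round-trip exactly on valid
files; readers validate schemas and name the offending sample/column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .immune import ImmunePanel
from .prep import AbundanceTable
from .synthetic import SyntheticCohort

__all__ = [
    "read_counts",
    "write_counts",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_mediators",
    "write_mediators",
    "write_cohort",
]

METADATA_REQUIRED = ("child_id", "time_years", "event")


def write_counts(table: AbundanceTable | pd.DataFrame, path: str | Path) -> None:
    df = table.counts if isinstance(table, AbundanceTable) else table
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_counts(path: str | Path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric count columns: {non_numeric}")
    return AbundanceTable(df.astype(np.int64))


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path: str | Path, default_length: float | None = None) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if default_length is None:
                raise ValueError(f"branch above {node.name or '<internal>'} has no length")
            node.length = default_length
    return tree


def write_metadata(survival: pd.DataFrame, path: str | Path) -> None:
    survival.to_csv(path, index_label="child_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if df["child_id"].duplicated().any():
        dups = df.loc[df["child_id"].duplicated(), "child_id"].tolist()
        raise ValueError(f"duplicate child_id: {dups}")
    return df.set_index("child_id")


def write_mediators(panel: ImmunePanel, path: str | Path) -> None:
    out = panel.values.where(~panel.missing_mask)
    out.to_csv(path, index_label="sample_id", na_rep="NA")


def read_mediators(path: str | Path, excluded: list[str] | None = None) -> ImmunePanel:
    df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    mask = df.isna()
    # placeholder 1.0 under the mask; imputation replaces it before use
    return ImmunePanel(values=df.fillna(1.0), missing_mask=mask, excluded_samples=excluded or [])


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every container of a simulated cohort; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "genus_counts.tsv",
        "otu_counts": out / "otu_counts.tsv",
        "tree": out / "otu_tree.nwk",
        "metadata": out / "metadata.csv",
        "mediators": out / "mediators.csv",
    }
    write_counts(cohort.abundance, paths["counts"])
    write_counts(cohort.otu_abundance, paths["otu_counts"])
    write_tree(cohort.tree, paths["tree"])
    write_metadata(cohort.survival, paths["metadata"])
    panel = ImmunePanel(
        values=cohort.immune_values,
        missing_mask=cohort.immune_missing,
        excluded_samples=cohort.immune_excluded,
    )
    write_mediators(panel, paths["mediators"])
    (out / "excluded_immune.txt").write_text("\n".join(cohort.immune_excluded) + "\n")
    return paths
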