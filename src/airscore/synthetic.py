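"""Synthetic infant-airway cohort generator with planted ground truth.

Emulates the statistical structure of a prospective birth cohort of ~600
children with a single early-life airway sample each: compositional
genus-level 16S counts (Dirichlet-multinomial around log-normal base
proportions, a few dominant genera), a time-to-asthma outcome whose
log-hazard depends on planted taxa and categorical covariates, a correlated
20-mediator immune panel partially driven by those taxa, and a random
phylogeny over OTUs for UniFrac.  Identical (config, seed) pairs reproduce
the cohort byte-for-byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .prep import AbundanceTable

__all__ = [
    "MEDIATOR_NAMES",
    "SEASONS",
    "SimulationConfig",
    "PlantedTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_tree",
]

#: Cytokine/chemokine panel assayed in nasal mucosal lining fluid.
MEDIATOR_NAMES = (
    "TNF-a", "IL-1b", "CCL2", "CCL17", "IL-8", "IL-6", "IL-10", "IL-12p70",
    "IL-13", "IL-17A", "IL-4", "IL-5", "IFN-g", "CCL4", "CCL11", "CCL13",
    "CCL22", "CCL26", "IL-2", "IL-33",
)

SEASONS = ("winter", "spring", "summer", "autumn")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one synthetic cohort.

    ``planted_taxa`` maps taxon index -> log-hazard per SD of the z-scaled
    log relative abundance of that taxon.  ``covariate_effects`` maps
    covariate name (``paternal_asthma``, ``older_siblings``,
    ``season_spring``/``season_summer``/``season_autumn``; winter is the
    reference season) -> log-hazard.  ``mediator_loadings`` is a length-20
    vector of loadings of each mediator (log-concentration scale) on the
    planted-taxa signal.
    """

    n_children: int = 600
    n_taxa: int = 60
    n_otus_per_taxon: int = 5
    read_depth_range: tuple[int, int] = (2000, 60000)
    planted_taxa: dict[int, float] = field(default_factory=dict)
    baseline_hazard_rate: float = 0.045
    follow_up_years: float = 6.0
    mediator_loadings: tuple[float, ...] | None = None
    mediator_noise_sd: float = 1.0
    mediator_noise_corr: float = 0.3
    missing_rate: float = 0.012
    immune_excluded_rate: float = 0.07
    covariate_effects: dict[str, float] = field(default_factory=dict)
    concentration: float = 50.0
    base_log_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.read_depth_range
        if lo < 1 or lo > hi:
            raise ValueError("read_depth_range must satisfy 1 <= min <= max")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.follow_up_years <= 0:
            raise ValueError("follow_up_years must be positive")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be positive")
        if self.n_children < 1 or self.n_taxa < 1 or self.n_otus_per_taxon < 1:
            raise ValueError("cohort dimensions must be positive")
        for idx, eff in self.planted_taxa.items():
            if not (0 <= idx < self.n_taxa):
                raise ValueError(f"planted taxon index {idx} outside [0, {self.n_taxa})")
            if not np.isfinite(eff):
                raise ValueError(f"non-finite planted effect for taxon {idx}")
        for name, eff in self.covariate_effects.items():
            if not np.isfinite(eff):
                raise ValueError(f"non-finite covariate effect for {name}")
        if self.mediator_loadings is not None and len(self.mediator_loadings) != len(
            MEDIATOR_NAMES
        ):
            raise ValueError(f"mediator_loadings must have {len(MEDIATOR_NAMES)} entries")


@dataclass
class PlantedTruth:
    """Ground truth behind a simulated cohort."""

    planted_taxa: dict[str, float]
    mediator_loadings: pd.Series
    covariate_effects: dict[str, float]
    taxa_signal: pd.Series
    linear_predictor: pd.Series


@dataclass
class SyntheticCohort:
    """All containers of one simulated cohort, indexed by child id."""

    abundance: AbundanceTable
    otu_abundance: AbundanceTable
    tree: TreeNode
    survival: pd.DataFrame
    immune_values: pd.DataFrame
    immune_missing: pd.DataFrame
    immune_excluded: list[str]
    truth: PlantedTruth
    config: SimulationConfig

    @property
    def child_ids(self) -> list[str]:
        return list(self.abundance.sample_ids)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_tree(n_otus: int, seed: int, names: list[str] | None = None) -> TreeNode:
    """Random rooted binary tree with ``n_otus`` leaves and positive branch lengths.

    Built by iteratively joining random pairs of subtrees; lengths are
    exponential(0.1) + 0.01 so every branch is strictly positive.
    """
    if n_otus < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"otu{i:04d}" for i in range(n_otus)]
    nodes = list(names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bi, bj = rng.exponential(0.1, size=2) + 0.01
        merged = f"({nodes[i]}:{bi:.6f},{nodes[j]}:{bj:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    # newick readers treat underscores as spaces unless told otherwise
    return TreeNode.read(io.StringIO(nodes[0] + ";"), convert_underscores=False)


def _simulate_counts(cfg: SimulationConfig, rng: np.random.Generator):
    """Dirichlet-multinomial genus counts plus an OTU-level split."""
    # sorted so low taxon indices are the dominant genera; planted indices
    # therefore map to taxa that survive the prevalence/abundance filter
    base_log = np.sort(rng.normal(0.0, cfg.base_log_sigma, size=cfg.n_taxa))[::-1]
    base = np.exp(base_log)
    base /= base.sum()
    depths = rng.integers(
        cfg.read_depth_range[0], cfg.read_depth_range[1] + 1, size=cfg.n_children
    )
    counts = np.empty((cfg.n_children, cfg.n_taxa), dtype=np.int64)
    for i in range(cfg.n_children):
        p = rng.dirichlet(cfg.concentration * base)
        counts[i] = rng.multinomial(depths[i], p)
    # fixed within-genus OTU composition shared across samples
    otu_props = rng.dirichlet(np.ones(cfg.n_otus_per_taxon), size=cfg.n_taxa)
    otu_counts = np.zeros((cfg.n_children, cfg.n_taxa * cfg.n_otus_per_taxon), dtype=np.int64)
    for j in range(cfg.n_taxa):
        cols = slice(j * cfg.n_otus_per_taxon, (j + 1) * cfg.n_otus_per_taxon)
        for i in range(cfg.n_children):
            if counts[i, j] > 0:
                otu_counts[i, cols] = rng.multinomial(counts[i, j], otu_props[j])
    return counts, otu_counts


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort from ``config``; deterministic given (config, seed).

    Counts are Dirichlet-multinomial around log-normal genus base
    proportions.  The per-child log-hazard is the sum of planted effects
    times z-scaled log relative abundances plus covariate effects; event
    times are exponential with rate ``baseline * exp(eta)``, administratively
    censored at ``follow_up_years``.  Mediators are ``loading * signal``
    plus equicorrelated Gaussian noise on the log-concentration scale, with
    a missing-at-random mask.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    child_ids = [f"child{i:04d}" for i in range(cfg.n_children)]
    taxa = [f"g{j:03d}" for j in range(cfg.n_taxa)]
    otu_names = [
        f"g{j:03d}_otu{k}" for j in range(cfg.n_taxa) for k in range(cfg.n_otus_per_taxon)
    ]

    counts, otu_counts = _simulate_counts(cfg, rng)
    abundance = AbundanceTable(pd.DataFrame(counts, index=child_ids, columns=taxa))
    otu_abundance = AbundanceTable(pd.DataFrame(otu_counts, index=child_ids, columns=otu_names))
    tree = simulate_tree(
        max(len(otu_names), 2), seed=int(rng.integers(2**31)), names=otu_names
    )

    # z-scaled log relative abundance of planted taxa -> linear predictor
    rel = counts / counts.sum(axis=1, keepdims=True)
    nonzero_min = rel[rel > 0].min()
    logrel = np.log(np.where(rel > 0, rel, 0.5 * nonzero_min))
    eta = np.zeros(cfg.n_children)
    signal = np.zeros(cfg.n_children)
    planted_named: dict[str, float] = {}
    for idx, eff in sorted(cfg.planted_taxa.items()):
        z = _zscore(logrel[:, idx])
        eta += eff * z
        signal += eff * z
        planted_named[taxa[idx]] = float(eff)
    if planted_named:
        signal = _zscore(signal)

    # covariates
    paternal = rng.random(cfg.n_children) < 0.20
    siblings = rng.random(cfg.n_children) < 0.50
    season = rng.choice(len(SEASONS), size=cfg.n_children)
    sensitized = rng.random(cfg.n_children) < 0.20
    cov = cfg.covariate_effects
    eta = eta + cov.get("paternal_asthma", 0.0) * paternal
    eta = eta + cov.get("older_siblings", 0.0) * siblings
    for s_idx, s_name in enumerate(SEASONS[1:], start=1):
        eta = eta + cov.get(f"season_{s_name}", 0.0) * (season == s_idx)

    # exponential event times, administrative censoring
    rate = cfg.baseline_hazard_rate * np.exp(eta)
    raw_times = rng.exponential(1.0 / rate)
    event = raw_times <= cfg.follow_up_years
    time_years = np.minimum(raw_times, cfg.follow_up_years)

    survival = pd.DataFrame(
        {
            "child_id": child_ids,
            "time_years": time_years,
            "event": event.astype(int),
            "paternal_asthma": paternal.astype(int),
            "older_siblings": siblings.astype(int),
            "season": [SEASONS[s] for s in season],
            "sensitized": sensitized.astype(int),
        }
    ).set_index("child_id")

    # immune mediator panel on log-concentration scale, exponentiated to raw
    m = len(MEDIATOR_NAMES)
    loadings = (
        np.asarray(cfg.mediator_loadings, dtype=float)
        if cfg.mediator_loadings is not None
        else np.zeros(m)
    )
    base_level = rng.normal(2.0, 1.0, size=m)
    rho = cfg.mediator_noise_corr
    if cfg.mediator_noise_sd > 0:
        cov_mat = cfg.mediator_noise_sd**2 * (rho * np.ones((m, m)) + (1 - rho) * np.eye(m))
        noise = rng.multivariate_normal(
            np.zeros(m), cov_mat, size=cfg.n_children, method="cholesky"
        )
    else:
        noise = np.zeros((cfg.n_children, m))
    log_conc = base_level + np.outer(signal, loadings) + noise
    immune_values = pd.DataFrame(np.exp(log_conc), index=child_ids, columns=list(MEDIATOR_NAMES))
    immune_missing = pd.DataFrame(
        rng.random((cfg.n_children, m)) < cfg.missing_rate,
        index=child_ids,
        columns=list(MEDIATOR_NAMES),
    )
    # never blank out an entire child
    all_missing = immune_missing.all(axis=1)
    immune_missing.loc[all_missing, MEDIATOR_NAMES[0]] = False
    n_excl = int(round(cfg.immune_excluded_rate * cfg.n_children))
    immune_excluded = sorted(rng.choice(child_ids, size=n_excl, replace=False).tolist())

    truth = PlantedTruth(
        planted_taxa=planted_named,
        mediator_loadings=pd.Series(loadings, index=list(MEDIATOR_NAMES)),
        covariate_effects=dict(cov),
        taxa_signal=pd.Series(signal, index=child_ids),
        linear_predictor=pd.Series(eta, index=child_ids),
    )
    return SyntheticCohort(
        abundance=abundance,
        otu_abundance=otu_abundance,
        tree=tree,
        survival=survival,
        immune_values=immune_values,
        immune_missing=immune_missing,
        immune_excluded=immune_excluded,
        truth=truth,
        config=cfg,
    )


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Convenience: a cohort with no planted taxon, covariate or mediator effects."""
    return replace(SimulationConfig(seed=seed), **overrides)
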