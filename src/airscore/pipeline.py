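"""End-to-end pipeline driver.

Runs prep -> diversity -> differential abundance -> bacterial score ->
immune profile -> mediation on one cohort's files, writing each stage's
artifact plus a machine-readable manifest (inputs, parameters, seed,
checksums).  All randomness derives from one top-level seed; each stage
draws a named substream so stages are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .diversity import bray_curtis, permanova, richness_per_sample, shannon, weighted_unifrac, wilcoxon_rank_sum
from .immune import immune_score, mediator_associations, pca_adjustment, preprocess_panel
from .mediation import mediate
from .prep import prepare_abundance, to_relative, zscale
from .spls import DEFAULT_GRID, assemble_score, cv_select
from .survival import adjusted_association, differential_abundance, kaplan_meier, score_tertiles

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("prep", "diversity", "diffabund", "score", "immune", "mediate")


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    mediators: str | None = None
    tree: str | None = None
    otu_counts: str | None = None
    out_dir: str = "airscore_out"
    min_reads: int = 2000
    min_prevalence: float = 0.10
    min_mean_abundance: float = 1e-4
    cv_folds: int = 10
    cv_repeats: int = 20
    grid: tuple = DEFAULT_GRID
    permutations: int = 10_000
    richness_depth: int = 2000
    knn_k: int = 10
    pca_components: int = 4
    n_boot: int = 1000
    adjust: tuple[str, ...] = ("paternal_asthma", "older_siblings", "season")
    horizon: float = 6.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory bundle and writes artifacts."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    timings: dict[str, float] = {}

    def _run(stage, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        timings[stage] = time.perf_counter() - t0

    table = aio.read_counts(cfg.counts)
    survival = aio.read_metadata(cfg.metadata)

    def prep_stage():
        prepared_log, excluded = prepare_abundance(
            table, cfg.min_reads, cfg.min_prevalence, cfg.min_mean_abundance, scale=False
        )
        prepared = zscale(prepared_log)
        prepared.values.to_csv(out / "prepared_matrix.tsv", sep="\t", index_label="sample_id")
        (out / "prep_provenance.json").write_text(
            json.dumps(
                {
                    "min_reads": cfg.min_reads,
                    "min_prevalence": cfg.min_prevalence,
                    "min_mean_abundance": cfg.min_mean_abundance,
                    "pseudocount": prepared.pseudocount,
                    "excluded_samples": excluded,
                    "retained_taxa": prepared.retained_taxa,
                },
                indent=1,
            )
        )
        bundle["prepared"] = prepared
        bundle["prepared_log"] = prepared_log
        bundle["excluded"] = excluded

    def diversity_stage():
        prepared = bundle["prepared"]
        ids = prepared.values.index
        surv = survival.loc[ids]
        counts = table.counts.loc[ids]
        rel = to_relative(counts)
        alpha = pd.DataFrame({"shannon": [shannon(r) for _, r in counts.iterrows()]}, index=ids)
        groups = surv["event"].map({1: "asthma", 0: "no_asthma"})
        div_summary: dict = {"n": int(len(ids))}
        wil = wilcoxon_rank_sum(alpha.loc[groups == "asthma", "shannon"],
                                alpha.loc[groups == "no_asthma", "shannon"])
        div_summary["shannon"] = wil
        if cfg.otu_counts:
            otus = aio.read_counts(cfg.otu_counts)
            rich = richness_per_sample(
                otus.counts.loc[ids], cfg.richness_depth, seed=_stage_seed(cfg.seed, "diversity")
            )
            alpha["richness"] = rich.per_sample
            both = alpha.dropna(subset=["richness"])
            div_summary["richness"] = wilcoxon_rank_sum(
                both.loc[groups.loc[both.index] == "asthma", "richness"],
                both.loc[groups.loc[both.index] == "no_asthma", "richness"],
            )
        bc = bray_curtis(rel)
        perm_seed = _stage_seed(cfg.seed, "diversity")
        bc_res = permanova(bc, groups, n_perm=cfg.permutations, seed=perm_seed)
        div_summary["bray_curtis"] = {"F": bc_res.f_statistic, "p": bc_res.p_value}
        if cfg.tree and cfg.otu_counts:
            tree = aio.read_tree(cfg.tree)
            otus = aio.read_counts(cfg.otu_counts)
            wu = weighted_unifrac(otus.counts.loc[ids], tree)
            wu_res = permanova(wu, groups, n_perm=cfg.permutations, seed=perm_seed)
            div_summary["weighted_unifrac"] = {"F": wu_res.f_statistic, "p": wu_res.p_value}
        alpha.to_csv(out / "alpha_diversity.csv", index_label="sample_id")
        (out / "diversity_summary.json").write_text(json.dumps(div_summary, indent=1))
        bundle["diversity"] = div_summary

    def diffabund_stage():
        da = differential_abundance(bundle["prepared"].values, survival)
        da.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
        bundle["diffabund"] = da

    def score_stage():
        prepared = bundle["prepared"]
        ids = prepared.values.index
        y = survival.loc[ids, "event"].to_numpy()
        # cv_select z-scales within folds; hand it the unscaled log matrix
        cv = cv_select(
            bundle["prepared_log"].values, y, grid=cfg.grid, n_folds=cfg.cv_folds, n_repeats=cfg.cv_repeats,
            seed=_stage_seed(cfg.seed, "score"),
        )
        score = assemble_score(cv, y)
        score.per_child.to_csv(out / "bacterial_score.csv", index_label="child_id")
        score.importance.rename("relative_importance").to_csv(
            out / "importance.tsv", sep="\t", index_label="taxon"
        )
        cv.median_by_grid.rename("median_auc").to_csv(
            out / "cv_diagnostics.csv", index_label="n_selected"
        )
        assoc = adjusted_association(score.per_child, survival, list(cfg.adjust))
        tert = score_tertiles(score.per_child)
        km = kaplan_meier(
            survival.loc[ids, "time_years"], survival.loc[ids, "event"], tert, cfg.horizon
        )
        bundle["score"] = score
        bundle["score_association"] = assoc
        bundle["km"] = {k: {kk: vv for kk, vv in v.items() if kk != "survival"} for k, v in km.items()}
        (out / "score_association.json").write_text(
            json.dumps(
                {
                    "hr_per_sd": assoc.hr,
                    "ci95": assoc.ci95,
                    "p": assoc.p,
                    "n": assoc.n,
                    "adjusted_for": assoc.adjusted_for,
                    "km_tertiles": bundle["km"],
                },
                indent=1,
            )
        )

    def immune_stage():
        if not cfg.mediators:
            bundle["immune"] = None
            return
        panel = aio.read_mediators(cfg.mediators)
        prepared_panel = preprocess_panel(panel, cfg.knn_k)
        score = bundle["score"]
        ids = prepared_panel.log_values.index.intersection(score.per_child.index)
        selected = set(score.importance.index)
        others = [t for t in bundle["prepared"].retained_taxa if t not in selected]
        # with every taxon in the score there are no "other bacteria" to adjust for
        pcs = (
            pca_adjustment(bundle["prepared"].values.loc[ids, others], cfg.pca_components)
            if len(others) >= cfg.pca_components
            else None
        )
        assoc = mediator_associations(prepared_panel, score.per_child, pcs)
        pd.DataFrame(
            [
                {"mediator": a.mediator, "ratio_per_sd": a.ratio_per_sd,
                 "ci_low": a.ci95[0], "ci_high": a.ci95[1], "p": a.p}
                for a in assoc
            ]
        ).to_csv(out / "mediator_associations.tsv", sep="\t", index=False)
        iscore = immune_score(
            prepared_panel, score, n_folds=cfg.cv_folds, n_repeats=cfg.cv_repeats,
            seed=_stage_seed(cfg.seed, "immune"),
        )
        iscore.per_child.to_csv(out / "immune_score.csv", index_label="child_id")
        bundle["immune"] = {"associations": assoc, "score": iscore}

    def mediate_stage():
        if bundle.get("immune") is None:
            bundle["mediation"] = None
            return
        res = mediate(
            bundle["score"].per_child,
            bundle["immune"]["score"].per_child,
            survival,
            covariates=list(cfg.adjust),
            n_boot=cfg.n_boot,
            seed=_stage_seed(cfg.seed, "mediate"),
        )
        payload = asdict(res)
        (out / "mediation.json").write_text(json.dumps(payload, indent=1))
        (out / "mediation_summary.txt").write_text(
            "Bacterial asthma score alone: HR {:.2f}; combined analysis {:.2f}; "
            "immune mediator score HR {:.2f}; proportion mediated {:.1f}% "
            "[{:.1f}-{:.1f}%], p = {:.4g}\n".format(
                res.hr_total, res.hr_direct, res.hr_mediator,
                100 * res.proportion_mediated,
                100 * res.ci95_pm[0], 100 * res.ci95_pm[1], res.p_pm,
            )
        )
        bundle["mediation"] = res

    for stage, fn in zip(
        _STAGES, (prep_stage, diversity_stage, diffabund_stage, score_stage, immune_stage, mediate_stage)
    ):
        _run(stage, fn)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
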