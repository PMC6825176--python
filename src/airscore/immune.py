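"""Immune-mediator panel processing and the immune mediator score.

The 20-mediator mucosal-lining-fluid panel is imputed (k-nearest-neighbour
on raw log concentrations), standardized per mediator, total-sum normalized
per sample, log transformed and z-scored.  Per-mediator linear models relate
log concentrations to the bacterial asthma score, adjusted for the common
variation of other bacteria via four principal components.  A one-component
sparse-PLS model of the mediators against the continuous bacterial score,
cross-validated on held-out Spearman correlation, yields the immune
mediator score from out-of-fold predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer

from .spls import BacterialScore, CvResult, assemble_score, cv_select

__all__ = [
    "ImmunePanel",
    "PreparedPanel",
    "MediatorAssociation",
    "ImmuneScore",
    "preprocess_panel",
    "pca_adjustment",
    "mediator_associations",
    "immune_score",
]


@dataclass
class ImmunePanel:
    """Raw mediator concentrations with a missingness mask and exclusions."""

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask must match values shape")
        frac = float(self.missing_mask.to_numpy().mean())
        if frac >= 0.20:
            raise ValueError(f"missing fraction {frac:.1%} exceeds 20%")

    @property
    def mediator_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PreparedPanel:
    """Processed panel: z-scored values for modelling, log-scale values for
    concentration-ratio models, and the imputed raw concentrations."""

    zscored: pd.DataFrame
    log_values: pd.DataFrame
    imputed_raw: pd.DataFrame


@dataclass
class MediatorAssociation:
    mediator: str
    ratio_per_sd: float
    ci95: tuple[float, float]
    p: float


@dataclass
class ImmuneScore:
    per_child: pd.Series
    weights: pd.Series
    cv_correlation: float
    cv: CvResult


def preprocess_panel(
    panel: ImmunePanel, k_neighbors: int = 10, median_standardize: bool = True
) -> PreparedPanel:
    """Impute then normalize the mediator panel.

    Missing cells are imputed by the unweighted mean of the ``k_neighbors``
    nearest samples (Euclidean distance over mediators observed in both
    samples) on raw log concentrations, before any normalization.  The
    normalization pipeline is: per-mediator standardization (division by the
    mediator median), per-sample total-sum normalization, log transform,
    per-mediator z-score.
    """
    values = panel.values.drop(index=panel.excluded_samples, errors="ignore")
    mask = panel.missing_mask.loc[values.index]
    raw = values.where(~mask)
    if raw.isna().all(axis=1).any():
        bad = list(raw.index[raw.isna().all(axis=1)])
        raise ValueError(f"samples with all mediators missing: {bad}")
    log_raw = np.log(raw)
    if mask.to_numpy().any():
        imputer = KNNImputer(n_neighbors=k_neighbors, weights="uniform")
        imputed_log = pd.DataFrame(
            imputer.fit_transform(log_raw), index=log_raw.index, columns=log_raw.columns
        )
    else:
        imputed_log = log_raw
    imputed_raw = np.exp(imputed_log)

    std = imputed_raw / imputed_raw.median(axis=0) if median_standardize else imputed_raw
    tss = std.div(std.sum(axis=1), axis=0)
    log_values = np.log(tss)
    z = (log_values - log_values.mean(axis=0)) / log_values.std(axis=0, ddof=0)
    return PreparedPanel(zscored=z, log_values=log_values, imputed_raw=imputed_raw)


def pca_adjustment(other_bacteria: pd.DataFrame, n_components: int = 4) -> pd.DataFrame:
    """First ``n_components`` principal-component scores of the centered
    "other bacteria" matrix, for use as adjustment covariates."""
    rank = np.linalg.matrix_rank(other_bacteria - other_bacteria.mean(axis=0))
    if rank < n_components:
        warnings.warn(
            f"matrix rank {rank} below {n_components} components; trailing "
            "components carry no variance",
            stacklevel=2,
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(other_bacteria.to_numpy())
    return pd.DataFrame(
        scores,
        index=other_bacteria.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


def mediator_associations(
    prepared: PreparedPanel, score: pd.Series, pcs: pd.DataFrame | None = None
) -> list[MediatorAssociation]:
    """Per-mediator linear model of log concentration on the score (+ PCs).

    ``ratio_per_sd`` is the multiplicative change in concentration per SD of
    the bacterial asthma score: exp of the score coefficient.
    """
    ids = prepared.log_values.index.intersection(score.index)
    X = pd.DataFrame({"score": score.loc[ids]})
    if pcs is not None:
        X = X.join(pcs.loc[ids])
        corr = np.corrcoef(np.column_stack([X["score"], pcs.loc[ids]]), rowvar=False)[0, 1:]
        if np.abs(corr).max() > 0.95:
            warnings.warn("score nearly collinear with PCA adjustment", stacklevel=2)
    X = sm.add_constant(X)
    out = []
    for mediator in prepared.log_values.columns:
        fit = sm.OLS(prepared.log_values.loc[ids, mediator], X).fit()
        beta = float(fit.params["score"])
        lo, hi = fit.conf_int().loc["score"]
        out.append(
            MediatorAssociation(
                mediator=str(mediator),
                ratio_per_sd=float(np.exp(beta)),
                ci95=(float(np.exp(lo)), float(np.exp(hi))),
                p=float(fit.pvalues["score"]),
            )
        )
    return out


def immune_score(
    prepared: PreparedPanel,
    target: BacterialScore | pd.Series,
    grid=(1, 2, 3, 4, 5, 7, 10, 15, 20),
    n_folds: int = 10,
    n_repeats: int = 20,
    seed: int = 0,
) -> ImmuneScore:
    """One-component sparse PLS of mediators against the continuous
    bacterial score; out-of-fold predictions form the immune mediator score.

    Sparsity is chosen by the highest median held-out Spearman correlation.
    """
    y = target.per_child if isinstance(target, BacterialScore) else target
    ids = prepared.log_values.index.intersection(y.index)
    x = prepared.log_values.loc[ids]
    cv = cv_select(
        x, y.loc[ids], grid=grid, n_folds=n_folds, n_repeats=n_repeats, seed=seed,
        criterion="spearman",
    )
    score = assemble_score(cv, y.loc[ids])
    med = np.median(np.abs(cv.loadings[cv.chosen_index]), axis=0)
    weights = pd.Series(med, index=cv.feature_names)
    return ImmuneScore(
        per_child=score.per_child.rename("immune_score"),
        weights=weights[weights > 0].sort_values(ascending=False),
        cv_correlation=float(np.nanmedian(cv.criterion_values[cv.chosen_index])),
        cv=cv,
    )
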