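"""Cross-validated one-component sparse PLS and the bacterial asthma score.

The score is built the way the original analysis prescribes: a single
sparse-PLS component of z-scaled log genus abundances against asthma-ever
(binary, centered), with the number of retained taxa chosen by repeated
stratified 10-fold cross-validation of the held-out AUC (highest median
AUC; ties prefer the sparser model).  Held-out component scores from the
left-out folds are averaged across repeats into a per-child score, oriented
so that higher values mean higher asthma risk, and z-scaled.  Relative
importance of a taxon is the median of its absolute loading across all
folds and repeats, divided by the sum of those medians.

Centering/scaling parameters and the sparsity threshold are estimated from
training folds only, so the out-of-fold score carries no optimism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "SplsFit",
    "CvResult",
    "BacterialScore",
    "spls_component",
    "auc",
    "cv_select",
    "assemble_score",
    "DEFAULT_GRID",
]

#: Candidate numbers of retained predictors for cross-validated selection.
DEFAULT_GRID = (1, 2, 3, 5, 7, 10, 15, 20, 30, None)  # None -> all predictors


@dataclass
class SplsFit:
    """One sparse-PLS component: unit-norm weights, zeros outside the
    selected set."""

    weights: pd.Series
    n_selected: int
    threshold: float

    def transform(self, x_scaled: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = x_scaled.to_numpy() if isinstance(x_scaled, pd.DataFrame) else x_scaled
        return x @ self.weights.to_numpy()


@dataclass
class CvResult:
    """Cross-validation record: AUC (or Spearman) per grid value and fold."""

    grid: list[int]
    criterion_values: np.ndarray  # (len(grid), n_repeats * n_folds)
    chosen: int
    chosen_index: int
    oof_scores: np.ndarray  # (len(grid), n_repeats, n_samples)
    loadings: np.ndarray  # (len(grid), n_repeats * n_folds, n_features)
    feature_names: list[str]
    sample_ids: list[str]
    fold_assignments: np.ndarray  # (n_repeats, n_samples)
    criterion: str
    seed: int

    @property
    def median_by_grid(self) -> pd.Series:
        return pd.Series(np.median(self.criterion_values, axis=1), index=self.grid)


@dataclass
class BacterialScore:
    """Out-of-fold sPLS score (z-scaled, higher = higher risk) and taxon
    importances (fractions summing to 1 over selected taxa)."""

    per_child: pd.Series
    importance: pd.Series
    cv: CvResult
    source: str = "out-of-fold"
    orientation: int = 1
    extras: dict = field(default_factory=dict)


def spls_component(x, y, n_keep: int, feature_names=None) -> SplsFit:
    """One sparse-PLS component by soft-thresholded covariance weights.

    ``x`` must be z-scaled (columns mean 0, SD 1) and ``y`` centered.  The
    weight vector is the covariance c = x'y/(n-1) soft-thresholded at the
    (n_keep+1)-th largest |c| and normalized to unit Euclidean norm; with
    ``n_keep`` equal to the number of columns no shrinkage is applied.  Ties
    in |c| at the threshold are broken toward the lexicographically first
    feature name.
    """
    xv = x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    if feature_names is None:
        feature_names = (
            list(x.columns) if isinstance(x, pd.DataFrame) else [f"f{j}" for j in range(xv.shape[1])]
        )
    yv = np.asarray(y, dtype=float)
    if np.ptp(yv) == 0:
        raise ValueError("y must be non-constant")
    n, p = xv.shape
    if not 1 <= n_keep <= p:
        raise ValueError(f"n_keep must lie in [1, {p}]")
    c = xv.T @ (yv - yv.mean()) / (n - 1)
    # rank by |c| descending, names ascending for deterministic ties
    order = sorted(range(p), key=lambda j: (-abs(c[j]), str(feature_names[j])))
    selected = order[:n_keep]
    lam = abs(c[order[n_keep]]) if n_keep < p else 0.0
    w = np.zeros(p)
    w[selected] = np.sign(c[selected]) * (np.abs(c[selected]) - lam)
    if np.any(w[selected] == 0):  # exact tie at the threshold: fall back to hard keep
        w[selected] = c[selected]
    w /= np.linalg.norm(w)
    return SplsFit(
        weights=pd.Series(w, index=feature_names),
        n_selected=int(np.count_nonzero(w)),
        threshold=float(lam),
    )


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _held_out_metric(scores, y, criterion: str) -> float:
    if criterion == "auc":
        return auc(scores, y)
    rho = spearmanr(scores, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def cv_select(
    x: pd.DataFrame,
    y,
    grid=DEFAULT_GRID,
    n_folds: int = 10,
    n_repeats: int = 20,
    seed: int = 0,
    criterion: str = "auc",
) -> CvResult:
    """Choose the sparsity level by repeated cross-validation.

    ``x`` is the log-abundance matrix (unscaled); per fold, centering and
    scaling parameters come from the training samples only.  ``criterion``
    is ``"auc"`` for a binary outcome (stratified folds) or ``"spearman"``
    for a continuous target (plain folds).  The chosen sparsity maximizes
    the median criterion over all folds x repeats; ties prefer fewer
    predictors.
    """
    yv = np.asarray(y, dtype=float)
    n, p = x.shape
    grid_resolved = sorted({p if g is None else int(g) for g in grid if g is None or g <= p})
    if not grid_resolved:
        raise ValueError("empty candidate grid")
    n_cells = n_repeats * n_folds
    crit = np.full((len(grid_resolved), n_cells), np.nan)
    oof = np.full((len(grid_resolved), n_repeats, n), np.nan)
    loadings = np.zeros((len(grid_resolved), n_cells, p))
    assignments = np.zeros((n_repeats, n), dtype=int)
    root = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_repeats)]

    for r in range(n_repeats):
        if criterion == "auc":
            splitter = StratifiedKFold(n_folds, shuffle=True, random_state=repeat_seeds[r])
            splits = splitter.split(np.zeros(n), yv.astype(int))
        else:
            splitter = KFold(n_folds, shuffle=True, random_state=repeat_seeds[r])
            splits = splitter.split(np.zeros(n))
        for f, (tr, te) in enumerate(splits):
            assignments[r, te] = f
            if criterion == "auc" and len(np.unique(yv[te])) < 2:
                warnings.warn("single-class fold skipped", stacklevel=2)
                continue
            mu = x.iloc[tr].mean(axis=0)
            sd = x.iloc[tr].std(axis=0, ddof=0).replace(0, 1.0)
            xtr = (x.iloc[tr] - mu) / sd
            xte = (x.iloc[te] - mu) / sd
            ytr = yv[tr] - yv[tr].mean()
            for gi, k in enumerate(grid_resolved):
                fit = spls_component(xtr, ytr, k)
                t_te = fit.transform(xte)
                crit[gi, r * n_folds + f] = _held_out_metric(t_te, yv[te], criterion)
                oof[gi, r, te] = t_te
                loadings[gi, r * n_folds + f] = fit.weights.to_numpy()

    medians = np.nanmedian(crit, axis=1)
    chosen_index = int(np.argmax(medians))  # argmax takes the first (sparsest) on ties
    return CvResult(
        grid=grid_resolved,
        criterion_values=crit,
        chosen=grid_resolved[chosen_index],
        chosen_index=chosen_index,
        oof_scores=oof,
        loadings=loadings,
        feature_names=list(x.columns),
        sample_ids=list(x.index),
        fold_assignments=assignments,
        criterion=criterion,
        seed=seed,
    )


def assemble_score(cv: CvResult, y) -> BacterialScore:
    """Combine held-out predictions at the chosen sparsity into a per-child
    score; compute median-loading relative importances.

    Held-out component scores are averaged across repeats, oriented to
    correlate positively with the outcome, and z-scaled.  Importance of
    taxon j is the median over folds x repeats of |loading_j|, divided by
    the sum of these medians over taxa with a nonzero median.
    """
    yv = np.asarray(y, dtype=float)
    per_rep = cv.oof_scores[cv.chosen_index]  # (n_repeats, n_samples)
    if np.isnan(per_rep).all(axis=0).any():
        raise AssertionError("some child was never held out")
    raw = np.nanmean(per_rep, axis=0)
    orientation = 1
    corr = np.corrcoef(raw, yv)[0, 1]
    if np.isfinite(corr) and corr < 0:
        orientation = -1
        raw = -raw
    score = (raw - raw.mean()) / raw.std()
    med = np.median(np.abs(cv.loadings[cv.chosen_index]), axis=0)
    selected = med > 0
    importance = pd.Series(0.0, index=cv.feature_names)
    importance[selected] = med[selected] / med[selected].sum()
    importance = importance[importance > 0].sort_values(ascending=False)
    return BacterialScore(
        per_child=pd.Series(score, index=cv.sample_ids, name="bacterial_score"),
        importance=importance,
        cv=cv,
        orientation=orientation,
    )
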