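"""Cox proportional-hazards machinery and asthma phenotype classification.

Per-genus differential abundance with Benjamini-Hochberg FDR, adjusted
score-asthma associations (HR per SD), Kaplan-Meier tertile risks, logistic
regression odds ratios, and age-at-onset phenotype labels.

Cox models use Efron tie handling (lifelines' default) with Wald confidence
intervals and p-values.  Season of birth enters as three dummies against a
winter reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "CoxResult",
    "MonotoneLikelihoodError",
    "SeparationError",
    "cox_fit",
    "differential_abundance",
    "adjusted_association",
    "score_tertiles",
    "kaplan_meier",
    "logistic_or",
    "classify_phenotype",
    "bh_qvalues",
]

SEASON_DUMMIES = ("season_spring", "season_summer", "season_autumn")


class MonotoneLikelihoodError(RuntimeError):
    """Cox partial likelihood has no finite maximizer (complete separation)."""


class SeparationError(RuntimeError):
    """Logistic likelihood diverges (perfectly predictive covariate)."""


@dataclass
class CoxResult:
    """Estimate for the predictor of interest from a Cox model.

    ``beta`` is the log-hazard per unit of the predictor (per SD when the
    input was z-scaled); ``hr`` = exp(beta); ``ci95`` is the Wald interval
    on the HR scale.
    """

    beta: float
    hr: float
    ci95: tuple[float, float]
    p: float
    n: int
    n_events: int
    adjusted_for: list[str] = field(default_factory=list)
    se: float = float("nan")
    all_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.hr > 0


def _design_frame(
    times, events, x, covariate_matrix: pd.DataFrame | None, name: str
) -> tuple[pd.DataFrame, str]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if isinstance(x, pd.Series):
        name = x.name or name
        x = x.to_numpy()
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("predictor contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if events.sum() < 1:
        raise ValueError("no events observed")
    df = pd.DataFrame({"time": times, "event": events, name: x})
    if covariate_matrix is not None:
        cov = covariate_matrix.reset_index(drop=True)
        # constant adjustment columns carry no information and break the fit
        cov = cov.loc[:, cov.nunique() > 1]
        df = pd.concat([df, cov], axis=1)
    return df, name


def cox_fit(
    times,
    events,
    x,
    covariate_matrix: pd.DataFrame | None = None,
    name: str = "x",
) -> CoxResult:
    """Cox partial-likelihood fit (Efron ties); Wald CI and p for ``x``.

    Monotone likelihood (e.g. a predictor perfectly ordering the events) is
    raised as :class:`MonotoneLikelihoodError`.
    """
    df, name = _design_frame(times, events, x, covariate_matrix, name)
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise MonotoneLikelihoodError(f"Cox fit for {name!r} diverged: {err}") from err
    beta = float(fitter.params_[name])
    se = float(fitter.standard_errors_[name])
    if abs(beta) > 8 or se > 50:
        raise MonotoneLikelihoodError(
            f"Cox estimate for {name!r} diverged (beta={beta:.2f}, se={se:.2f})"
        )
    lo, hi = beta - 1.959964 * se, beta + 1.959964 * se
    return CoxResult(
        beta=beta,
        hr=float(np.exp(beta)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p=float(fitter.summary.loc[name, "p"]),
        n=len(df),
        n_events=int(df["event"].sum()),
        adjusted_for=[] if covariate_matrix is None else list(covariate_matrix.columns),
        se=se,
        all_params={str(k): float(v) for k, v in fitter.params_.items()},
    )


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(prepared_values: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    """One unadjusted Cox fit per genus; BH q-values over retained genera.

    ``prepared_values`` is the z-scaled log abundance matrix
    (samples x taxa); ``survival`` must carry ``time_years`` and ``event``
    for the same samples.  Output rows (taxon, beta, hr, ci, p, q) are
    sorted by p.
    """
    missing = prepared_values.index.difference(survival.index)
    if len(missing):
        raise ValueError(f"samples without survival records: {list(missing)[:5]}")
    surv = survival.loc[prepared_values.index]
    rows = []
    for taxon in prepared_values.columns:
        res = cox_fit(surv["time_years"], surv["event"], prepared_values[taxon], name=str(taxon))
        rows.append(
            {
                "taxon": taxon,
                "beta": res.beta,
                "hr": res.hr,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "p": res.p,
                "n": res.n,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_qvalues(table["p"])
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def covariate_design(survival: pd.DataFrame, adjust: list[str]) -> pd.DataFrame:
    """Expand adjustment covariates into a numeric design (season -> 3 dummies,
    winter reference)."""
    cols = {}
    for cov in adjust:
        if cov == "season":
            for dummy in SEASON_DUMMIES:
                season_name = dummy.removeprefix("season_")
                cols[dummy] = (survival["season"] == season_name).astype(float)
        else:
            cols[cov] = survival[cov].astype(float)
    return pd.DataFrame(cols, index=survival.index)


def adjusted_association(
    score: pd.Series,
    survival: pd.DataFrame,
    adjust: list[str] = ("paternal_asthma", "older_siblings", "season"),
) -> CoxResult:
    """Cox fit of asthma on the (z-scaled) score, adjusted for covariates."""
    surv = survival.loc[score.index]
    design = covariate_design(surv, list(adjust)) if adjust else None
    return cox_fit(
        surv["time_years"],
        surv["event"],
        score,
        covariate_matrix=design,
        name=score.name or "score",
    )


def score_tertiles(score: pd.Series) -> pd.Series:
    """Tertile labels T1 (lowest) .. T3, ties broken by stable sample order."""
    order = np.argsort(score.to_numpy(), kind="stable")
    n = len(score)
    labels = np.empty(n, dtype=object)
    bounds = [round(n / 3), round(2 * n / 3)]
    labels[order[: bounds[0]]] = "T1"
    labels[order[bounds[0] : bounds[1]]] = "T2"
    labels[order[bounds[1] :]] = "T3"
    return pd.Series(labels, index=score.index, name="tertile")


def kaplan_meier(
    times, events, groups: pd.Series, horizon: float = 6.0
) -> dict[str, dict]:
    """Per-group product-limit survival and cumulative risk 1 - S(horizon)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = pd.Series(np.asarray(groups))
    out: dict[str, dict] = {}
    for label in sorted(groups.unique()):
        mask = (groups == label).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        s_h = float(kmf.predict(horizon))
        out[str(label)] = {
            "n": int(mask.sum()),
            "risk_at_horizon": 1.0 - s_h,
            "survival": kmf.survival_function_,
        }
    return out


def logistic_or(
    outcome,
    score: pd.Series,
    adjust_design: pd.DataFrame | None = None,
) -> dict:
    """Maximum-likelihood logistic fit; OR per SD of score with Wald CI."""
    y = np.asarray(outcome, dtype=int)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    name = score.name or "score"
    X = pd.DataFrame({name: np.asarray(score, dtype=float)})
    if adjust_design is not None:
        X = pd.concat([X, adjust_design.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as err:  # PerfectSeparationError in older statsmodels
            raise SeparationError(str(err)) from err
    beta = float(fit.params[name])
    se = float(fit.bse[name])
    if abs(beta) > 12 or se > 50:
        raise SeparationError(f"logistic estimate diverged (beta={beta:.2f})")
    return {
        "or": float(np.exp(beta)),
        "ci95": (float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se))),
        "p": float(fit.pvalues[name]),
        "n": len(y),
    }


def classify_phenotype(
    diagnosis_age: float | None,
    remission_by_6: bool | None,
    active_at_6: bool,
) -> frozenset[str]:
    """Age-at-onset asthma phenotype labels.

    ``transient_early``: diagnosis before age 3 with remission before 6;
    ``persistent``: diagnosis before 3 still ongoing at 6; ``late_onset``:
    diagnosis at or after age 3.  ``current_at_6`` overlays any of these
    when the diagnosis is active at age 6.  No asthma -> empty set.
    """
    if diagnosis_age is None:
        if active_at_6:
            raise ValueError("active diagnosis at 6 without a diagnosis age")
        return frozenset()
    if remission_by_6 and active_at_6:
        raise ValueError("remission before 6 and active at 6 are inconsistent")
    labels: set[str] = set()
    if diagnosis_age < 3.0:
        labels.add("transient_early" if remission_by_6 else "persistent")
    else:
        labels.add("late_onset")
    if active_at_6:
        labels.add("current_at_6")
    return frozenset(labels)
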