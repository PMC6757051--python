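"""Case-control logistic modelling.

Clinical predictor selection follows a two-phase recipe: a bidirectional
(add-or-drop-one-term) stepwise search minimizing AIC starting from the
intercept-only model, followed by backward elimination of terms whose
multivariate Wald p-value exceeds 0.05.  Metabolites enter an existing
clinical model as z-scored natural-log intensities, so their odds ratio
is per one standard deviation of log intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .containers import (
    GRAVIDITY_LEVELS,
    IntensityMatrix,
    ROLE_SAMPLE,
    SMOKING_LEVELS,
    analysis_subset,
    case_labels,
)
from .preprocess import STEP_LOG

#: default clinical candidate terms (matching variables age/BMI excluded
#: by default: they are design variables, balanced by construction)
DEFAULT_CANDIDATES = [
    "height",
    "infant_sex",
    "smoking",
    "fertility_treatment",
    "prev_miscarriage",
    "gravidity",
    "vaginal_bleeding_15w",
    "infection_15w",
]

TERM_LEVELS = {"smoking": SMOKING_LEVELS, "gravidity": GRAVIDITY_LEVELS}

#: |coefficient| beyond which a logit fit is flagged as separated
SEPARATION_COEF = 15.0

#: |r| beyond which an added metabolite draws a collinearity diagnostic
COLLINEARITY_R = 0.8


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[pd.DataFrame, dict]:
    """Numeric design matrix (no intercept column) plus term -> columns map.

    Categorical terms expand to treatment-coded dummies against their first
    level ("no smoking", gravidity "1").
    """
    cols: dict[str, pd.Series] = {}
    term_map: dict[str, list[str]] = {}
    for term in terms:
        s = data[term]
        if term in TERM_LEVELS:
            names = []
            for lvl in TERM_LEVELS[term][1:]:
                name = f"{term}[{lvl}]"
                cols[name] = (s == lvl).astype(float)
                names.append(name)
            term_map[term] = names
        elif s.dtype == object:
            levels = sorted(s.dropna().unique())
            names = []
            for lvl in levels[1:]:
                name = f"{term}[{lvl}]"
                cols[name] = (s == lvl).astype(float)
                names.append(name)
            term_map[term] = names
        else:
            cols[term] = s.astype(float)
            term_map[term] = [term]
    X = pd.DataFrame(cols, index=data.index)
    return X, term_map


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with its inputs kept for reuse."""

    terms: list[str]
    params: pd.Series            # log-odds scale, incl. "const"
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    llf: float
    linear_predictor: pd.Series  # eta_i = x_i' beta, incl. intercept
    n: int
    y: pd.Series
    X: pd.DataFrame              # design without intercept
    term_map: dict[str, list[str]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)

    def odds_ratios(self) -> pd.DataFrame:
        z = 1.959963984540054
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "or": np.exp(self.params),
                "or_lo": np.exp(self.params - z * self.bse),
                "or_hi": np.exp(self.params + z * self.bse),
                "p": self.pvalues,
            }
        )
        return out.drop(index="const", errors="ignore")

    @property
    def converged(self) -> bool:
        return "separation" not in self.flags and "non-convergence" not in self.flags


def fit_logistic(y, X: pd.DataFrame, terms: list[str] | None = None,
                 term_map: dict | None = None) -> LogisticFit:
    """Fit a logistic regression of ``y`` on the numeric design ``X``.

    Non-convergence and (quasi-)separation are reported as flags on the
    returned fit, never silently.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="case")
    classes = set(np.unique(y))
    if classes - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("y must contain both classes")
    if X.shape[1]:
        full = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValueError("design matrix is collinear (rank deficient)")
    flags: list[str] = []
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["const", *X.columns]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y.to_numpy(), exog)
        try:
            res = model.fit(disp=0, maxiter=200, method="newton")
        except Exception:
            res = model.fit(disp=0, maxiter=500, method="bfgs")
            flags.append("newton-failed")
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            flags.append("separation")
        elif issubclass(w.category, ConvergenceWarning):
            flags.append("non-convergence")
    if np.max(np.abs(res.params)) > SEPARATION_COEF and "separation" not in flags:
        flags.append("separation")
    params = pd.Series(res.params, index=names)
    eta = pd.Series(exog @ res.params, index=X.index, name="eta")
    return LogisticFit(
        terms=list(terms) if terms is not None else list(X.columns),
        params=params,
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        aic=float(res.aic),
        llf=float(res.llf),
        linear_predictor=eta,
        n=len(y),
        y=y,
        X=X.copy(),
        term_map=dict(term_map) if term_map else {c: [c] for c in X.columns},
        flags=flags,
    )


def _fit_terms(y, data: pd.DataFrame, terms: list[str]) -> LogisticFit:
    X, term_map = build_design(data, terms)
    return fit_logistic(y, X, terms=terms, term_map=term_map)


def stepwise_select(
    y,
    data: pd.DataFrame,
    candidates: list[str] | None = None,
    p_remove: float = 0.05,
) -> LogisticFit:
    """Two-phase clinical model selection.

    Phase 1: from the intercept-only model, repeatedly apply the single
    add-or-drop move that lowers AIC the most, until no move improves it.
    Phase 2: repeatedly drop the term with the largest Wald p above
    ``p_remove`` and refit.  The full step trace (every AIC evaluated, and
    every elimination) is attached to the returned fit.
    """
    candidates = list(candidates) if candidates is not None else list(DEFAULT_CANDIDATES)
    y = np.asarray(y, dtype=float)
    trace: list[dict] = []
    current: list[str] = []
    current_fit = _fit_terms(y, data, current)
    step = 0
    while True:
        moves = []
        for term in candidates:
            action = "drop" if term in current else "add"
            trial = [t for t in current if t != term] if action == "drop" else [*current, term]
            try:
                aic = _fit_terms(y, data, trial).aic
            except ValueError:
                continue
            moves.append({"action": action, "term": term, "aic": aic})
        best = min(moves, key=lambda m: m["aic"], default=None)
        trace.append({"phase": 1, "step": step, "current": list(current),
                      "current_aic": current_fit.aic, "moves": moves,
                      "chosen": best if best and best["aic"] < current_fit.aic - 1e-9 else None})
        if best is None or best["aic"] >= current_fit.aic - 1e-9:
            break
        current = ([t for t in current if t != best["term"]]
                   if best["action"] == "drop" else [*current, best["term"]])
        current_fit = _fit_terms(y, data, current)
        step += 1

    # phase 2: backward elimination at p_remove
    while current:
        fit = _fit_terms(y, data, current)
        term_p = {
            term: float(np.min(fit.pvalues[fit.term_map[term]]))
            for term in current
        }
        worst = max(term_p, key=term_p.get)
        if term_p[worst] <= p_remove:
            break
        trace.append({"phase": 2, "dropped": worst, "p": term_p[worst]})
        current = [t for t in current if t != worst]
    final = _fit_terms(y, data, current)
    final.trace = trace
    return final


def subject_log_intensity(matrix: IntensityMatrix, compound: str) -> pd.Series:
    """Natural-log intensity per subject (applies log unless already logged)."""
    if compound not in matrix.values.columns:
        raise KeyError(f"compound {compound!r} not in matrix")
    study = matrix.role_mask(ROLE_SAMPLE)
    vals = matrix.values.loc[study, compound].to_numpy(dtype=float)
    subjects = matrix.sample_meta.loc[study, "subject_id"].to_numpy()
    s = pd.Series(vals, index=subjects, name=compound)
    if not matrix.has_step(STEP_LOG):
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.log(s.where(s > 0))
    return s


def add_metabolite(
    base: LogisticFit,
    compound: str,
    matrix: IntensityMatrix,
    standardize: bool = True,
) -> LogisticFit:
    """Refit the base model with a z-scored natural-log metabolite added.

    Standardization (mean 0, SD 1) is computed over exactly the subjects
    entering the refit, so the metabolite's odds ratio is per one standard
    deviation of log intensity in the analysis sample.
    """
    logint = subject_log_intensity(matrix, compound)
    col = logint.reindex(base.X.index)
    keep = col.notna()
    X = base.X.loc[keep].copy()
    y = base.y.loc[keep]
    col = col.loc[keep].astype(float)
    sd = float(col.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError(f"compound {compound!r} has zero variance; cannot standardize")
    name = f"log({compound})"
    X[name] = (col - col.mean()) / sd if standardize else col
    term_map = {**base.term_map, name: [name]}
    fit = fit_logistic(y, X, terms=[*base.terms, name], term_map=term_map)
    numeric = [c for c in base.X.columns if base.X[c].nunique() > 2]
    if numeric:
        corr = base.X.loc[keep, numeric].corrwith(X[name]).abs()
        if (corr > COLLINEARITY_R).any():
            fit.flags.append("collinear-metabolite")
    return fit


def clinical_model_frame(clinical: pd.DataFrame, threshold: float = 37.0) -> pd.DataFrame:
    """Analysis frame (indexed by subject) with derived case indicator."""
    sub = analysis_subset(clinical, threshold).set_index("subject_id")
    frame = sub.copy()
    frame["case"] = case_labels(sub, threshold).astype(float)
    return frame


def threshold_sensitivity(
    clinical: pd.DataFrame,
    matrix: IntensityMatrix,
    compound: str,
    clinical_terms: list[str],
    thresholds: list[float],
    min_cases: int = 5,
) -> pd.DataFrame:
    """Per-SD metabolite odds ratio as the preterm threshold is lowered.

    For each threshold t, cases are deliveries before t and controls remain
    the term deliveries (>= 37 weeks); the clinical+metabolite model is
    refit and the metabolite's per-SD OR and Wald p reported.  Thresholds
    leaving fewer than ``min_cases`` cases are flagged, not fit.
    """
    records = []
    for t in thresholds:
        frame = clinical_model_frame(clinical, t)
        n_case = int(frame["case"].sum())
        if n_case < min_cases:
            records.append({"threshold": t, "n_case": n_case, "or": np.nan,
                            "p": np.nan, "flag": "too few cases"})
            continue
        base = _fit_terms(frame["case"], frame, clinical_terms)
        fit = add_metabolite(base, compound, matrix)
        name = f"log({compound})"
        ors = fit.odds_ratios()
        records.append(
            {
                "threshold": t,
                "n_case": int(fit.y.sum()),
                "n": fit.n,
                "or": float(ors.loc[name, "or"]),
                "or_lo": float(ors.loc[name, "or_lo"]),
                "or_hi": float(ors.loc[name, "or_hi"]),
                "p": float(ors.loc[name, "p"]),
                "flag": ";".join(fit.flags),
            }
        )
    return pd.DataFrame.from_records(records)
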