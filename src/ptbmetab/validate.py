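"""Model utility assessment: ROC/AUC and permutation tests.

Three permutation tests of "is this model better than random?":

* the linear-predictor difference test — the fitted model's mean linear
  predictor in cases minus controls, compared against the same statistic
  from models refit to label-shuffled data;
* the random-forest out-of-bag error test — OOB error of a forest grown
  on the real labels versus forests grown on shuffled labels;
* (in :mod:`ptbmetab.splsda`) the balanced-error-rate test.

All use the add-one permutation p-value
``p = (1 + #{replicates at least as extreme}) / (1 + B)`` with the label
shuffle keeping group sizes fixed, so ``p`` can never be smaller than
``1/(B+1)`` (0.001 at the conventional B = 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .models import LogisticFit, fit_logistic


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    permuted: np.ndarray
    p: float
    direction: str              # "greater" or "less": how extremeness is read
    seed: int
    B: int
    extra: dict = field(default_factory=dict)

    @property
    def n_beaten(self) -> int:
        """Permuted replicates strictly less extreme than the observation."""
        if self.direction == "greater":
            return int((self.permuted < self.observed).sum())
        return int((self.permuted > self.observed).sum())


def add_one_p(observed: float, permuted: np.ndarray, direction: str) -> float:
    permuted = np.asarray(permuted, dtype=float)
    if direction == "greater":
        k = int((permuted >= observed).sum())
    elif direction == "less":
        k = int((permuted <= observed).sum())
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return (1 + k) / (1 + len(permuted))


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    score_name: str
    n_case: int
    n_control: int
    flags: list[str] = field(default_factory=list)


def roc_auc(scores, labels, score_name: str = "score") -> RocCurve:
    """Threshold-sweep ROC curve; ties get half credit, so the AUC equals
    the Mann-Whitney U of the case scores divided by n_case * n_control."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    flags = []
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group equal scores into single thresholds
    distinct = np.r_[True, np.diff(s) != 0]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    thresh_idx = np.r_[np.nonzero(np.r_[distinct[1:], True])[0]]
    tpr = np.r_[0.0, tp[thresh_idx] / n1]
    fpr = np.r_[0.0, fp[thresh_idx] / n0]
    auc = float(np.trapezoid(tpr, fpr))
    if np.unique(scores).size == 1:
        flags.append("degenerate: constant scores")
        auc = 0.5
    return RocCurve(fpr, tpr, auc, score_name, n1, n0, flags)


def compare_aucs(fit_a: LogisticFit, fit_b: LogisticFit) -> tuple[RocCurve, RocCurve, float]:
    """In-sample ROC curves of two fits on the same subjects, plus the AUC
    difference (b minus a)."""
    common = fit_a.linear_predictor.index
    if not common.equals(fit_b.linear_predictor.index):
        raise ValueError("fits were computed on different subject sets")
    roc_a = roc_auc(fit_a.linear_predictor.to_numpy(), fit_a.y.to_numpy(),
                    "+".join(fit_a.terms) or "intercept")
    roc_b = roc_auc(fit_b.linear_predictor.to_numpy(), fit_b.y.to_numpy(),
                    "+".join(fit_b.terms) or "intercept")
    return roc_a, roc_b, roc_b.auc - roc_a.auc


def _lp_diff(fit: LogisticFit, y: np.ndarray) -> float:
    eta = fit.linear_predictor.to_numpy()
    return float(eta[y == 1].mean() - eta[y == 0].mean())


def lp_difference_test(
    y,
    X: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.01,
) -> PermutationResult:
    """Linear-predictor difference permutation test of model utility.

    The observed statistic is the case-control difference in mean linear
    predictor from the model fit to the real labels.  Each replicate
    shuffles the labels (group sizes fixed), refits the SAME model formula
    and recomputes the difference; the p-value is one-sided (observed
    greater).  More than ``max_failure_rate`` non-converged refits aborts.
    """
    y = np.asarray(y, dtype=float)
    observed_fit = fit_logistic(y, X)
    observed = _lp_diff(observed_fit, y)
    rng = np.random.default_rng(seed)
    permuted = np.empty(B)
    failures = 0
    flagged = 0
    for b in range(B):
        y_perm = rng.permutation(y)
        # a (quasi-)separated refit still yields a well-defined statistic:
        # D is a deterministic function of (y_perm, X), so including it
        # preserves the exactness of the permutation test.  Only refits
        # that error out or return a non-finite D count as failures.
        try:
            fit = fit_logistic(y_perm, X)
            d = _lp_diff(fit, y_perm)
            if not np.isfinite(d):
                failures += 1
                d = np.nan
            elif not fit.converged:
                flagged += 1
            permuted[b] = d
        except Exception:
            failures += 1
            permuted[b] = np.nan
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"{failures}/{B} permutation refits failed"
        )
    permuted = np.where(np.isnan(permuted), np.inf, permuted)  # conservative
    p = add_one_p(observed, permuted, "greater")
    return PermutationResult(
        "linear predictor case-control difference", observed, permuted, p,
        "greater", seed, B,
        {"refit_failures": failures, "flagged_refits": flagged},
    )


DEFAULT_FOREST = {"n_estimators": 500, "max_features": "sqrt"}


def rf_oob_test(
    features: pd.DataFrame,
    labels,
    B: int = 1000,
    seed: int = 0,
    **forest_params,
) -> PermutationResult:
    """Random-forest out-of-bag error permutation test.

    Observed statistic: OOB misclassification rate of a forest grown on the
    real labels.  Replicates grow a fresh forest (seed derived from the
    master seed) on shuffled labels; one-sided p, observed LESS than
    permuted.  The OOB accuracy is reported alongside.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("features must be a non-empty 2-D table")
    if X.shape[1] == 1 and np.std(X[:, 0]) == 0:
        raise ValueError("single constant feature")
    params = {**DEFAULT_FOREST, **forest_params}
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(B + 1)

    def oob_error(Xa, ya, rs) -> float:
        forest = RandomForestClassifier(
            oob_score=True, bootstrap=True, random_state=int(rs % (2**31)), **params
        )
        forest.fit(Xa, ya)
        return 1.0 - float(forest.oob_score_)

    observed = oob_error(X, y, child[0])
    rng = np.random.default_rng(seed)
    permuted = np.empty(B)
    for b in range(B):
        permuted[b] = oob_error(X, rng.permutation(y), child[b + 1])
    p = add_one_p(observed, permuted, "less")
    return PermutationResult(
        "random-forest OOB error", observed, permuted, p, "less", seed, B,
        {"oob_accuracy": 1.0 - observed, "forest_params": params},
    )
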