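"""Two-class sparse partial least squares discriminant analysis.

The class membership is encoded as a column-centred indicator matrix Y.
Each component extracts the dominant left singular vector of the
cross-covariance X'Y of the (deflated, standardized) predictor block with
Y, sparsified by keeping the ``keep_x`` largest-magnitude weights and
renormalizing to unit norm.  X and Y are deflated by regression on the
component score, so successive scores are orthogonal.  New samples are
classified by the nearest class centroid in score space under the
Mahalanobis metric of the pooled within-class score covariance.

Model size (1-3 components, five predictors each) is chosen by the
balanced error rate (mean of the two per-class error rates) under
stratified repeated k-fold cross-validation, and model significance by a
label-permutation test on that same error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .validate import PermutationResult, add_one_p


@dataclass
class SplsdaFit:
    weights: np.ndarray        # p x ncomp sparse X-weights (unit norm cols)
    x_loadings: np.ndarray     # p x ncomp regression loadings for deflation
    scores: np.ndarray         # n x ncomp training scores
    classes: np.ndarray        # the two class labels, sorted
    centroids: np.ndarray      # 2 x ncomp class means in score space
    within_cov: list[np.ndarray]   # pooled within-class score cov per ncomp
    center: np.ndarray
    scale: np.ndarray
    keep_x: int
    ncomp: int
    flags: list[str] = field(default_factory=list)


def _standardize(X: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (X - center) / scale


def fit(X, y, ncomp: int = 3, keep_x: int = 5) -> SplsdaFit:
    """Fit a sparse PLS-DA model.

    Deterministic: the weight vector comes from the SVD of the p x 2
    cross-covariance, not from a random initialization.  ``keep_x`` larger
    than the number of usable predictors is clamped (flagged); a component
    with vanishing cross-covariance ends the extraction early (flagged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if np.isnan(X).any():
        raise ValueError("X must be column-complete (impute upstream)")
    n, p = X.shape
    flags: list[str] = []

    center = X.mean(axis=0)
    # population SD: makes the fit exactly invariant to sample replication
    scale = X.std(axis=0)
    dead = ~(scale > 0)
    if dead.any():
        flags.append(f"{int(dead.sum())} zero-variance predictors excluded")
        scale = np.where(dead, 1.0, scale)
    keep = min(keep_x, int((~dead).sum()))
    if keep < keep_x:
        flags.append(f"keep_x clamped to {keep}")
    Xc = _standardize(X, center, scale)
    Xc[:, dead] = 0.0
    Y = np.column_stack([(y == c).astype(float) for c in classes])
    Yc = Y - Y.mean(axis=0)

    weights, loadings, scores = [], [], []
    Xd, Yd = Xc.copy(), Yc.copy()
    for _ in range(ncomp):
        M = Xd.T @ Yd
        if np.linalg.norm(M) < 1e-12:
            flags.append("vanishing cross-covariance; fewer components returned")
            break
        U, _, _ = np.linalg.svd(M, full_matrices=False)
        w = U[:, 0]
        # sparsity: hard top-keep selection by magnitude, then renormalize
        if keep < p:
            cutoff = np.argsort(np.abs(w), kind="stable")[: p - keep]
            w = w.copy()
            w[cutoff] = 0.0
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            flags.append("vanishing sparse weight; fewer components returned")
            break
        w = w / norm
        if w[np.argmax(np.abs(w))] < 0:   # deterministic sign convention
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            flags.append("vanishing score; fewer components returned")
            break
        pl = Xd.T @ t / tt
        q = Yd.T @ t / tt
        Xd = Xd - np.outer(t, pl)
        Yd = Yd - np.outer(t, q)
        weights.append(w)
        loadings.append(pl)
        scores.append(t)

    if not weights:
        raise ValueError("no component could be extracted (zero cross-covariance)")
    W = np.column_stack(weights)
    P = np.column_stack(loadings)
    T = np.column_stack(scores)
    h_max = T.shape[1]
    centroids = np.vstack([T[y == c].mean(axis=0) for c in classes])
    within = []
    for h in range(1, h_max + 1):
        S = np.zeros((h, h))
        dof = 0
        for k, c in enumerate(classes):
            D = T[y == c, :h] - centroids[k, :h]
            S += D.T @ D
            dof += D.shape[0] - 1
        within.append(S / max(dof, 1))
    return SplsdaFit(W, P, T, classes, centroids, within, center, scale,
                     keep, h_max, flags)


def transform(fit: SplsdaFit, X_new, use_ncomp: int | None = None) -> np.ndarray:
    """Project new samples into score space with the training deflation."""
    h = fit.ncomp if use_ncomp is None else use_ncomp
    if h > fit.ncomp:
        raise ValueError(f"use_ncomp={h} exceeds fitted {fit.ncomp}")
    Xd = _standardize(np.asarray(X_new, dtype=float), fit.center, fit.scale)
    T = np.empty((Xd.shape[0], h))
    for j in range(h):
        t = Xd @ fit.weights[:, j]
        T[:, j] = t
        Xd = Xd - np.outer(t, fit.x_loadings[:, j])
    return T


def predict(fit: SplsdaFit, X_new, use_ncomp: int | None = None):
    """Nearest-centroid Mahalanobis classification in score space.

    Returns (labels, distances) where ``distances`` is samples x 2
    (squared Mahalanobis distance to each class centroid).  A singular
    score covariance is ridge-regularized (eps = 1e-8 x trace) and the
    fit is flagged.
    """
    h = fit.ncomp if use_ncomp is None else use_ncomp
    T = transform(fit, X_new, h)
    S = fit.within_cov[h - 1].copy()
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        Sinv = None
    if Sinv is None or np.linalg.cond(S) > 1e12:
        eps = 1e-8 * max(np.trace(S), 1e-300)
        Sinv = np.linalg.inv(S + eps * np.eye(h))
        if "singular score covariance ridge-regularized" not in fit.flags:
            fit.flags.append("singular score covariance ridge-regularized")
    d = np.empty((T.shape[0], 2))
    for k in range(2):
        diff = T - fit.centroids[k, :h]
        d[:, k] = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
    labels = fit.classes[np.argmin(d, axis=1)]
    return labels, d


def balanced_error_rate(y_true, y_pred, classes) -> float:
    """Mean of the two per-class misclassification rates."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    errs = []
    for c in classes:
        mask = y_true == c
        if mask.sum() == 0:
            continue
        errs.append(float((y_pred[mask] != c).mean()))
    return float(np.mean(errs))


@dataclass
class CvReport:
    ber: dict[int, float]          # ncomp -> mean BER over folds x repeats
    ber_sd: dict[int, float]       # spread of per-fold BERs
    selected_ncomp: int
    folds: int
    repeats: int
    seed: int
    flags: list[str] = field(default_factory=list)


def _stratified_folds(y, folds, rng):
    """Fold assignment with each class spread evenly across folds."""
    y = np.asarray(y)
    assign = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def cv_select(
    X,
    y,
    max_ncomp: int = 3,
    keep_x: int = 5,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CvReport:
    """Choose the number of components by repeated stratified k-fold CV.

    For each candidate size the model is refit on every training fold and
    the Mahalanobis balanced error rate evaluated on the held-out fold;
    the mean over folds x repeats is reported and the smallest-BER size
    selected, ties broken toward fewer components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    flags: list[str] = []
    if counts.min() < folds:
        folds = int(counts.min())
        flags.append(f"folds reduced to {folds} (smallest class)")
    if folds < 2:
        raise ValueError("smallest class too small for cross-validation")
    rng = np.random.default_rng(seed)
    bers: dict[int, list[float]] = {h: [] for h in range(1, max_ncomp + 1)}
    for _ in range(repeats):
        assign = _stratified_folds(y, folds, rng)
        for f in range(folds):
            test = assign == f
            model = fit(X[~test], y[~test], ncomp=max_ncomp, keep_x=keep_x)
            for h in range(1, max_ncomp + 1):
                hh = min(h, model.ncomp)
                pred, _ = predict(model, X[test], use_ncomp=hh)
                bers[h].append(balanced_error_rate(y[test], pred, classes))
    mean_ber = {h: float(np.mean(v)) for h, v in bers.items()}
    sd_ber = {h: float(np.std(v, ddof=1)) for h, v in bers.items()}
    selected = min(mean_ber, key=lambda h: (round(mean_ber[h], 12), h))
    return CvReport(mean_ber, sd_ber, selected, folds, repeats, seed, flags)


def permutation_significance(
    X,
    y,
    B: int = 1000,
    seed: int = 0,
    max_ncomp: int = 3,
    keep_x: int = 5,
    folds: int = 10,
    repeats: int = 10,
) -> PermutationResult:
    """Label-permutation test of the cross-validated balanced error rate.

    The observed statistic is the selected model's BER on the real labels;
    each replicate reruns the full selection on shuffled labels.  One-sided
    p-value: observed BER less than permuted.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31))
    report = cv_select(X, y, max_ncomp, keep_x, folds, repeats, seed=cv_seed)
    observed = report.ber[report.selected_ncomp]
    permuted = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(y)
        rep = cv_select(X, y_perm, max_ncomp, keep_x, folds, repeats,
                        seed=int(rng.integers(2**31)))
        permuted[b] = rep.ber[rep.selected_ncomp]
    p = add_one_p(observed, permuted, "less")
    return PermutationResult(
        "sPLS-DA cross-validated balanced error rate", float(observed),
        permuted, p, "less", seed, B,
        {"selected_ncomp": report.selected_ncomp, "cv": report.ber},
    )
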