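"""Cross-validated choice of the number of PLS components.

The number of components A is chosen by k-fold cross-validation (7 folds by
default, stratified by outcome since unstratified folds on an unbalanced
62/116 design can end up single-class).  Scaling parameters are re-estimated
inside each training split so no information leaks from held-out subjects.
For each candidate A the predictive residual sum of squares (PRESS) on the
held-out 0/1 outcome accumulates across folds, giving

    Q2(A) = 1 - PRESS(A) / sum over folds of sum (y_held - mean(y_train))^2.

The selected A is the smallest one whose Q2 lies within a parsimony
tolerance (0.01) of the maximum, floored at A = 1; if no component predicts
at all (all Q2 < 0), A = 1 is returned with an explicit flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .datatypes import AnalysisError
from .pls import autoscale, fit_nipals

PARSIMONY_TOL = 0.01


@dataclass
class CVResult:
    n_folds: int
    candidate_components: list[int]
    press: np.ndarray  # per-A cumulative held-out squared error
    q2: np.ndarray  # per-A predictive R2
    selected_components: int
    fold_assignments: np.ndarray  # length-n fold index per sample
    seed: int
    no_predictive_component: bool = False
    in_sample_r2y: np.ndarray | None = None  # cumulative training R2Y per A


def assign_folds(
    y: np.ndarray, n_folds: int, stratified: bool, seed: int, max_redraws: int = 20
) -> np.ndarray:
    """Length-n fold labels; redraws unstratified folds whose training split
    would be single-class."""
    n = len(y)
    if n_folds > n:
        raise AnalysisError(f"n_folds = {n_folds} exceeds n = {n}")
    if n_folds < 2:
        raise AnalysisError("need at least 2 folds")
    for attempt in range(max_redraws):
        rs = seed + attempt
        if stratified:
            splitter = StratifiedKFold(n_folds, shuffle=True, random_state=rs)
            splits = splitter.split(np.zeros(n), y)
        else:
            splitter = KFold(n_folds, shuffle=True, random_state=rs)
            splits = splitter.split(np.zeros(n))
        assignment = np.empty(n, dtype=int)
        ok = True
        for k, (train_idx, test_idx) in enumerate(splits):
            assignment[test_idx] = k
            if np.unique(y[train_idx]).size < 2:
                ok = False
        if ok:
            return assignment
        warnings.warn(
            f"fold draw {attempt} left a single-class training split; redrawing",
            stacklevel=2,
        )
    raise AnalysisError("could not draw folds with both classes in every training split")


def _per_component_coefficients(fit: dict, A: int) -> np.ndarray:
    W, P, q = fit["W"][:, :A], fit["P"][:, :A], fit["q"][:A]
    return W @ np.linalg.solve(P.T @ W, q)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    n_folds: int = 7,
    stratified: bool = True,
    seed: int = 0,
    fold_assignments: np.ndarray | None = None,
    selection_tol: float = PARSIMONY_TOL,
) -> CVResult:
    """Estimate PRESS/Q2 for A = 1..max_components and select A.

    ``X`` is the coded but *unscaled* predictor matrix and ``y`` the 0/1
    outcome: autoscaling happens inside each training split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if max_components < 1:
        raise AnalysisError("max_components must be >= 1")
    if fold_assignments is None:
        fold_assignments = assign_folds(y, n_folds, stratified, seed)
    else:
        fold_assignments = np.asarray(fold_assignments, dtype=int)
        if len(fold_assignments) != n:
            raise AnalysisError("fold_assignments length mismatch")
        n_folds = int(fold_assignments.max()) + 1

    press = np.zeros(max_components)
    tss = 0.0
    for k in range(n_folds):
        test = fold_assignments == k
        train = ~test
        sd = X[train].std(axis=0, ddof=1)
        keep = sd > 0.0
        Xtr, xc, xs = autoscale(X[train][:, keep])
        yc = float(y[train].mean())
        ys = float(y[train].std(ddof=1))
        if ys == 0.0:
            raise AnalysisError(f"training split of fold {k} is single-class")
        ytr = (y[train] - yc) / ys
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # truncation handled below
            fit = fit_nipals(Xtr, ytr, max_components)
        avail = fit["n_components"]
        Xte = (X[test][:, keep] - xc) / xs
        for A in range(1, max_components + 1):
            b = _per_component_coefficients(fit, min(A, avail))
            y_hat = (Xte @ b) * ys + yc
            press[A - 1] += float(np.sum((y[test] - y_hat) ** 2))
        tss += float(np.sum((y[test] - yc) ** 2))

    q2 = 1.0 - press / tss
    cv = CVResult(
        n_folds=n_folds,
        candidate_components=list(range(1, max_components + 1)),
        press=press,
        q2=q2,
        selected_components=1,
        fold_assignments=fold_assignments,
        seed=seed,
    )
    cv.selected_components = select_components(cv, tol=selection_tol)
    return cv


def select_components(cv: CVResult, tol: float = PARSIMONY_TOL) -> int:
    """Smallest A whose Q2 is within ``tol`` of the best; floor at A = 1."""
    if len(cv.q2) == 0:
        raise AnalysisError("empty cross-validation result")
    best = float(np.max(cv.q2))
    if best < 0.0:
        cv.no_predictive_component = True
        return 1
    cv.no_predictive_component = False
    for A, q in zip(cv.candidate_components, cv.q2):
        if q >= best - tol:
            return A
    return cv.candidate_components[-1]


def cv_report(cv: CVResult) -> dict:
    """JSON-serialisable summary of a cross-validation run."""
    return {
        "n_folds": cv.n_folds,
        "seed": cv.seed,
        "candidate_components": cv.candidate_components,
        "press": cv.press.tolist(),
        "q2": cv.q2.tolist(),
        "selected_components": cv.selected_components,
        "no_predictive_component": cv.no_predictive_component,
        "fold_assignments": cv.fold_assignments.tolist(),
    }
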