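"""Single-response PLS regression fitted by the NIPALS algorithm.

The predictor block X (hundreds of correlated polygenic scores, optionally
plus a coded diagnosis covariate) and the 0/1 outcome y are autoscaled to
zero mean and unit variance.  Components are extracted one at a time: each
weight vector w maximises the covariance between the component score
t = X w and the (deflated) response, and both X and y are deflated before
the next component.  Because the response is a single column, NIPALS
converges in one pass per component; the iteration loop is retained for
generality and its iteration counts are recorded.

The binary outcome is treated with a linear model throughout — no logistic
link — so R2Y is the fraction of variance of the scaled 0/1 outcome
explained on training data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AnalysisError, PhenotypeTable, ScorePanel, align

DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 500


class NumericalError(RuntimeError):
    """NIPALS failed to converge; carries iteration diagnostics."""


@dataclass
class Design:
    """Prepared regression inputs: coded, aligned, autoscaled.

    ``X_raw`` holds the coded but unscaled predictor matrix (scores plus the
    optional 0/1 diagnosis column) after constant columns were dropped;
    ``X`` is its autoscaled version.  ``y_raw`` is the 0/1 outcome and ``y``
    its autoscaled version.
    """

    X: np.ndarray
    y: np.ndarray
    X_raw: np.ndarray
    y_raw: np.ndarray
    column_ids: list[str]
    is_covariate: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    sample_ids: list[str]
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]


def autoscale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise centering and unit-variance (ddof=1) scaling."""
    center = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1)
    scale = np.where(scale == 0.0, 1.0, scale)
    return (M - center) / scale, center, scale


COVARIATE_COLUMN = "diagnosis_BD"


def prepare(
    panel: ScorePanel,
    phenotypes: PhenotypeTable,
    include_diagnosis_covariate: bool = False,
) -> Design:
    """Code, align and autoscale the predictor block and outcome.

    The diagnosis covariate, when requested, enters X as one extra 0/1
    column (BD = 1) that is autoscaled like any score but flagged so that
    downstream importance ranking can exclude it.  Constant columns are
    dropped with a warning — a subgroup split can make a score constant.
    """
    phenotypes = align(panel, phenotypes)
    y_raw = phenotypes.outcome
    classes = np.unique(y_raw)
    if classes.size < 2:
        raise AnalysisError("outcome has a single class; nothing to model")

    X_raw = panel.scores.to_numpy(dtype=float)
    column_ids = list(panel.score_ids)
    is_covariate = np.zeros(len(column_ids), dtype=bool)
    if include_diagnosis_covariate:
        diag = phenotypes.diagnosis.to_numpy()
        levels = np.unique(diag)
        if levels.size != 2:
            raise AnalysisError(
                f"diagnosis covariate needs two levels, got {levels.tolist()}"
            )
        cov = (diag == "BD").astype(float) if "BD" in levels else (
            diag == levels[1]
        ).astype(float)
        X_raw = np.column_stack([X_raw, cov])
        column_ids = column_ids + [COVARIATE_COLUMN]
        is_covariate = np.append(is_covariate, True)

    sd = X_raw.std(axis=0, ddof=1)
    constant = sd == 0.0
    dropped: list[str] = []
    if constant.all():
        raise AnalysisError("all predictor columns are constant")
    if constant.any():
        dropped = [c for c, k in zip(column_ids, constant) if k]
        warnings.warn(
            f"dropping {len(dropped)} constant predictor column(s): "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        X_raw = X_raw[:, ~constant]
        column_ids = [c for c, k in zip(column_ids, constant) if not k]
        is_covariate = is_covariate[~constant]

    X, x_center, x_scale = autoscale(X_raw)
    y_center = float(y_raw.mean())
    y_scale = float(y_raw.std(ddof=1))
    y = (y_raw - y_center) / y_scale
    return Design(
        X=X,
        y=y,
        X_raw=X_raw,
        y_raw=y_raw,
        column_ids=column_ids,
        is_covariate=is_covariate,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        sample_ids=list(panel.sample_ids),
        dropped_columns=dropped,
    )


@dataclass
class PLSModel:
    """Fitted NIPALS PLS model with the training scaling baked in.

    Weight columns have unit Euclidean norm and a fixed sign convention:
    each component is flipped so that its largest-magnitude weight entry is
    positive, making the fit bitwise reproducible for a given input.
    ``coefficients`` live on the autoscaled scale; :meth:`predict` maps back
    to the original 0/1 outcome scale.
    """

    n_components: int
    weights: np.ndarray  # p_eff x A, unit-norm columns
    x_scores: np.ndarray  # n x A
    x_loadings: np.ndarray  # p_eff x A
    y_loadings: np.ndarray  # A
    r2x: np.ndarray  # per-component fraction of X variance
    r2y: np.ndarray  # per-component fraction of y variance
    coefficients: np.ndarray  # p_eff, autoscaled scale
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    column_ids: list[str]
    is_covariate: np.ndarray
    n_iterations: list[int]

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P'W)^-1; maps autoscaled X to component scores."""
        PtW = self.x_loadings.T @ self.weights
        return self.weights @ np.linalg.inv(PtW)

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != len(self.column_ids):
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects "
                f"{len(self.column_ids)}"
            )
        Xs = (X_new - self.x_center) / self.x_scale
        return Xs @ self.rotation

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != len(self.column_ids):
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects "
                f"{len(self.column_ids)}"
            )
        Xs = (X_new - self.x_center) / self.x_scale
        return (Xs @ self.coefficients) * self.y_scale + self.y_center

    @property
    def fitted_values(self) -> np.ndarray:
        """Training predictions on the original 0/1 outcome scale."""
        return (self.x_scores @ self.y_loadings) * self.y_scale + self.y_center

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "n_components": self.n_components,
            "column_ids": self.column_ids,
            "is_covariate": self.is_covariate.astype(int).tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "r2x": self.r2x.tolist(),
            "r2y": self.r2y.tolist(),
            "coefficients": self.coefficients.tolist(),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center,
            "y_scale": self.y_scale,
            "n_iterations": self.n_iterations,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _fix_sign(w: np.ndarray) -> float:
    """Sign that makes the largest-|w| entry positive."""
    j = int(np.argmax(np.abs(w)))
    return 1.0 if w[j] >= 0 else -1.0


def fit_nipals(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> dict:
    """Run NIPALS on (already autoscaled) X, y; return the raw decomposition.

    Returns a dict with W, T, P, q, r2x, r2y, b and per-component iteration
    counts.  If the deflated response (or cross-covariance) vanishes before
    ``n_components`` components were extracted, the decomposition is
    truncated with a warning rather than failing.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol and max_iter must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    ssx0 = float(np.sum(X**2))
    ssy0 = float(np.sum(y**2))
    if ssy0 == 0.0:
        raise AnalysisError("response has zero variance")

    Xa, ya = X.copy(), y.copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    r2x = np.zeros(n_components)
    r2y = np.zeros(n_components)
    n_iter: list[int] = []

    a_done = 0
    for a in range(n_components):
        cov = Xa.T @ ya
        cnorm = float(np.linalg.norm(cov))
        if cnorm < 1e-14 * max(1.0, np.sqrt(ssx0 * ssy0)) or np.sum(ya**2) < 1e-14 * ssy0:
            warnings.warn(
                f"deflated signal exhausted after {a} components; "
                f"truncating from {n_components}",
                stacklevel=2,
            )
            break
        w = cov / cnorm
        u = ya
        it = 0
        while True:
            it += 1
            w_new = Xa.T @ u
            w_new = w_new / np.linalg.norm(w_new)
            t = Xa @ w_new
            qa = float(ya @ t) / float(t @ t)
            # single response: the y-block score u is proportional to y itself
            u_new = ya
            delta = float(np.linalg.norm(w_new - w))
            w = w_new
            u = u_new
            if delta < tol:
                break
            if it >= max_iter:
                raise NumericalError(
                    f"NIPALS did not converge for component {a + 1}: "
                    f"|dw| = {delta:.3e} after {it} iterations"
                )
        sign = _fix_sign(w)
        w = sign * w
        t = Xa @ w
        tt = float(t @ t)
        pa = (Xa.T @ t) / tt
        qa = float(ya @ t) / tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W[:, a] = w
        T[:, a] = t
        P[:, a] = pa
        q[a] = qa
        r2x[a] = tt * float(pa @ pa) / ssx0
        r2y[a] = qa**2 * tt / ssy0
        n_iter.append(it)
        a_done = a + 1

    if a_done == 0:
        raise AnalysisError("no PLS component could be extracted (X'y = 0)")
    W, T, P, q = W[:, :a_done], T[:, :a_done], P[:, :a_done], q[:a_done]
    r2x, r2y = r2x[:a_done], r2y[:a_done]
    b = W @ np.linalg.solve(P.T @ W, q)
    return {
        "n_components": a_done,
        "W": W,
        "T": T,
        "P": P,
        "q": q,
        "r2x": r2x,
        "r2y": r2y,
        "b": b,
        "n_iterations": n_iter,
    }


def fit_model(
    design: Design,
    n_components: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PLSModel:
    """Fit NIPALS on a prepared design and package the result."""
    fit = fit_nipals(design.X, design.y, n_components, tol=tol, max_iter=max_iter)
    return PLSModel(
        n_components=fit["n_components"],
        weights=fit["W"],
        x_scores=fit["T"],
        x_loadings=fit["P"],
        y_loadings=fit["q"],
        r2x=fit["r2x"],
        r2y=fit["r2y"],
        coefficients=fit["b"],
        x_center=design.x_center,
        x_scale=design.x_scale,
        y_center=design.y_center,
        y_scale=design.y_scale,
        column_ids=design.column_ids,
        is_covariate=design.is_covariate,
        n_iterations=fit["n_iterations"],
    )


def predict(model: PLSModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project new (original-scale) rows: latent scores and 0/1-scale y-hat."""
    return model.transform(X_new), model.predict(X_new)
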