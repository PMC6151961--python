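"""Two-response PLS regression (NIPALS), latent-variable selection by
cross-validation, and error metrics.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``transform`` / ``get_params``) so it composes with pipelines and model
selection, while exposing the quantities the model inversion needs: X-weights
W, X-loadings P, Y-loadings C, the transformed weights R* = W(PᵀW)⁻¹ mapping
a scaled row x to its scores t = xᵀR*, the training scores and their sample
covariance S (the Hotelling-T² metric of the score space).

Model equations (autoscaled domain)::

    X = T Pᵀ + E        T = X R*
    Y = T Cᵀ + F        ŷ = C t̂

with A latent variables extracted by NIPALS with X-deflation; Y residuals are
re-computed per component (Y-deflation by t cᵀ).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import ValidationError
from .preprocess import Autoscaler

SCHEMA_VERSION = 1


class NipalsPLS(RegressorMixin, BaseEstimator):
    """NIPALS PLS2 regression with internal autoscaling.

    Parameters
    ----------
    n_components : int
        Number of latent variables A (1 <= A <= min(n-1, p)).
    scale : bool, default True
        Autoscale X and Y with training mean / sample sd; predictions are
        returned in original units either way.
    max_iter, tol : retained for API compatibility; the NIPALS inner loop is
        solved in closed form (q×q eigenproblem), so no iteration occurs.

    Attributes (fitted)
    -------------------
    x_weights_ : (p, A) W;  x_loadings_ : (p, A) P;  y_loadings_ : (q, A) C
    x_rotations_ : (p, A) R* = W(PᵀW)⁻¹
    x_scores_ : (n, A) training scores T
    score_cov_ : (A, A) sample covariance of T
    r2x_, r2y_ : cumulative explained variance fractions
    s0_ : pooled training residual sd used by DModX
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting -----------------------------------------------------------

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        q = Y.shape[1]
        A = self.n_components
        if not 1 <= A <= min(n - 1, p):
            raise ValidationError(
                f"n_components={A} must lie in [1, min(n-1, p)] = "
                f"[1, {min(n - 1, p)}]")
        self._x_scaler = Autoscaler().fit(X)
        if self.scale:
            Xs = self._x_scaler.transform(X)
            self._y_scaler = Autoscaler().fit(Y)
            Ys = self._y_scaler.transform(Y)
        else:
            Xs = X - X.mean(axis=0)
            self._y_mean = Y.mean(axis=0)
            Ys = Y - self._y_mean
        ssx0 = float((Xs ** 2).sum())
        ssy0 = float((Ys ** 2).sum())

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        C = np.zeros((q, A))
        T = np.zeros((n, A))
        Xr, Yr = Xs.copy(), Ys.copy()
        n_extracted = 0
        for a in range(A):
            if float((Yr ** 2).sum()) <= 1e-12 * max(ssy0, 1.0):
                break  # Y fully explained; further components are noise
            # The NIPALS inner loop is a power iteration for the dominant
            # eigenvector of (YᵀX)(XᵀY) — a q×q symmetric problem solved here
            # in closed form, which is exact even when the eigenvalues are
            # nearly degenerate and the iteration would stall.
            XtY = Xr.T @ Yr
            M = XtY.T @ XtY
            evals, evecs = np.linalg.eigh(M)
            z = evecs[:, -1]
            w = XtY @ z
            nw = np.linalg.norm(w)
            if nw <= 1e-14 * max(1.0, np.linalg.norm(Xr)):
                break  # X and Y residuals uncorrelated; nothing left to model
            w /= nw
            if w[int(np.argmax(np.abs(w)))] < 0:
                w = -w  # deterministic sign convention
            t = Xr @ w
            tt = float(t @ t)
            if tt <= 1e-14:
                raise ValidationError("NIPALS: degenerate score vector")
            c = Yr.T @ t / tt
            pa = Xr.T @ t / tt
            Xr -= np.outer(t, pa)
            Yr -= np.outer(t, c)
            W[:, a], P[:, a], C[:, a], T[:, a] = w, pa, c, t
            n_extracted += 1

        A = n_extracted
        if A == 0:
            raise ValidationError("no PLS component could be extracted")
        W, P, C, T = W[:, :A], P[:, :A], C[:, :A], T[:, :A]
        self.n_components_ = A
        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, C
        self.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        self.x_scores_ = T
        self.score_cov_ = np.atleast_2d(np.cov(T, rowvar=False, ddof=1))
        self.coef_ = self.x_rotations_ @ C.T  # scaled-domain (p, q)
        self.r2x_ = 1.0 - float((Xr ** 2).sum()) / ssx0 if ssx0 > 0 else 1.0
        self.r2y_ = 1.0 - float((Yr ** 2).sum()) / ssy0 if ssy0 > 0 else 1.0
        # pooled residual sd of the training X-block, SIMCA dof convention
        dof = (n - A - 1) * (p - A)
        self.s0_ = float(np.sqrt((Xr ** 2).sum() / dof)) if dof > 0 else np.nan
        self._n_train = n
        self.n_features_in_ = p
        self._q = Ys.shape[1]
        return self

    # -- scaling helpers ---------------------------------------------------

    def _scale_x(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} columns, model was trained on "
                f"{self.n_features_in_}")
        if self.scale:
            return self._x_scaler.transform(X)
        return X - self._x_scaler.mean_

    def _unscale_y(self, Ys):
        if self.scale:
            return self._y_scaler.inverse_transform(Ys)
        return Ys + self._y_mean

    # -- prediction --------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Scores t̂ = xᵀR* of (raw-unit) query rows."""
        check_is_fitted(self, "x_rotations_")
        return self._scale_x(X) @ self.x_rotations_

    def predict(self, X) -> np.ndarray:
        """Predicted (logkw, logKi) in original units."""
        check_is_fitted(self, "x_rotations_")
        T = self.transform(X)
        return self._unscale_y(T @ self.y_loadings_.T)

    def predict_from_scores(self, T) -> np.ndarray:
        check_is_fitted(self, "y_loadings_")
        return self._unscale_y(np.asarray(T) @ self.y_loadings_.T)

    def predict_cumulative(self, X) -> np.ndarray:
        """Predictions for every truncation 1..A, shape (A, n, q).

        NIPALS components are nested, so one fit yields all smaller models —
        used by cross-validation to price every A in a single pass.
        """
        check_is_fitted(self, "x_rotations_")
        Xs = self._scale_x(X)
        A = self.n_components_
        out = np.empty((A, Xs.shape[0], self._q))
        # R* for truncated models must be recomputed: W_a(P_aᵀW_a)⁻¹
        for a in range(1, A + 1):
            Wa, Pa, Ca = self.x_weights_[:, :a], self.x_loadings_[:, :a], self.y_loadings_[:, :a]
            Ra = Wa @ np.linalg.inv(Pa.T @ Wa)
            out[a - 1] = self._unscale_y(Xs @ Ra @ Ca.T)
        return out

    def x_residuals(self, X) -> np.ndarray:
        """Scaled-domain reconstruction residuals e = x − t̂Pᵀ per row."""
        check_is_fitted(self, "x_loadings_")
        Xs = self._scale_x(X)
        return Xs - (Xs @ self.x_rotations_) @ self.x_loadings_.T

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "x_rotations_")
        doc = {
            "schema_version": SCHEMA_VERSION,
            "n_components": self.n_components_,
            "scale": self.scale,
            "x_mean": self._x_scaler.mean_.tolist(),
            "x_scale": self._x_scaler.scale_.tolist(),
            "y_mean": self._y_scaler.mean_.tolist() if self.scale else self._y_mean.tolist(),
            "y_scale": self._y_scaler.scale_.tolist() if self.scale else [1.0] * self._q,
            "W": self.x_weights_.tolist(),
            "P": self.x_loadings_.tolist(),
            "C": self.y_loadings_.tolist(),
            "T": self.x_scores_.tolist(),
            "r2x": self.r2x_,
            "r2y": self.r2y_,
            "s0": self.s0_,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "NipalsPLS":
        doc = json.loads(text)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValidationError(f"unsupported model schema {doc.get('schema_version')}")
        model = cls(n_components=doc["n_components"], scale=doc["scale"])
        W = np.asarray(doc["W"])
        P = np.asarray(doc["P"])
        C = np.asarray(doc["C"])
        T = np.asarray(doc["T"])
        model._x_scaler = Autoscaler()
        model._x_scaler.mean_ = np.asarray(doc["x_mean"])
        model._x_scaler.scale_ = np.asarray(doc["x_scale"])
        model._y_scaler = Autoscaler()
        model._y_scaler.mean_ = np.asarray(doc["y_mean"])
        model._y_scaler.scale_ = np.asarray(doc["y_scale"])
        model.x_weights_, model.x_loadings_, model.y_loadings_ = W, P, C
        model.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        model.x_scores_ = T
        model.score_cov_ = np.atleast_2d(np.cov(T, rowvar=False, ddof=1))
        model.coef_ = model.x_rotations_ @ C.T
        model.n_components_ = W.shape[1]
        model.n_features_in_ = W.shape[0]
        model._q = C.shape[0]
        model._n_train = T.shape[0]
        model.r2x_, model.r2y_, model.s0_ = doc["r2x"], doc["r2y"], doc["s0"]
        return model


# ---------------------------------------------------------------------------
# Cross-validation and metrics


def _cv_rmsecv(X, Y, a_max: int, k: int, seed: int) -> np.ndarray:
    """Per-(A, response) root-mean-square CV error, shape (a_max, q)."""
    n = X.shape[0]
    if k > n:
        raise ValidationError(f"k={k} folds exceed n={n} samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    if n - max(len(f) for f in folds) < 2:
        raise ValidationError("a fold leaves fewer than 2 training samples")
    a_max = min(a_max, n - max(len(f) for f in folds) - 1, X.shape[1])
    press = np.zeros((a_max, Y.shape[1]))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = NipalsPLS(n_components=a_max).fit(X[mask], Y[mask])
        preds = model.predict_cumulative(X[fold])  # (A', n_fold, q)
        a_got = preds.shape[0]
        err = preds - Y[fold][None, :, :]
        press[:a_got] += (err ** 2).sum(axis=1)
        if a_got < a_max:  # early NIPALS stop: larger A behaves identically
            press[a_got:] += (err[-1] ** 2).sum(axis=0)[None, :]
    return np.sqrt(press / n)


def cross_validate(X, Y, a_max: int, k: int = 7, seed: int = 0) -> tuple[pd.DataFrame, int]:
    """k-fold CV error for A = 1..a_max; returns (table, chosen A).

    Folds are contiguous blocks of a seeded shuffle. The per-A error is the
    sum over the two responses of the root-mean-square CV residual (original
    units); the chosen A minimises it.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rmsecv = _cv_rmsecv(X, Y, a_max, k, seed)
    a_max = rmsecv.shape[0]
    total = rmsecv.sum(axis=1)
    table = pd.DataFrame({
        "A": np.arange(1, a_max + 1),
        "rmsecv_logkw": rmsecv[:, 0],
        "rmsecv_logKi": rmsecv[:, 1] if Y.shape[1] > 1 else np.nan,
        "rmsecv_total": total,
    })
    return table, int(np.argmin(total)) + 1


@dataclass
class ModelMetrics:
    rmsee: tuple[float, float]
    rmsep: tuple[float, float]
    mre_pct: tuple[float, float]
    r2x: float
    r2y: float


def rmse(pred: np.ndarray, obsd: np.ndarray) -> np.ndarray:
    """Per-response root-mean-square error sqrt(sum((pred-obsd)^2)/n)."""
    pred, obsd = np.atleast_2d(pred), np.atleast_2d(obsd)
    return np.sqrt(((pred - obsd) ** 2).mean(axis=0))


def mean_relative_error_pct(pred: np.ndarray, obsd: np.ndarray) -> np.ndarray:
    """Per-response mean of |pred-obsd|/|obsd| in percent.

    Observations equal to zero make the ratio undefined; they are excluded
    with a warning.
    """
    pred, obsd = np.atleast_2d(pred), np.atleast_2d(obsd)
    out = np.empty(obsd.shape[1])
    for j in range(obsd.shape[1]):
        ok = obsd[:, j] != 0.0
        if not ok.all():
            warnings.warn(
                f"MRE: excluded {int((~ok).sum())} observation(s) equal to 0 "
                f"in response {j}", RuntimeWarning, stacklevel=2)
        out[j] = 100.0 * (np.abs(pred[ok, j] - obsd[ok, j]) / np.abs(obsd[ok, j])).mean()
    return out


def metrics(model: NipalsPLS, X_train, Y_train, X_test=None, Y_test=None) -> ModelMetrics:
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    rmsee = rmse(model.predict(X_train), Y_train)
    if X_test is not None and len(np.asarray(X_test)):
        Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
        pt = model.predict(X_test)
        rmsep = rmse(pt, Y_test)
        mre = mean_relative_error_pct(pt, Y_test)
    else:
        rmsep = np.full(Y_train.shape[1], np.nan)
        mre = np.full(Y_train.shape[1], np.nan)
    return ModelMetrics(
        rmsee=tuple(float(v) for v in rmsee),
        rmsep=tuple(float(v) for v in rmsep),
        mre_pct=tuple(float(v) for v in mre),
        r2x=model.r2x_,
        r2y=model.r2y_,
    )


def fit_pls(X, Y, n_components: int) -> NipalsPLS:
    """Thin functional wrapper over :class:`NipalsPLS`."""
    return NipalsPLS(n_components=n_components).fit(X, Y)
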