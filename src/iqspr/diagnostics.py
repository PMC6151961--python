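"""Applicability-domain and model-health statistics.

A QSPR prediction is only trustworthy for query compounds resembling the
training set. Three complementary statistics bound that region:

* **leverage** ``h`` — distance from the training centroid in the full
  (scaled) descriptor space, with the conventional warning threshold
  ``h* = 3(k+1)/n``;
* **Hotelling T²** — Mahalanobis distance of the PLS scores from the score
  centroid, with an F-based critical ellipsoid;
* **DModX** — normalized distance to the PLS model plane (residual after
  projection), with an F-based critical limit.

The Williams-plot rule declares a compound in-domain when its standardized
residuals stay within ±3 and its leverage within h*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ValidationError
from .pls_core import NipalsPLS, rmse

# ---------------------------------------------------------------------------
# Leverage


def leverage(X_train: np.ndarray, X_query: np.ndarray | None = None) -> np.ndarray:
    """Hat-style leverage of query rows against a scaled training matrix.

    ``h = 1/n + x_cᵀ(X_cᵀX_c)⁻¹x_c`` with X_c the column-centred training
    matrix (the +1/n term is the intercept convention that makes training
    leverages sum to k+1). Both matrices must already be on the same
    (autoscaled) footing.
    """
    X_train = np.asarray(X_train, dtype=float)
    n = X_train.shape[0]
    center = X_train.mean(axis=0)
    Xc = X_train - center
    G = Xc.T @ Xc
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        warnings.warn("singular XᵀX; using pseudo-inverse for leverage",
                      RuntimeWarning, stacklevel=2)
        Ginv = np.linalg.pinv(G)
    Q = np.atleast_2d(np.asarray(X_query, dtype=float)) if X_query is not None else X_train
    Qc = Q - center
    return 1.0 / n + np.einsum("ij,jk,ik->i", Qc, Ginv, Qc)


def leverage_threshold(k: int, n: int) -> float:
    """Conventional leverage warning limit h* = 3(k+1)/n."""
    if k < 0 or n <= k + 1:
        raise ValidationError(f"need n > k+1 (got k={k}, n={n})")
    return 3.0 * (k + 1) / n


# ---------------------------------------------------------------------------
# Hotelling T2


def hotelling_t2(score_cov: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """T² = tᵀS⁻¹t per score row, S the training score covariance."""
    S = np.atleast_2d(np.asarray(score_cov, dtype=float))
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise ValidationError("singular score covariance")
    sol = np.linalg.solve(S, T.T)
    return np.einsum("ij,ji->i", T, sol)


def t2_critical(A: int, n: int, alpha: float = 0.05) -> float:
    """F-based critical limit: T²_crit = A(n−1)/(n−A) · F_{1−α}(A, n−A)."""
    if not (0 < A < n):
        raise ValidationError(f"need 0 < A < n (got A={A}, n={n})")
    return A * (n - 1) / (n - A) * float(stats.f.ppf(1 - alpha, A, n - A))


# ---------------------------------------------------------------------------
# DModX


def observation_inflation(model: NipalsPLS) -> float:
    """Variance inflation of a new observation's residual, n/(n−A−1).

    A row not used in fitting carries the estimation error of the centring,
    scaling and loadings on top of its own noise; the standard chemometric
    correction divides the squared residual by this factor so that training
    and query DModX values share one critical limit.
    """
    n, A = model._n_train, model.n_components_
    return n / (n - A - 1)


def dmodx(model: NipalsPLS, X_query: np.ndarray) -> np.ndarray:
    """Normalized distance to the PLS model plane per query row.

    DModX = sqrt(Σe²/((p−A)·g)) / s0 with e the scaled-domain reconstruction
    residual, s0 the pooled training residual sd (dof (n−A−1)(p−A)) and g the
    new-observation inflation factor n/(n−A−1).
    """
    p, A = model.n_features_in_, model.n_components_
    if p <= A:
        raise ValidationError("DModX undefined for p <= A")
    E = model.x_residuals(X_query)
    g = observation_inflation(model)
    out = np.sqrt((E ** 2).sum(axis=1) / ((p - A) * g))
    if model.s0_ > 1e-10:
        out /= model.s0_
    # an (essentially) exact training fit has s0 ~ 0; the unnormalized
    # residual distance is returned so exact reconstructions report 0
    return out


def dmodx_critical(model: NipalsPLS, alpha: float = 0.05) -> float:
    """F-based DModX limit: sqrt(F_{1−α}(p−A, (n−A−1)(p−A)))."""
    p, A, n = model.n_features_in_, model.n_components_, model._n_train
    if p <= A:
        raise ValidationError("DModX undefined for p <= A")
    return float(np.sqrt(stats.f.ppf(1 - alpha, p - A, (n - A - 1) * (p - A))))


# ---------------------------------------------------------------------------
# Standardized residuals and the combined report


def standardized_residuals(model: NipalsPLS, X, Y) -> np.ndarray:
    """Per-response residuals scaled by the training RMSEE (Williams-plot y-axis)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    resid = model.predict(X) - Y
    denom = model._rmsee_train_
    return resid / denom


@dataclass
class DiagnosticsReport:
    table: pd.DataFrame          # per-compound h, t2, dmodx, std resid, in_domain
    leverage_threshold: float
    t2_crit: float
    dmodx_crit: float


def diagnostics_report(model: NipalsPLS, X_train, Y_train, X_query=None,
                       Y_query=None, ids=None, alpha: float = 0.05) -> DiagnosticsReport:
    """Full applicability-domain report for query rows (default: training set)."""
    X_train = np.asarray(X_train, dtype=float)
    if X_query is None:
        X_query, Y_query = X_train, Y_train
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    n, k = X_train.shape
    model._rmsee_train_ = rmse(model.predict(X_train), np.atleast_2d(Y_train))
    Xs_train = model._scale_x(X_train)
    Xs_query = model._scale_x(X_query)
    h = leverage(Xs_train, Xs_query)
    h_star = leverage_threshold(k, n)
    t2 = hotelling_t2(model.score_cov_, model.transform(X_query))
    t2c = t2_critical(model.n_components_, n, alpha)
    dx = dmodx(model, X_query)
    dxc = dmodx_critical(model, alpha)
    data = {"h": h, "t2": t2, "dmodx": dx}
    in_domain = h <= h_star
    if Y_query is not None:
        sr = standardized_residuals(model, X_query, Y_query)
        data["std_resid_logkw"] = sr[:, 0]
        if sr.shape[1] > 1:
            data["std_resid_logKi"] = sr[:, 1]
        in_domain = in_domain & (np.abs(sr) <= 3.0).all(axis=1)
    data["in_domain"] = in_domain
    idx = pd.Index(ids if ids is not None else range(len(h)), name="compound_id")
    return DiagnosticsReport(
        table=pd.DataFrame(data, index=idx),
        leverage_threshold=h_star,
        t2_crit=t2c,
        dmodx_crit=dxc,
    )
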