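"""Constrained mixed-integer inversion of a fitted PLS model.

Given reference drug-property values (logkw_ref, logKi_ref), the inversion
searches descriptor space for the vector x* whose model prediction is
closest to the reference while x* stays inside the model's valid region::

    x* = argmin (ŷ_logkw(x) − logkw_ref)² + (ŷ_logKi(x) − logKi_ref)²
    s.t. t̂ᵀS⁻¹t̂ ≤ c1                 (score-space Hotelling T² ellipsoid)
         ‖t̂Pᵀ − x‖² ≤ c2             (reconstruction residual: x near the
                                       model plane, scaled domain)
         x_min ≤ x ≤ x_max            (training descriptor ranges)
         binary/integer descriptors on their lattices

with t̂ = xᵀR* (the standard PLS score projection, following the
latent-variable model-inversion framework of Jaeckle and MacGregor). c1 is
the F-based T² limit; c2 converts the DModX critical value into a
squared-residual bound via the training normalization s0²·(p−A)·DModX_crit².

Because the descriptor kinds mix continuous, integer and binary variables,
the solver is a seeded mixed-variable genetic algorithm with
feasibility-first ranking (any feasible individual dominates any infeasible
one; infeasible individuals rank by total constraint violation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import DescriptorTable, ReferenceProperties, ValidationError
from .diagnostics import dmodx_critical, observation_inflation, t2_critical
from .pls_core import NipalsPLS


@dataclass
class InverterConfig:
    population_size: int = 100
    generations: int = 200
    mutation_rate: float = 0.2
    crossover_fraction: float = 0.8
    elitism: int = 2
    seed: int = 0


@dataclass
class InversionProblem:
    model: NipalsPLS
    reference: ReferenceProperties
    bounds: np.ndarray            # (p, 2) raw per-descriptor (min, max)
    kinds: list[str]
    c1: float                     # T2 limit in score space
    c2: float                     # squared reconstruction-residual limit
    config: InverterConfig = field(default_factory=InverterConfig)

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (self.model.n_features_in_, 2):
            raise ValidationError("bounds must be (p, 2)")
        if not np.all(np.isfinite(self.bounds)):
            raise ValidationError("bounds must be finite")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValidationError("constraint limits must be positive")


@dataclass
class InversionSolution:
    x_star: np.ndarray            # raw descriptor units
    x_star_scaled: np.ndarray
    predicted: tuple[float, float]
    objective: float
    t2_value: float
    recon_residual: float
    feasible: bool


def build_problem(model: NipalsPLS, reference: ReferenceProperties,
                  train_desc: DescriptorTable, alpha: float = 0.05,
                  config: InverterConfig | None = None) -> InversionProblem:
    """Assemble the inversion problem from a fitted model and training data.

    c1 = T²_crit(A, n, α); c2 = s0²·(p−A)·DModX_crit(α)² — the squared
    residual a row sitting exactly on the DModX limit would have. Bounds are
    the per-descriptor training min/max.
    """
    if not hasattr(model, "score_cov_"):
        raise ValidationError("model must be fitted (missing score covariance)")
    n = model._n_train
    A = model.n_components_
    p = model.n_features_in_
    c1 = t2_critical(A, n, alpha)
    c2 = (model.s0_ ** 2 * (p - A) * observation_inflation(model)
          * dmodx_critical(model, alpha) ** 2)
    bounds = np.column_stack([train_desc.values.min(axis=0),
                              train_desc.values.max(axis=0)])
    if A < 2:
        warnings.warn(
            "model has fewer latent variables than responses; the inversion "
            "is over-determined in score space and the objective may not "
            "reach 0", RuntimeWarning, stacklevel=2)
    return InversionProblem(model=model, reference=reference, bounds=bounds,
                            kinds=list(train_desc.kinds), c1=c1, c2=c2,
                            config=config or InverterConfig())


def _evaluate(problem: InversionProblem, X_raw: np.ndarray):
    """Vectorised objective + constraint values for a population (m, p)."""
    model = problem.model
    Xs = model._scale_x(X_raw)
    T = Xs @ model.x_rotations_
    pred = model.predict_from_scores(T)
    ref = np.array([problem.reference.logkw_ref, problem.reference.logKi_ref])
    obj = ((pred - ref) ** 2).sum(axis=1)
    Sinv_t = np.linalg.solve(model.score_cov_, T.T)
    t2 = np.einsum("ij,ji->i", T, Sinv_t)
    E = Xs - T @ model.x_loadings_.T
    recon = (E ** 2).sum(axis=1)
    violation = (np.maximum(0.0, t2 - problem.c1) / problem.c1
                 + np.maximum(0.0, recon - problem.c2) / problem.c2)
    return obj, t2, recon, violation, pred


def objective(x: np.ndarray, problem: InversionProblem) -> float:
    """Squared property deviation of a single raw-unit descriptor vector."""
    x = np.asarray(x, dtype=float)
    _check_kinds(x, problem)
    obj, *_ = _evaluate(problem, x[None, :])
    return float(obj[0])


def _check_kinds(x: np.ndarray, problem: InversionProblem) -> None:
    for j, kind in enumerate(problem.kinds):
        if kind == "binary" and x[j] not in (0.0, 1.0):
            raise ValidationError(f"descriptor {j} is binary but x[{j}]={x[j]}")
        if kind == "integer" and x[j] != round(x[j]):
            raise ValidationError(f"descriptor {j} is integer but x[{j}]={x[j]}")
        lo, hi = problem.bounds[j]
        if not lo <= x[j] <= hi:
            raise ValidationError(f"x[{j}]={x[j]} outside bounds [{lo}, {hi}]")


def _init_population(problem: InversionProblem, rng: np.random.Generator,
                     m: int) -> np.ndarray:
    p = problem.bounds.shape[0]
    lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
    X = lo + rng.random((m, p)) * (hi - lo)
    for j, kind in enumerate(problem.kinds):
        if kind == "binary":
            X[:, j] = rng.integers(0, 2, size=m)
            X[:, j] = np.clip(X[:, j], lo[j], hi[j])
        elif kind == "integer":
            X[:, j] = rng.integers(int(np.ceil(lo[j])), int(np.floor(hi[j])) + 1,
                                   size=m)
    return X


def _mutate_rows(X: np.ndarray, problem: InversionProblem,
                 rng: np.random.Generator, progress: float) -> None:
    """Per-gene mutation with a step size annealed over the run.

    Continuous genes take Gaussian steps whose sd shrinks geometrically from
    20% to 1% of the gene's range as ``progress`` goes 0 -> 1 (coarse global
    search early, fine local search late); integer genes step ±1, binary
    genes flip.
    """
    m, p = X.shape
    lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
    span = hi - lo
    rate = problem.config.mutation_rate
    step = 0.2 * (0.05 ** progress)
    mask = rng.random((m, p)) < rate
    for j, kind in enumerate(problem.kinds):
        rows = np.nonzero(mask[:, j])[0]
        if rows.size == 0:
            continue
        if kind == "binary":
            X[rows, j] = 1.0 - X[rows, j]
            np.clip(X[rows, j], lo[j], hi[j], out=X[rows, j])
        elif kind == "integer":
            X[rows, j] = np.clip(X[rows, j] + rng.choice((-1.0, 1.0), rows.size),
                                 np.ceil(lo[j]), np.floor(hi[j]))
        else:
            X[rows, j] = np.clip(
                X[rows, j] + rng.normal(0.0, step * max(span[j], 1e-12), rows.size),
                lo[j], hi[j])


def _polish_continuous(problem: InversionProblem, x0: np.ndarray) -> np.ndarray:
    """Local refinement of the continuous genes by SLSQP (hybrid GA).

    Lattice (binary/integer) genes stay frozen; the two quadratic domain
    constraints and the box bounds are imposed exactly. Returns the refined
    vector, or ``x0`` unchanged if the local step fails or degrades the
    feasibility-first ranking.
    """
    from scipy.optimize import minimize

    cont = np.array([k == "continuous" for k in problem.kinds])
    if not cont.any():
        return x0

    def full(xc):
        x = x0.copy()
        x[cont] = xc
        return x

    def f(xc):
        return _evaluate(problem, full(xc)[None, :])[0][0]

    def t2_slack(xc):
        return problem.c1 - _evaluate(problem, full(xc)[None, :])[1][0]

    def recon_slack(xc):
        return problem.c2 - _evaluate(problem, full(xc)[None, :])[2][0]

    bounds = list(zip(problem.bounds[cont, 0], problem.bounds[cont, 1]))
    res = minimize(
        f, x0[cont], method="SLSQP", bounds=bounds,
        constraints=[{"type": "ineq", "fun": t2_slack},
                     {"type": "ineq", "fun": recon_slack}],
        options={"maxiter": 200, "ftol": 1e-14})
    def key(x):
        # feasibility-first with tolerance: violations below 1e-9 count as 0
        obj, _, _, viol, _ = _evaluate(problem, x[None, :])
        v = 0.0 if viol[0] <= 1e-9 else float(viol[0])
        return (v, float(obj[0]))

    best = x0
    if res.success:
        cand = full(res.x)
        if key(cand) <= key(x0) and key(cand)[0] == 0.0:
            best = cand
    # among property-matching solutions the inversion is degenerate off the
    # latent plane; pick the canonical representative by minimising the
    # reconstruction residual at (essentially) unchanged objective
    obj_b = float(_evaluate(problem, best[None, :])[0][0])

    def recon(xc):
        return _evaluate(problem, full(xc)[None, :])[2][0]

    def obj_slack(xc):
        return obj_b + 1e-8 - f(xc)

    res2 = minimize(
        recon, best[cont], method="SLSQP", bounds=bounds,
        constraints=[{"type": "ineq", "fun": t2_slack},
                     {"type": "ineq", "fun": recon_slack},
                     {"type": "ineq", "fun": obj_slack}],
        options={"maxiter": 200, "ftol": 1e-14})
    if res2.success:
        cand = full(res2.x)
        obj_c, _, rec_c, viol_c, _ = _evaluate(problem, cand[None, :])
        _, _, rec_b, _, _ = _evaluate(problem, best[None, :])
        if (viol_c[0] <= 1e-9 and obj_c[0] <= obj_b + 1e-6
                and rec_c[0] < rec_b[0]):
            best = cand
    return best


def invert(problem: InversionProblem) -> InversionSolution:
    """Solve the inversion with a seeded mixed-variable GA.

    Binary tournament selection on the feasibility-first key, scattered
    crossover, per-gene mutation with generation-annealed step size, elitism,
    and a final SLSQP polish of the continuous genes (hybrid GA). If no
    feasible individual is ever seen, the least-violating one is returned
    flagged infeasible.
    """
    cfg = problem.config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.population_size
    X = _init_population(problem, rng, m)

    def keys(obj, violation):
        # lexicographic: feasible first, then violation, then objective
        infeasible = violation > 0
        return np.where(infeasible, 1e12 + violation, obj)

    obj, t2, recon, violation, _ = _evaluate(problem, X)
    k = keys(obj, violation)
    best_idx = int(np.argmin(k))
    best = (X[best_idx].copy(), k[best_idx])

    for gen in range(cfg.generations):
        order = np.argsort(k, kind="stable")
        elite = X[order[:cfg.elitism]].copy()
        # binary tournament on the feasibility-first key
        n_children = m - cfg.elitism
        a = rng.integers(m, size=n_children)
        b = rng.integers(m, size=n_children)
        parents1 = np.where(k[a] <= k[b], a, b)
        a = rng.integers(m, size=n_children)
        b = rng.integers(m, size=n_children)
        parents2 = np.where(k[a] <= k[b], a, b)
        do_cx = rng.random(n_children) < cfg.crossover_fraction
        mask = rng.random((n_children, X.shape[1])) < 0.5
        children = np.where(do_cx[:, None] & mask, X[parents2], X[parents1])
        _mutate_rows(children, problem, rng,
                     progress=gen / max(cfg.generations - 1, 1))
        X = np.vstack([elite, children])
        obj, t2, recon, violation, _ = _evaluate(problem, X)
        k = keys(obj, violation)
        i = int(np.argmin(k))
        if k[i] < best[1]:
            best = (X[i].copy(), k[i])

    x_star = _polish_continuous(problem, best[0])
    obj, t2, recon, violation, pred = _evaluate(problem, x_star[None, :])
    feasible = bool(violation[0] <= 1e-9)
    if not feasible:
        warnings.warn("inversion found no feasible solution; returning the "
                      "least-violating individual", RuntimeWarning, stacklevel=2)
    return InversionSolution(
        x_star=x_star,
        x_star_scaled=problem.model._scale_x(x_star[None, :])[0],
        predicted=(float(pred[0, 0]), float(pred[0, 1])),
        objective=float(obj[0]),
        t2_value=float(t2[0]),
        recon_residual=float(recon[0]),
        feasible=feasible,
    )
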