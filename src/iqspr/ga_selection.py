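"""Genetic-algorithm descriptor-subset selection coupled to PLS (GA-PLS).

Chromosomes are binary membership vectors over the filtered descriptor pool,
repaired into a cardinality window. Each subset is priced by fitting a PLS
model (latent-variable count chosen by k-fold cross-validation) and pooling
training and external-test errors per response::

    η_j = sqrt(((n_T − n_S − 1)·RMSEE_j² + n_P·RMSEP_j²) / (n_T + n_P − n_S − 1))
    η   = sqrt(η_1² + η_2²)

so that model complexity (n_S selected descriptors) discounts the training
error's weight, and η keeps RMSE units. The GA minimises η.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .data_model import ValidationError
from .pls_core import NipalsPLS, _cv_rmsecv, rmse

SELECTION_FNS = ("uniform", "roulette", "tournament")
CROSSOVER_FNS = ("scattered", "single_point", "two_point")


@dataclass
class GAConfig:
    """Search settings; the enum fields mirror common GA toolbox options."""

    crossover_fraction: float = 0.8
    mutation_rate: float = 0.2
    n_select_min: int = 5
    n_select_max: int = 20
    selection_fn: str = "tournament"
    crossover_fn: str = "scattered"
    population_size: int = 64
    generations: int = 100
    seed: int = 0
    a_max: int = 10
    cv_folds: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.crossover_fraction <= 1:
            raise ValidationError("crossover_fraction must lie in (0, 1]")
        if not 0 < self.mutation_rate <= 1:
            raise ValidationError("mutation_rate must lie in (0, 1]")
        if self.n_select_min < 1 or self.n_select_max < self.n_select_min:
            raise ValidationError("need 1 <= n_select_min <= n_select_max")
        if self.generations < 1 or self.population_size < 2:
            raise ValidationError("population_size >= 2 and generations >= 1 required")
        if self.selection_fn not in SELECTION_FNS:
            raise ValidationError(f"selection_fn must be one of {SELECTION_FNS}")
        if self.crossover_fn not in CROSSOVER_FNS:
            raise ValidationError(f"crossover_fn must be one of {CROSSOVER_FNS}")


@dataclass
class FitnessResult:
    eta: float
    eta1: float
    eta2: float
    rmsee: tuple[float, float]
    rmsep: tuple[float, float]
    A: int


@dataclass
class SelectionResult:
    selected_names: list[str]
    eta: float
    eta1: float
    eta2: float
    rmsee: tuple[float, float]
    rmsep: tuple[float, float]
    A_chosen: int
    history: list[float] = field(default_factory=list)


def eta_components(rmsee: np.ndarray, rmsep: np.ndarray,
                   n_train: int, n_test: int, n_selected: int) -> tuple[float, ...]:
    """Pooled per-response error η_j and the composite η."""
    w_train = n_train - n_selected - 1
    denom = n_train + n_test - n_selected - 1
    if w_train < 0 or denom <= 0:
        raise ValidationError(
            f"subset too large: n_selected={n_selected} vs n_train={n_train}")
    etas = np.sqrt((w_train * np.asarray(rmsee) ** 2
                    + n_test * np.asarray(rmsep) ** 2) / denom)
    return float(np.sqrt((etas ** 2).sum())), *(float(e) for e in etas)


def fitness(subset: np.ndarray, X_train, Y_train, X_test, Y_test,
            a_max: int = 10, cv_folds: int = 7, seed: int = 0) -> FitnessResult:
    """Price one descriptor subset (boolean mask or index array)."""
    subset = np.asarray(subset)
    if subset.dtype == bool:
        subset = np.nonzero(subset)[0]
    if subset.size == 0:
        raise ValidationError("empty descriptor subset")
    Xtr = np.asarray(X_train, dtype=float)[:, subset]
    Xte = np.asarray(X_test, dtype=float)[:, subset]
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
    a_cap = min(a_max, Xtr.shape[0] - 1, Xtr.shape[1])
    rmsecv = _cv_rmsecv(Xtr, Y_train, a_cap, cv_folds, seed)
    A = int(np.argmin(rmsecv.sum(axis=1))) + 1
    model = NipalsPLS(n_components=A).fit(Xtr, Y_train)
    rmsee = rmse(model.predict(Xtr), Y_train)
    rmsep = rmse(model.predict(Xte), Y_test)
    eta, eta1, eta2 = eta_components(rmsee, rmsep, Xtr.shape[0], Xte.shape[0],
                                     subset.size)
    return FitnessResult(eta, eta1, eta2,
                         tuple(map(float, rmsee)), tuple(map(float, rmsep)),
                         model.n_components_)


# ---------------------------------------------------------------------------
# GA machinery


def _repair(chrom: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> None:
    """In-place cardinality repair by random add/drop into [lo, hi]."""
    on = np.nonzero(chrom)[0]
    if on.size > hi:
        drop = rng.choice(on, size=on.size - hi, replace=False)
        chrom[drop] = False
    elif on.size < lo:
        off = np.nonzero(~chrom)[0]
        add = rng.choice(off, size=lo - on.size, replace=False)
        chrom[add] = True


def _select_parent(fits: np.ndarray, fn: str, rng: np.random.Generator) -> int:
    m = fits.size
    if fn == "uniform":
        return int(rng.integers(m))
    if fn == "tournament":
        a, b = rng.integers(m), rng.integers(m)
        return int(a if fits[a] <= fits[b] else b)
    # roulette on inverted fitness (minimisation)
    w = fits.max() - fits + 1e-12
    return int(rng.choice(m, p=w / w.sum()))


def _crossover(p1: np.ndarray, p2: np.ndarray, fn: str,
               rng: np.random.Generator) -> np.ndarray:
    p = p1.size
    if fn == "scattered":
        mask = rng.random(p) < 0.5
        return np.where(mask, p1, p2)
    if fn == "single_point":
        cut = int(rng.integers(1, p))
        return np.concatenate([p1[:cut], p2[cut:]])
    cut1, cut2 = sorted(rng.integers(1, p, size=2).tolist())
    child = p1.copy()
    child[cut1:cut2] = p2[cut1:cut2]
    return child


def _mutate(chrom: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    # per-gene flip probability scaled so a mutated chromosome sees ~5*rate
    # flips regardless of the descriptor-pool size
    prob = min(1.0, 5.0 * rate / chrom.size)
    flips = rng.random(chrom.size) < prob
    chrom[flips] = ~chrom[flips]


def run_ga(X_train, Y_train, X_test, Y_test, descriptor_names,
           config: GAConfig) -> SelectionResult:
    """Seeded GA search for the descriptor subset minimising η.

    Elitism of one guarantees the best-fitness history is non-increasing.
    Evaluated subsets are cached, so re-visited chromosomes cost nothing.
    """
    X_train = np.asarray(X_train, dtype=float)
    p = X_train.shape[1]
    names = list(descriptor_names)
    if len(names) != p:
        raise ValidationError("descriptor_names length does not match X columns")
    lo, hi = config.n_select_min, min(config.n_select_max, p)
    if lo > p:
        raise ValidationError(f"n_select_min={lo} exceeds pool size {p}")
    rng = np.random.default_rng(config.seed)
    cache: dict[frozenset, FitnessResult] = {}

    def evaluate(chrom: np.ndarray) -> FitnessResult:
        key = frozenset(np.nonzero(chrom)[0].tolist())
        if key not in cache:
            cache[key] = fitness(chrom, X_train, Y_train, X_test, Y_test,
                                 a_max=config.a_max, cv_folds=config.cv_folds,
                                 seed=config.seed)
        return cache[key]

    pop = np.zeros((config.population_size, p), dtype=bool)
    for i in range(config.population_size):
        size = int(rng.integers(lo, hi + 1))
        pop[i, rng.choice(p, size=size, replace=False)] = True
    results = [evaluate(c) for c in pop]
    fits = np.array([r.eta for r in results])
    history: list[float] = []

    for _ in range(config.generations):
        best = int(np.argmin(fits))
        history.append(float(fits[best]))
        children = [pop[best].copy()]  # elitism of 1
        while len(children) < config.population_size:
            i = _select_parent(fits, config.selection_fn, rng)
            if rng.random() < config.crossover_fraction:
                j = _select_parent(fits, config.selection_fn, rng)
                child = _crossover(pop[i], pop[j], config.crossover_fn, rng)
            else:
                child = pop[i].copy()
            _mutate(child, config.mutation_rate, rng)
            _repair(child, lo, hi, rng)
            children.append(child)
        pop = np.array(children)
        results = [evaluate(c) for c in pop]
        fits = np.array([r.eta for r in results])

    best = int(np.argmin(fits))
    history.append(float(fits[best]))
    res = results[best]
    selected = [names[j] for j in np.nonzero(pop[best])[0]]
    return SelectionResult(
        selected_names=selected, eta=res.eta, eta1=res.eta1, eta2=res.eta2,
        rmsee=res.rmsee, rmsep=res.rmsep, A_chosen=res.A, history=history)


def grid_search(X_train, Y_train, X_test, Y_test, descriptor_names,
                base_config: GAConfig,
                grid: dict[str, list] | None = None) -> pd.DataFrame:
    """Exhaustive GA hyper-parameter sweep; one derived seed per cell.

    The default grid mirrors the conventional tuning ranges: crossover
    fraction and mutation rate in {0.2, 0.4, 0.6, 0.8} plus the selection and
    crossover function enums.
    """
    if grid is None:
        grid = {
            "crossover_fraction": [0.2, 0.4, 0.6, 0.8],
            "mutation_rate": [0.2, 0.4, 0.6, 0.8],
            "selection_fn": list(SELECTION_FNS),
            "crossover_fn": list(CROSSOVER_FNS),
        }
    keys = sorted(grid)
    rows = []
    for cell_idx, combo in enumerate(product(*(grid[k] for k in keys))):
        overrides = dict(zip(keys, combo))
        cfg = replace(base_config, **overrides,
                      seed=(base_config.seed + 1000003 * (cell_idx + 1)) % (2 ** 31))
        res = run_ga(X_train, Y_train, X_test, Y_test, descriptor_names, cfg)
        rows.append({**overrides, "seed": cfg.seed, "eta": res.eta,
                     "n_selected": len(res.selected_names),
                     "A_chosen": res.A_chosen,
                     "selected_names": ";".join(res.selected_names)})
    return pd.DataFrame(rows).sort_values("eta", kind="stable").reset_index(drop=True)
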