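"""Bound-constrained minimization of trace-comparison costs.

All algorithms work on parameters normalized to the unit cube: with
bounds (l_i, h_i) the search variable is u_i = (x_i - l_i)/(h_i - l_i),
so parameters of very different magnitudes (e.g. conductance densities
vs time constants) are treated on an equal footing.  Candidates are
never evaluated outside [0, 1]^d.

Four algorithms are provided:

``EO``
    A generational evolutionary algorithm with weak elitism:
    tournament selection, blend (BLX-alpha) crossover, per-gene
    Gaussian mutation whose scale anneals geometrically from
    ``mutation_sigma`` to ``mutation_sigma_final`` over the configured
    generations, offspring clipped to the cube, and the single best
    parent carried over each generation so the best-so-far cost never
    increases.  The wide blend interval (alpha = 0.5) lets the
    population extrapolate along correlated parameter valleys, and the
    annealed mutation refines the solution to high precision once the
    search has localized.
``SA``
    Canonical simulated annealing: Gaussian proposals around a single
    state, Metropolis acceptance, geometric cooling every ``dwell``
    evaluations from T0 down to Tf.
``NM``
    Nelder-Mead downhill simplex (scipy), bounds enforced by clipping.
``LBFGSB``
    Limited-memory BFGS with native box constraints (scipy), gradients
    by finite differences.

Every run records a :class:`FitHistory` (per-generation best/mean/
median/worst and populations) and returns a :class:`FitResult` whose
``best_params`` are denormalized back to physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt

__all__ = [
    "OptimizerSettings",
    "FitHistory",
    "FitResult",
    "normalize_params",
    "denormalize_params",
    "optimize",
    "population_stats",
    "grid_slices",
    "ALGORITHMS",
]

ALGORITHMS = ("EO", "SA", "NM", "LBFGSB")


@dataclass
class SASettings:
    T0: float = 1.0
    Tf: float = 1e-4
    cooling: float = 0.95
    dwell: int = 20
    max_evals: int = 5000


@dataclass
class NMSettings:
    max_iter: int = 1000
    xtol: float = 1e-8
    ftol: float = 1e-8


@dataclass
class LBFGSBSettings:
    max_iter: int = 500
    accuracy: float = 1e-10  # ftol passed to the scipy implementation


@dataclass
class OptimizerSettings:
    """Algorithm choice, bounds and hyperparameters for one fit."""

    algorithm: str
    bounds: list
    seed: int = 1234
    start: list | None = None
    pop_size: int = 100
    generations: int = 100
    mutation_rate: float = 0.25
    mutation_sigma: float = 0.3
    mutation_sigma_final: float = 1e-6  # set equal to mutation_sigma to disable annealing
    blend_alpha: float = 0.5
    tournament_size: int = 4
    out_of_bounds: str = "clip"  # or "reflect"
    sa: SASettings = field(default_factory=SASettings)
    nm: NMSettings = field(default_factory=NMSettings)
    lbfgsb: LBFGSBSettings = field(default_factory=LBFGSBSettings)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid: {', '.join(ALGORITHMS)}"
            )
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("every bound must be finite with lower < upper")
        if self.algorithm == "EO" and self.pop_size < 2:
            raise ValueError("the evolutionary algorithm needs pop_size >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be at least 1")
        if not 0 < self.mutation_sigma_final <= self.mutation_sigma:
            raise ValueError(
                "mutation_sigma_final must lie in (0, mutation_sigma]"
            )
        if self.out_of_bounds not in ("clip", "reflect"):
            raise ValueError("out_of_bounds must be 'clip' or 'reflect'")

    @property
    def dim(self) -> int:
        return len(self.bounds)


@dataclass
class FitHistory:
    """Per-generation fitness statistics and populations."""

    best: list = field(default_factory=list)
    mean: list = field(default_factory=list)
    median: list = field(default_factory=list)
    worst: list = field(default_factory=list)
    populations: list = field(default_factory=list)  # normalized candidates

    def record(self, fitnesses: np.ndarray, population: np.ndarray) -> None:
        self.best.append(float(np.min(fitnesses)))
        self.mean.append(float(np.mean(fitnesses)))
        self.median.append(float(np.median(fitnesses)))
        self.worst.append(float(np.max(fitnesses)))
        self.populations.append(np.array(population, copy=True))


@dataclass
class FitResult:
    best_params: np.ndarray  # denormalized
    best_fitness: float
    history: FitHistory
    final_population: list  # [(denormalized params, fitness), ...]
    seed: int
    n_evaluations: int


def normalize_params(x, bounds) -> np.ndarray:
    """Map a physical parameter vector onto the unit cube."""
    x = np.asarray(x, dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("parameter vector outside its bounds")
    return (x - lo) / (hi - lo)


def denormalize_params(u, bounds) -> np.ndarray:
    """Map a unit-cube vector back to physical units."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("normalized vector outside [0, 1]")
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + u * (hi - lo)


class _CountingObjective:
    """Wraps the user objective: counts evaluations, checks the contract."""

    def __init__(self, objective):
        self.objective = objective
        self.n = 0
        self.best_u = None
        self.best_f = np.inf

    def __call__(self, u: np.ndarray) -> float:
        u = np.asarray(u, dtype=float)
        if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
            raise ValueError(f"candidate outside the unit cube: {u}")
        f = float(self.objective(np.clip(u, 0.0, 1.0)))
        if not np.isfinite(f):
            raise ValueError(f"objective returned a non-finite value at {u}")
        self.n += 1
        if f < self.best_f:
            self.best_f = f
            self.best_u = u.copy()
        return f


def _repair(u: np.ndarray, how: str) -> np.ndarray:
    if how == "reflect":
        u = np.where(u < 0, -u, u)
        u = np.where(u > 1, 2 - u, u)
    return np.clip(u, 0.0, 1.0)


def _run_eo(obj, settings: OptimizerSettings, rng, history: FitHistory):
    d = settings.dim
    pop = rng.uniform(size=(settings.pop_size, d))
    if settings.start is not None:
        pop[0] = normalize_params(settings.start, settings.bounds)
    fit = np.array([obj(u) for u in pop])
    history.record(fit, pop)
    # geometric annealing of the mutation scale across generations
    decay = (settings.mutation_sigma_final / settings.mutation_sigma) ** (
        1.0 / max(settings.generations - 1, 1)
    )
    for gen in range(settings.generations):
        sigma = settings.mutation_sigma * decay**gen
        elite_idx = int(np.argmin(fit))
        elite, elite_fit = pop[elite_idx].copy(), fit[elite_idx]
        offspring = np.empty_like(pop)
        for k in range(settings.pop_size):
            parents = []
            for _ in range(2):
                idx = rng.integers(settings.pop_size, size=settings.tournament_size)
                parents.append(pop[idx[np.argmin(fit[idx])]])
            p1, p2 = parents
            lo = np.minimum(p1, p2)
            hi = np.maximum(p1, p2)
            ext = settings.blend_alpha * (hi - lo)
            offspring[k] = rng.uniform(lo - ext, hi + ext)
        mutate = rng.uniform(size=offspring.shape) < settings.mutation_rate
        offspring = offspring + mutate * rng.normal(
            scale=sigma, size=offspring.shape
        )
        offspring = _repair(offspring, settings.out_of_bounds)
        off_fit = np.array([obj(u) for u in offspring])
        # weak elitism: the best parent survives, replacing the worst child
        if elite_fit < off_fit.min():
            worst = int(np.argmax(off_fit))
            offspring[worst] = elite
            off_fit[worst] = elite_fit
        pop, fit = offspring, off_fit
        history.record(fit, pop)
    return pop, fit


def _run_sa(obj, settings: OptimizerSettings, rng, history: FitHistory):
    d = settings.dim
    if settings.start is not None:
        u = normalize_params(settings.start, settings.bounds)
    else:
        u = rng.uniform(size=d)
    f = obj(u)
    best_u, best_f = u.copy(), f
    T = settings.sa.T0
    evals = 0
    block_f = [f]
    while evals < settings.sa.max_evals and T > settings.sa.Tf:
        for _ in range(settings.sa.dwell):
            if evals >= settings.sa.max_evals:
                break
            prop = _repair(
                u + rng.normal(scale=settings.mutation_sigma, size=d),
                settings.out_of_bounds,
            )
            fp = obj(prop)
            evals += 1
            if fp <= f or rng.uniform() < np.exp(-(fp - f) / T):
                u, f = prop, fp
                if f < best_f:
                    best_u, best_f = u.copy(), f
            block_f.append(f)
        history.record(np.array(block_f), u[None, :])
        block_f = [f]
        T *= settings.sa.cooling
    return best_u[None, :], np.array([best_f])


def _run_scipy_local(obj, settings: OptimizerSettings, rng, history: FitHistory):
    d = settings.dim
    if settings.start is not None:
        u0 = normalize_params(settings.start, settings.bounds)
    else:
        u0 = np.full(d, 0.5)

    def wrapped(u):
        # projection plus a quadratic infeasibility penalty: keeps every
        # objective call inside the cube while giving the simplex a
        # slope back toward the feasible region (plain clipping leaves
        # the landscape flat outside and can strand Nelder-Mead there)
        u = np.asarray(u, dtype=float)
        uc = np.clip(u, 0.0, 1.0)
        dist2 = float(np.sum((u - uc) ** 2))
        return obj(uc) + 1e3 * dist2

    def cb(xk, *args):
        f = obj(_repair(np.asarray(xk, dtype=float), "clip"))
        history.record(np.array([f]), _repair(np.asarray(xk), "clip")[None, :])

    if settings.algorithm == "NM":
        res = sciopt.minimize(
            wrapped, u0, method="Nelder-Mead",
            options={
                "maxiter": settings.nm.max_iter,
                "xatol": settings.nm.xtol,
                "fatol": settings.nm.ftol,
            },
            callback=cb,
        )
    else:  # LBFGSB
        res = sciopt.minimize(
            wrapped, u0, method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * d,
            options={
                "maxiter": settings.lbfgsb.max_iter,
                "ftol": settings.lbfgsb.accuracy,
                "eps": 1e-6,
            },
            callback=cb,
        )
    u_best = _repair(np.asarray(res.x, dtype=float), "clip")
    f_best = obj(u_best)
    return u_best[None, :], np.array([f_best])


def optimize(objective, settings: OptimizerSettings) -> FitResult:
    """Minimize *objective* (defined on physical parameters) within bounds.

    The objective receives denormalized parameter vectors; all search
    happens on the unit cube with a single seeded generator, so a fixed
    seed reproduces the result bit for bit.
    """
    if settings.generations < 1 and settings.algorithm == "EO":
        raise ValueError("need at least one generation")
    rng = np.random.default_rng(settings.seed)
    bounds = settings.bounds

    def unit_objective(u):
        return objective(denormalize_params(u, bounds))

    obj = _CountingObjective(unit_objective)
    history = FitHistory()
    if settings.algorithm == "EO":
        pop, fit = _run_eo(obj, settings, rng, history)
    elif settings.algorithm == "SA":
        pop, fit = _run_sa(obj, settings, rng, history)
    else:
        pop, fit = _run_scipy_local(obj, settings, rng, history)
    best_u, best_f = obj.best_u, obj.best_f
    final_population = [
        (denormalize_params(u, bounds), float(f)) for u, f in zip(pop, fit)
    ]
    return FitResult(
        best_params=denormalize_params(best_u, bounds),
        best_fitness=float(best_f),
        history=history,
        final_population=final_population,
        seed=settings.seed,
        n_evaluations=obj.n,
    )


def population_stats(final_population) -> dict:
    """Descriptive statistics of the fitness values of a population."""
    if not final_population:
        raise ValueError("empty population")
    f = np.array([fit for _, fit in final_population], dtype=float)
    return {
        "min": float(f.min()),
        "max": float(f.max()),
        "mean": float(f.mean()),
        "median": float(np.median(f)),
        "std": float(f.std()),
    }


def grid_slices(objective, best, bounds, n_points: int = 20, ranges=None):
    """One-dimensional scans of the cost around an optimum.

    For each parameter j the objective is evaluated on ``n_points``
    equally spaced values spanning its bound interval (or a caller-
    supplied narrower window) with all other parameters held at
    ``best``.  Returns a list of ``(grid, values)`` pairs.
    """
    best = np.asarray(best, dtype=float)
    if n_points < 2:
        raise ValueError("need at least two grid points per slice")
    slices = []
    for j, (lo, hi) in enumerate(bounds):
        if ranges is not None:
            lo, hi = ranges[j]
        grid = np.linspace(lo, hi, n_points)
        values = np.empty(n_points)
        for k, g in enumerate(grid):
            x = best.copy()
            x[j] = g
            values[k] = objective(x)
        slices.append((grid, values))
    return slices
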