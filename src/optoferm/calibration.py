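"""Per-condition kinetic parameter estimation.

Each (light intensity, EL222 copy number) condition gets its own fit of
the six batch-model parameters to replicate OD and fluorescence time
courses plus the known initial glucose concentration.  The fit minimizes
a relative least-squares objective with a global-best particle swarm in
log10-parameter space — parameters span several orders of magnitude and
are strictly positive, so the log transform both enforces positivity and
equalizes search scales.

The fitted values, one per condition, become the labels of the
Gaussian-process training sets consumed by :mod:`optoferm.gp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    Condition,
    KineticParams,
    PARAM_NAMES,
    SimulationError,
    StateVector,
    simulate,
)

__all__ = [
    "FitProblem",
    "FitResult",
    "PSOSettings",
    "PSOResult",
    "DEFAULT_BOUNDS",
    "fit_objective",
    "pso_minimize",
    "fit_condition",
    "build_training_set",
    "GPTrainingSet",
]

#: Default search boxes spanning plausible yeast batch kinetics.  The two
#: half-saturation constants get deliberately tight upper bounds: a k_g
#: comparable to the initial glucose concentration, or a beta comparable
#: to mu_max, makes the corresponding saturating law indistinguishable
#: from a linear one and opens a flat likelihood ridge along which
#: mu_max (with k_g) or alpha (with beta) can drift arbitrarily.  Yeast
#: glucose half-saturations sit well below 1 g/L, and an identifiable
#: production law needs beta below the growth rates actually observed.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "mu_max": (0.01, 1.0),     # 1/h
    "k_g": (0.005, 1.0),       # g/L
    "alpha": (1.0, 1e6),       # a.u./h
    "beta": (1e-3, 0.3),       # 1/h
    "d_p": (1e-4, 0.5),        # 1/h
    "y_gb": (0.1, 10.0),       # (g/L)/OD
}


@dataclass
class FitProblem:
    """Observations for one condition: replicate (times, od, protein) series.

    ``observations`` maps replicate index -> dict with keys ``times``,
    ``od``, ``protein`` (aligned 1-D arrays, >= 3 time points each).
    Initial states are taken from the data: OD at the first time point
    (averaged over replicates), protein at ``cp0`` (default 0: dark
    pre-growth gives no expression before induction), glucose at the
    measured ``initial_glucose``.
    """

    observations: dict[int, dict[str, np.ndarray]]
    initial_glucose: float
    condition: Condition
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    weights: dict[str, float] = field(default_factory=lambda: {"od": 1.0, "protein": 1.0})
    cp0: float = 0.0
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        if not self.observations:
            raise ValueError("FitProblem needs at least one replicate")
        for rep, obs in self.observations.items():
            t = np.asarray(obs["times"], dtype=float)
            if t.size < 3:
                raise ValueError(f"replicate {rep} has fewer than 3 time points")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"replicate {rep} times not strictly increasing")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"invalid bounds for {name}: [{lo}, {hi}]")
        if self.initial_glucose <= 0:
            raise ValueError("initial_glucose must be positive")
        # cache per-problem arrays used on every objective evaluation
        self._times = self.shared_times()
        self._init = self.initial_state()
        self._obs_idx = {
            rep: np.searchsorted(self._times, np.asarray(o["times"], float))
            for rep, o in self.observations.items()
        }

    def initial_state(self) -> StateVector:
        od0 = float(np.mean([obs["od"][0] for obs in self.observations.values()]))
        return StateVector(
            c_b=od0, c_p=self.cp0, c_g=self.initial_glucose, n=self.condition.copy_number
        )

    def shared_times(self) -> np.ndarray:
        """Sorted union of all replicate observation times."""
        all_t = np.concatenate([np.asarray(o["times"], float) for o in self.observations.values()])
        return np.unique(all_t)


@dataclass
class FitResult:
    params: KineticParams
    objective_value: float
    n_evaluations: int
    seed: int
    converged: bool
    condition: Condition | None = None


@dataclass
class PSOSettings:
    """Canonical global-best PSO settings (constriction-style defaults)."""

    swarm_size: int = 40
    iterations: int = 300
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 5:
            raise ValueError("swarm size must be >= 5")


@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    trace: np.ndarray  # best-ever objective after each iteration (nonincreasing)


def fit_objective(params: KineticParams, problem: FitProblem) -> float:
    """Relative weighted sum of squared residuals across channels/replicates.

    Each channel's pooled residuals are divided by the pooled mean-square
    of its observations, so OD (order 0.1-20) and fluorescence (order
    1e3-1e5 a.u.) contribute comparably.  Solver failures map to +inf so
    the swarm can route around non-integrable parameter sets.
    """
    times = problem._times
    init = problem._init
    try:
        traj = simulate(init, params, times, rtol=problem.rtol, atol=problem.atol,
                        condition=problem.condition)
    except (SimulationError, ValueError):
        return float("inf")

    model = {"od": traj.c_b, "protein": traj.c_p}
    total = 0.0
    for channel in ("od", "protein"):
        w = problem.weights.get(channel, 1.0)
        if w == 0:
            continue
        sq_res = 0.0
        sq_obs = 0.0
        n_obs = 0
        for rep, obs in problem.observations.items():
            idx = problem._obs_idx[rep]
            pred = model[channel][idx]
            y = np.asarray(obs[channel], dtype=float)
            sq_res += float(np.sum((pred - y) ** 2))
            sq_obs += float(np.sum(y**2))
            n_obs += y.size
        ms = sq_obs / n_obs if n_obs else 1.0
        if ms <= 0:
            ms = 1.0
        total += w * sq_res / ms
    if not np.isfinite(total):
        return float("inf")
    return total


def pso_minimize(
    objective,
    bounds: np.ndarray,
    settings: PSOSettings | None = None,
) -> PSOResult:
    """Global-best particle swarm minimization in a box.

    Velocity update ``v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)``
    with positions reflected at the bounds.  Deterministic for a fixed
    seed; NaN objective values are treated as +inf.

    Parameters
    ----------
    objective : callable mapping a 1-D position to a scalar
    bounds : array of shape (d, 2) with low < high per dimension
    """
    settings = settings or PSOSettings()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must be (d, 2) with low < high")
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = bounds.shape[0]
    rng = np.random.default_rng(settings.seed)

    def evaluate(x: np.ndarray) -> float:
        v = objective(x)
        return float("inf") if (v is None or np.isnan(v)) else float(v)

    x = rng.uniform(lo, hi, size=(settings.swarm_size, d))
    span = hi - lo
    v = rng.uniform(-span, span, size=(settings.swarm_size, d)) * 0.1

    f = np.array([evaluate(xi) for xi in x])
    n_eval = settings.swarm_size
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

    trace = np.empty(settings.iterations)
    for it in range(settings.iterations):
        r1 = rng.random((settings.swarm_size, d))
        r2 = rng.random((settings.swarm_size, d))
        v = (
            settings.inertia * v
            + settings.cognitive * r1 * (pbest_x - x)
            + settings.social * r2 * (gbest_x - x)
        )
        x = x + v
        # reflect at the box walls (may need several passes for big steps)
        for _ in range(8):
            below, above = x < lo, x > hi
            if not (below.any() or above.any()):
                break
            x = np.where(below, 2 * lo - x, x)
            x = np.where(above, 2 * hi - x, x)
            v = np.where(below | above, -v, v)
        x = np.clip(x, lo, hi)

        f = np.array([evaluate(xi) for xi in x])
        n_eval += settings.swarm_size
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trace[it] = gbest_f

    return PSOResult(x=gbest_x, fun=gbest_f, n_evaluations=n_eval, trace=trace)


def fit_condition(
    problem: FitProblem,
    settings: PSOSettings | None = None,
    *,
    polish: bool = True,
    polish_maxfev: int = 4000,
) -> FitResult:
    """Fit the six kinetic parameters for one condition.

    Runs the particle swarm over :func:`fit_objective` in log10-parameter
    space within the problem's bounds, then (by default) polishes the
    swarm's best point with a bounded Nelder-Mead simplex — the alpha/beta
    half-saturation pair forms a long flat valley that population search
    localizes but descends slowly; the derivative-free simplex finishes
    the descent cheaply.  Raises if no parameter set in the box is
    integrable.
    """
    from scipy.optimize import minimize

    settings = settings or PSOSettings()
    names = list(PARAM_NAMES)
    box = np.log10(np.array([problem.bounds[n] for n in names], dtype=float))

    def obj(z: np.ndarray) -> float:
        theta = KineticParams.from_array(10.0**z)
        return fit_objective(theta, problem)

    res = pso_minimize(obj, box, settings)
    if not np.isfinite(res.fun):
        raise RuntimeError(
            f"model never integrable in bounds for condition {problem.condition}"
        )
    x, fun, n_eval = res.x, res.fun, res.n_evaluations
    if polish:
        nm_bounds = [(lo, hi) for lo, hi in box]
        for _ in range(3):  # simplex restarts from its own endpoint
            prev = fun
            nm = minimize(
                obj, x, method="Nelder-Mead", bounds=nm_bounds,
                options={"maxfev": polish_maxfev, "xatol": 1e-10, "fatol": 1e-14},
            )
            n_eval += nm.nfev
            if np.isfinite(nm.fun) and nm.fun <= fun:
                x, fun = nm.x, float(nm.fun)
            if nm.success or fun < 1e-10 or fun > prev * (1 - 1e-3):
                break  # converged, or a restart would gain < 0.1%
    params = KineticParams.from_array(10.0**x)
    return FitResult(
        params=params,
        objective_value=fun,
        n_evaluations=n_eval,
        seed=settings.seed,
        converged=True,
        condition=problem.condition,
    )


# ---------------------------------------------------------------------------
# GP training-set assembly
# ---------------------------------------------------------------------------

@dataclass
class GPTrainingSet:
    """Features V (2 x nd: light intensity, copy number) and labels L (nd,)
    for one kinetic parameter across all fitted conditions."""

    V: np.ndarray
    L: np.ndarray
    parameter: str

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.V.ndim != 2 or self.V.shape[0] != 2:
            raise ValueError("V must have shape (2, nd)")
        if self.L.shape != (self.V.shape[1],):
            raise ValueError("L must have shape (nd,)")
        if np.isnan(self.V).any() or np.isnan(self.L).any():
            raise ValueError("training set contains NaN")
        if self.nd < 2:
            raise ValueError("need at least 2 training conditions")

    @property
    def nd(self) -> int:
        return self.V.shape[1]


def build_training_set(results: list[FitResult]) -> dict[str, GPTrainingSet]:
    """Assemble one GP training set per kinetic parameter.

    Rows are sorted by copy number then light intensity so the output is
    independent of input order.  Duplicate (I, n) conditions with
    different fitted labels are kept (the GP's noise variance absorbs the
    scatter) with a warning.
    """
    import warnings

    if len(results) < 2:
        raise ValueError("need at least 2 fitted conditions to build a training set")
    keyed = sorted(
        results,
        key=lambda r: (r.condition.copy_number, r.condition.light_intensity),
    )
    keys = [(r.condition.light_intensity, r.condition.copy_number) for r in keyed]
    if len(set(keys)) < len(keys):
        warnings.warn(
            "duplicate (light, copy_number) conditions in training set; "
            "keeping all rows (GP noise absorbs the scatter)",
            stacklevel=2,
        )
    V = np.array(
        [[r.condition.light_intensity for r in keyed],
         [r.condition.copy_number for r in keyed]],
        dtype=float,
    )
    sets = {}
    for name in PARAM_NAMES:
        L = np.array([getattr(r.params, name) for r in keyed], dtype=float)
        sets[name] = GPTrainingSet(V=V, L=L, parameter=name)
    return sets
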