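"""One-call end-to-end pipeline on synthetic data.

Chains the full workflow — generate the characterization design from the
truth surface, fit kinetic parameters per condition, train the six
parameter GPs, scan the dose landscape — and reports recovery metrics
against the generating truth.  Used by the example scripts and by the
acceptance checks; every stage is also callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import FitProblem, FitResult, PSOSettings, build_training_set, fit_condition
from .gp import ParameterSurrogate
from .model import Condition, PARAM_NAMES, StateVector
from .predict import DoseResponseSurface, scan_dose_landscape
from .synthetic import (
    DesignSettings,
    NoiseModel,
    SyntheticDataset,
    TruthSurface,
    TruthSurfaceSettings,
    generate_design,
    make_truth_surface,
)

__all__ = ["PipelineResult", "run_pipeline", "problems_from_dataset", "fit_dataset"]


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    fits: list[FitResult]
    surrogate: ParameterSurrogate
    surface: DoseResponseSurface
    recovery: pd.DataFrame  # per condition: fitted vs truth relative errors

    def argmax_by_copy_number(self) -> dict[int, float]:
        return {n: v[0] for n, v in sorted(self.surface.argmax.items())}

    def argmax_nonincreasing(self) -> bool:
        """The headline qualitative check: the production-maximizing light
        intensity must not increase with EL222 copy number."""
        vals = [v for _, v in sorted(self.argmax_by_copy_number().items())]
        return all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def median_relative_error(self, parameter: str) -> float:
        return float(self.recovery[f"rel_err_{parameter}"].median())


def problems_from_dataset(
    dataset: SyntheticDataset,
    *,
    conditions: list[tuple[float, int]] | None = None,
    noiseless: bool = False,
    **problem_kwargs,
) -> list[FitProblem]:
    """Build per-condition fit problems from a synthetic dataset.

    ``noiseless`` swaps the noisy replicate observations for the single
    noise-free truth trajectory (self-consistency checks).
    """
    keys = conditions if conditions is not None else sorted(
        dataset.observations, key=lambda k: (k[1], k[0]))
    problems = []
    for key in keys:
        I, n = key
        if noiseless:
            traj = dataset.noiseless[key]
            obs = {0: {"times": traj.times, "od": traj.c_b, "protein": traj.c_p}}
        else:
            obs = dataset.observations[key]
        problems.append(FitProblem(
            observations=obs,
            initial_glucose=dataset.design.glucose0,
            condition=Condition(I, n),
            **problem_kwargs,
        ))
    return problems


def fit_dataset(
    dataset: SyntheticDataset,
    settings: PSOSettings,
    *,
    noiseless: bool = False,
    polish_maxfev: int = 4000,
    conditions: list[tuple[float, int]] | None = None,
) -> list[FitResult]:
    """Fit every requested condition; per-condition PSO seeds derive
    deterministically from the settings seed."""
    problems = problems_from_dataset(dataset, conditions=conditions, noiseless=noiseless)
    results = []
    for i, prob in enumerate(problems):
        s = PSOSettings(
            swarm_size=settings.swarm_size, iterations=settings.iterations,
            inertia=settings.inertia, cognitive=settings.cognitive,
            social=settings.social, seed=settings.seed * 1000 + i,
        )
        results.append(fit_condition(prob, s, polish_maxfev=polish_maxfev))
    return results


def _recovery_table(fits: list[FitResult], surface: TruthSurface) -> pd.DataFrame:
    rows = []
    for r in fits:
        truth = surface.params_at(r.condition)
        row = {"copy_number": r.condition.copy_number,
               "light_umol_m2_s": r.condition.light_intensity,
               "objective": r.objective_value}
        for name in PARAM_NAMES:
            tv, fv = getattr(truth, name), getattr(r.params, name)
            row[f"truth_{name}"] = tv
            row[f"fit_{name}"] = fv
            row[f"rel_err_{name}"] = abs(fv - tv) / tv
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    seed: int = 0,
    *,
    truth_settings: TruthSurfaceSettings | None = None,
    noise: NoiseModel | None = None,
    design: DesignSettings | None = None,
    pso: PSOSettings | None = None,
    polish_maxfev: int = 1500,
    gp_restarts: int = 6,
    intensity_grid: np.ndarray | None = None,
    scan_horizon: float = 24.0,
) -> PipelineResult:
    """Run generate -> fit -> train-gp -> scan on one master seed.

    The PSO default here (swarm 16 x 60 iterations plus simplex polish)
    is a test-scale budget tuned for the 18-condition design; raise it
    for production fits.
    """
    surface = make_truth_surface(truth_settings)
    dataset = generate_design(surface, noise, design, seed=seed)
    pso = pso or PSOSettings(swarm_size=16, iterations=60, seed=seed)
    fits = fit_dataset(dataset, pso, polish_maxfev=polish_maxfev)
    sets = build_training_set(fits)
    surrogate = ParameterSurrogate.train(sets, restarts=gp_restarts, seed=seed)
    if intensity_grid is None:
        intensity_grid = np.arange(0.0, 70.0 + 1e-9, 2.5)
    dose = scan_dose_landscape(
        surrogate,
        list(dataset.design.copy_numbers),
        intensity_grid,
        StateVector(c_b=dataset.design.od0, c_p=0.0, c_g=dataset.design.glucose0),
        horizon=scan_horizon,
    )
    return PipelineResult(
        dataset=dataset,
        fits=fits,
        surrogate=surrogate,
        surface=dose,
        recovery=_recovery_table(fits, surface),
    )
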