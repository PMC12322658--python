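"""Hybrid-model prediction: GP-surrogate parameters driving the ODE model.

Once the six parameter GPs are trained, any (light intensity, copy
number) condition — measured or not — can be simulated by plugging the
posterior-mean parameters into the batch model.  Scanning a grid of
intensities per copy number yields the dose-response landscape and the
production-maximizing intensity for each strain, the quantity a process
engineer actually wants from the characterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp import ParameterSurrogate
from .model import Condition, StateVector, Trajectory, simulate

__all__ = [
    "DoseResponseSurface",
    "predict_trajectory",
    "scan_dose_landscape",
]

#: Relative tolerance defining the "plateau" around the maximum: grid
#: points within this fraction of the best final protein are reported as
#: part of the optimal-intensity interval.
PLATEAU_TOL = 0.02


@dataclass
class DoseResponseSurface:
    """Predicted production landscape over a (light, copy-number) grid.

    ``table`` has one row per grid point with final protein (total and
    per-OD) and final biomass; ``argmax`` maps each copy number to
    (best intensity, interval low, interval high) where the interval
    collects grid points within ``plateau_tol`` of the maximum.
    """

    table: pd.DataFrame
    argmax: dict[int, tuple[float, float, float]]
    plateau_tol: float = PLATEAU_TOL
    objective: str = "final_protein"

    def argmax_intensity(self, copy_number: int) -> float:
        return self.argmax[copy_number][0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def predict_trajectory(
    condition: Condition,
    initial: StateVector,
    times: np.ndarray,
    surrogate: ParameterSurrogate,
    **simulate_kwargs,
) -> Trajectory:
    """Simulate the hybrid model at a condition.

    Deterministic given the trained surrogate: the GP posterior means at
    (I, n) are assembled into kinetic parameters and integrated from
    ``initial`` over ``times``.
    """
    params, _ = surrogate.predict_params(condition)
    return simulate(initial, params, times, condition=condition, **simulate_kwargs)


def scan_dose_landscape(
    surrogate: ParameterSurrogate,
    copy_numbers: list[int],
    intensity_grid: np.ndarray,
    initial: StateVector | None = None,
    horizon: float = 24.0,
    *,
    objective: str = "final_protein",
    plateau_tol: float = PLATEAU_TOL,
    allow_extrapolation: bool = False,
    n_times: int = 49,
) -> DoseResponseSurface:
    """Predict the production landscape and locate per-strain optima.

    For every grid point the hybrid model is run from ``initial``
    (default: OD 0.1, no protein, 10 g/L glucose — the characterization
    batch start) over ``horizon`` hours; the final total protein, per-OD
    protein and biomass are recorded.  Per copy number, the argmax of
    ``objective`` ("final_protein" or "protein_per_od") is reported along
    with the plateau interval of intensities within ``plateau_tol`` of
    the maximum (a flat landscape yields a wide interval, not a
    spuriously precise point).

    Intensities outside the surrogate's training hull are refused unless
    ``allow_extrapolation`` is set: the zero-mean GP prior reverts to the
    label mean off-data, which makes extrapolated kinetics unreliable.
    """
    intensity_grid = np.asarray(intensity_grid, float)
    if intensity_grid.ndim != 1 or intensity_grid.size < 1:
        raise ValueError("intensity_grid must be a non-empty 1-D array")
    if objective not in ("final_protein", "protein_per_od"):
        raise ValueError(f"unknown objective {objective!r}")

    hull_lo, hull_hi = surrogate.models["mu_max"].intensity_hull
    if not allow_extrapolation and (
        intensity_grid.min() < hull_lo - 1e-9 or intensity_grid.max() > hull_hi + 1e-9
    ):
        raise ValueError(
            f"intensity grid [{intensity_grid.min()}, {intensity_grid.max()}] leaves the "
            f"training hull [{hull_lo}, {hull_hi}]; pass allow_extrapolation=True to override"
        )

    if initial is None:
        initial = StateVector(c_b=0.1, c_p=0.0, c_g=10.0)
    times = np.linspace(0.0, horizon, n_times)

    rows = []
    for n in copy_numbers:
        for I in intensity_grid:
            cond = Condition(float(I), int(n))
            traj = predict_trajectory(cond, initial, times, surrogate)
            final_od = float(traj.c_b[-1])
            final_protein = float(traj.c_p[-1])
            rows.append({
                "copy_number": int(n),
                "light_umol_m2_s": float(I),
                "final_protein": final_protein,
                "final_od": final_od,
                "protein_per_od": final_protein / final_od,
            })
    table = pd.DataFrame(rows)

    argmax: dict[int, tuple[float, float, float]] = {}
    flags = np.zeros(len(table), dtype=bool)
    for n in copy_numbers:
        sub = table[table["copy_number"] == n]
        vals = sub[objective].to_numpy()
        best_i = int(np.argmax(vals))
        best = vals[best_i]
        plateau = sub["light_umol_m2_s"].to_numpy()[vals >= best * (1.0 - plateau_tol)]
        argmax[int(n)] = (
            float(sub["light_umol_m2_s"].iloc[best_i]),
            float(plateau.min()),
            float(plateau.max()),
        )
        flags[sub.index[best_i]] = True
    table["is_argmax"] = flags
    return DoseResponseSurface(table=table, argmax=argmax,
                               plateau_tol=plateau_tol, objective=objective)
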