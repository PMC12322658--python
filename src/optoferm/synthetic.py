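"""Synthetic ground truth for end-to-end testing of the hybrid pipeline.

Real characterization data for this system are plate-reader time courses
of OD and fluorescence across a grid of light intensities and EL222 copy
numbers.  This module fabricates such datasets from a known closed-form
parameter surface so every pipeline stage — per-condition calibration,
GP training, dose-landscape scanning — can be scored against truth.

The truth surface encodes the biology qualitatively:

* induction: the maximum production rate alpha rises with light via a
  Hill function whose half-activation intensity K_I(n) decreases with
  copy number (more EL222, more sensitivity to light);
* phototoxicity: growth (mu_max) and production are both damped by a
  logistic function of the effective dose I*n — activated EL222 emits
  reactive oxygen species, so high copy numbers tolerate only low light;
* the remaining parameters (k_g, beta, d_p, Y_gb) are held constant.

With the default settings the production-maximizing intensity of the ODE
model falls near 50, ~17 and ~6 μmol m⁻² s⁻¹ for 1, 3 and 8 copies — the
qualitative structure observed experimentally in this system (one-copy
strains peak at high light, eight-copy strains at the lowest doses).
The dark growth rate is set so glucose is exhausted within the 24 h
measurement window at the productive conditions, as in the real
characterization where growth plateaus and fluorescence then decays.

Measurement noise is multiplicative lognormal on OD and fluorescence
plus an additive fluorescence floor (plate-reader dark counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Condition, KineticParams, StateVector, Trajectory, simulate

__all__ = [
    "TruthSurfaceSettings",
    "TruthSurface",
    "NoiseModel",
    "DesignSettings",
    "SyntheticDataset",
    "make_truth_surface",
    "generate_design",
    "write_fixtures",
]


@dataclass(frozen=True)
class TruthSurfaceSettings:
    """Closed-form parameter surface settings (defaults calibrated so the
    per-copy-number optimum intensity is ~50 / ~20 / ~5 μmol m⁻² s⁻¹ for
    n = 1 / 3 / 8)."""

    mu0: float = 0.35          # dark maximum growth rate, 1/h
    alpha0: float = 3e4        # fully induced production rate, a.u./h
    leak: float = 0.05         # dark-state promoter leakage fraction of alpha0
    k_i0: float = 15.0         # half-activation intensity at n = 1, μmol m⁻² s⁻¹
    k_i_exponent: float = 1.0  # K_I(n) = k_i0 / n**k_i_exponent
    hill_q: float = 2.0        # induction Hill coefficient
    tox_x50: float = 75.0      # phototoxicity half-dose on I*n
    tox_p: float = 2.0         # phototoxicity steepness
    k_g: float = 0.5           # g/L
    beta: float = 0.05         # 1/h
    d_p: float = 0.02          # 1/h
    y_gb: float = 0.55         # (g/L)/OD

    def __post_init__(self):
        for name in ("mu0", "alpha0", "k_i0", "k_i_exponent", "hill_q",
                     "tox_x50", "tox_p", "k_g", "beta", "d_p", "y_gb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.leak < 1):
            raise ValueError("leak must be in [0, 1)")


@dataclass(frozen=True)
class TruthSurface:
    """Deterministic map (I, n) -> KineticParams used as ground truth."""

    settings: TruthSurfaceSettings

    def phototoxicity(self, intensity: float, copy_number: float) -> float:
        """Logistic damping 1/(1 + (I*n/x50)^p); 1 in the dark."""
        s = self.settings
        x = intensity * copy_number
        return 1.0 / (1.0 + (x / s.tox_x50) ** s.tox_p)

    def induction(self, intensity: float, copy_number: float) -> float:
        """Leaky Hill activation of the light-driven promoter, in [leak, 1]."""
        s = self.settings
        if copy_number == 0:
            return s.leak  # no photosensor: leakage only
        k = s.k_i0 / copy_number**s.k_i_exponent
        if intensity == 0:
            h = 0.0
        else:
            h = intensity**s.hill_q / (intensity**s.hill_q + k**s.hill_q)
        return s.leak + (1.0 - s.leak) * h

    def params_at(self, condition: Condition) -> KineticParams:
        s = self.settings
        I, n = condition.light_intensity, condition.copy_number
        tox = self.phototoxicity(I, n)
        return KineticParams(
            mu_max=s.mu0 * tox,
            k_g=s.k_g,
            alpha=s.alpha0 * self.induction(I, n) * tox,
            beta=s.beta,
            d_p=s.d_p,
            y_gb=s.y_gb,
        )


def make_truth_surface(
    settings: TruthSurfaceSettings | None = None,
    seed: int | None = None,
    *,
    check_grid: tuple[tuple[float, ...], tuple[int, ...]] | None = None,
) -> TruthSurface:
    """Build a truth surface, verifying positivity over the design grid.

    The surface is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic generator stages and ignored.
    """
    surface = TruthSurface(settings or TruthSurfaceSettings())
    intensities, copies = check_grid or ((0, 5, 10, 30, 50, 70), (1, 3, 8))
    for n in copies:
        for I in intensities:
            p = surface.params_at(Condition(I, n))  # KineticParams validates > 0
            del p
    return surface


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: multiplicative lognormal (median-unbiased) on OD
    and fluorescence, plus an additive Gaussian fluorescence floor."""

    od_sigma: float = 0.02
    fluor_sigma: float = 0.02
    fluor_floor: float = 50.0  # a.u., additive s.d.

    def __post_init__(self):
        if self.od_sigma < 0 or self.fluor_sigma < 0 or self.fluor_floor < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def apply(self, traj: Trajectory, rng: np.random.Generator) -> dict[str, np.ndarray]:
        m = traj.times.size
        od = traj.c_b * np.exp(self.od_sigma * rng.standard_normal(m))
        fl = traj.c_p * np.exp(self.fluor_sigma * rng.standard_normal(m))
        fl = fl + self.fluor_floor * rng.standard_normal(m)
        return {"times": traj.times.copy(), "od": od, "protein": fl}


@dataclass(frozen=True)
class DesignSettings:
    """The characterization design: copy numbers x intensities x replicates."""

    copy_numbers: tuple[int, ...] = (1, 3, 8)
    intensities: tuple[float, ...] = (0.0, 5.0, 10.0, 30.0, 50.0, 70.0)
    replicates: int = 3
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 15.0, 24.0)
    od0: float = 0.1
    glucose0: float = 10.0  # 1% glucose
    cp0: float = 0.0


@dataclass
class SyntheticDataset:
    """Noiseless truth trajectories plus noisy replicate observations.

    ``observations`` maps (light, copy_number) -> replicate -> channel
    arrays; ``truth_params`` tabulates the generating parameters per
    condition for recovery scoring.
    """

    design: DesignSettings
    noiseless: dict[tuple[float, int], Trajectory]
    observations: dict[tuple[float, int], dict[int, dict[str, np.ndarray]]]
    truth_params: pd.DataFrame
    seed: int

    @property
    def conditions(self) -> list[Condition]:
        return [Condition(I, n) for (I, n) in sorted(self.noiseless, key=lambda k: (k[1], k[0]))]


def generate_design(
    surface: TruthSurface,
    noise: NoiseModel | None = None,
    design: DesignSettings | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate the full design and attach per-replicate measurement noise.

    Every condition starts from OD ``od0``, zero protein and ``glucose0``
    g/L glucose.  All randomness derives from one master seed via a
    deterministic per-condition/replicate spawn, so the dataset is
    byte-identical for identical seeds and the noiseless means do not
    depend on the seed at all.
    """
    noise = noise or NoiseModel()
    design = design or DesignSettings()
    times = np.asarray(design.timepoints, float)

    noiseless: dict[tuple[float, int], Trajectory] = {}
    observations: dict[tuple[float, int], dict[int, dict[str, np.ndarray]]] = {}
    rows = []
    root = np.random.SeedSequence(seed)
    for ci, n in enumerate(design.copy_numbers):
        for cj, I in enumerate(design.intensities):
            cond = Condition(I, n)
            params = surface.params_at(cond)
            init = StateVector(c_b=design.od0, c_p=design.cp0, c_g=design.glucose0, n=n)
            traj = simulate(init, params, times, condition=cond)
            key = (float(I), int(n))
            noiseless[key] = traj
            reps = {}
            for r in range(design.replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(ci, cj, r))
                )
                reps[r] = noise.apply(traj, rng)
            observations[key] = reps
            rows.append({
                "copy_number": n, "light_umol_m2_s": I,
                "mu_max": params.mu_max, "k_g": params.k_g, "alpha": params.alpha,
                "beta": params.beta, "d_p": params.d_p, "y_gb": params.y_gb,
            })
    truth = pd.DataFrame(rows)
    return SyntheticDataset(design=design, noiseless=noiseless,
                            observations=observations, truth_params=truth, seed=seed)


TRAJ_COLUMNS = ("time_h", "od", "protein_au", "glucose_g_per_L",
                "copy_number", "light_umol_m2_s", "replicate")


def dataset_to_frame(dataset: SyntheticDataset) -> pd.DataFrame:
    """Flatten noisy observations to the trajectory table schema.

    Glucose is unobserved on the plate reader; the column carries the
    simulated truth at t0 and NaN elsewhere, matching how real batches
    record only the initial glucose concentration.
    """
    rows = []
    for (I, n), reps in dataset.observations.items():
        for r, obs in reps.items():
            for k, t in enumerate(obs["times"]):
                rows.append({
                    "time_h": t,
                    "od": obs["od"][k],
                    "protein_au": obs["protein"][k],
                    "glucose_g_per_L": dataset.design.glucose0 if k == 0 else np.nan,
                    "copy_number": n,
                    "light_umol_m2_s": I,
                    "replicate": r,
                })
    df = pd.DataFrame(rows, columns=TRAJ_COLUMNS)
    return df.sort_values(["copy_number", "light_umol_m2_s", "replicate", "time_h"],
                          ignore_index=True)


def write_fixtures(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as delimited text: observations, noiseless truth
    trajectories, and the truth-parameter table (for recovery scoring).

    Files round-trip bit-exactly through :func:`optoferm.io.read_trajectories`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    obs_path = directory / "observations.csv"
    truth_traj_path = directory / "truth_trajectories.csv"
    truth_params_path = directory / "truth_params.csv"

    dataset_to_frame(dataset).to_csv(obs_path, index=False)

    rows = []
    for (I, n), traj in dataset.noiseless.items():
        for k, t in enumerate(traj.times):
            rows.append({
                "time_h": t, "od": traj.c_b[k], "protein_au": traj.c_p[k],
                "glucose_g_per_L": traj.c_g[k], "copy_number": n,
                "light_umol_m2_s": I, "replicate": -1,
            })
    pd.DataFrame(rows, columns=TRAJ_COLUMNS).sort_values(
        ["copy_number", "light_umol_m2_s", "time_h"], ignore_index=True
    ).to_csv(truth_traj_path, index=False)

    dataset.truth_params.to_csv(truth_params_path, index=False)
    return {"observations": obs_path, "truth_trajectories": truth_traj_path,
            "truth_params": truth_params_path}
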