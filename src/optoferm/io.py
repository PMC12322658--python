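"""Delimited-text I/O and configuration for the pipeline stages.

All tables are plain CSV with a fixed schema; lines starting with ``#``
are provenance headers (config hash, seed, package version) written by
the CLI and skipped on read.  Configuration is YAML.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import DEFAULT_BOUNDS, FitProblem, FitResult, PSOSettings
from .model import Condition, KineticParams, PARAM_NAMES, Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "trajectories_to_problems",
    "write_fit_report",
    "read_fit_report",
    "load_config",
    "provenance_header",
]

TRAJ_COLUMNS = ("time_h", "od", "protein_au", "glucose_g_per_L",
                "copy_number", "light_umol_m2_s", "replicate")


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a trajectory table, validating the schema."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table {path} missing columns: {missing}")
    return df


def write_trajectories(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, index=False)


def trajectory_to_frame(traj: Trajectory, replicate: int = 0) -> pd.DataFrame:
    return pd.DataFrame({
        "time_h": traj.times,
        "od": traj.c_b,
        "protein_au": traj.c_p,
        "glucose_g_per_L": traj.c_g,
        "copy_number": traj.condition.copy_number,
        "light_umol_m2_s": traj.condition.light_intensity,
        "replicate": replicate,
    })


def trajectories_to_problems(
    df: pd.DataFrame,
    *,
    initial_glucose: float | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    weights: dict[str, float] | None = None,
) -> list[FitProblem]:
    """Group a trajectory table into one FitProblem per condition.

    The initial glucose concentration is read from the first time point's
    ``glucose_g_per_L`` (per condition) unless given explicitly.
    """
    problems = []
    for (I, n), grp in df.groupby(["light_umol_m2_s", "copy_number"]):
        obs = {}
        cg0 = initial_glucose
        for r, rep in grp.groupby("replicate"):
            rep = rep.sort_values("time_h")
            obs[int(r)] = {
                "times": rep["time_h"].to_numpy(float),
                "od": rep["od"].to_numpy(float),
                "protein": rep["protein_au"].to_numpy(float),
            }
            if cg0 is None:
                g0 = rep["glucose_g_per_L"].iloc[0]
                if np.isfinite(g0):
                    cg0 = float(g0)
        if cg0 is None:
            raise ValueError(f"no initial glucose for condition (I={I}, n={n})")
        kwargs = {}
        if bounds is not None:
            kwargs["bounds"] = bounds
        if weights is not None:
            kwargs["weights"] = weights
        problems.append(FitProblem(
            observations=obs,
            initial_glucose=cg0,
            condition=Condition(float(I), int(n)),
            **kwargs,
        ))
    problems.sort(key=lambda p: (p.condition.copy_number, p.condition.light_intensity))
    return problems


FIT_COLUMNS = ("copy_number", "light_umol_m2_s", *PARAM_NAMES, "objective", "seed")


def write_fit_report(results: list[FitResult], path: str | Path, header: str | None = None) -> None:
    rows = []
    for r in results:
        row = {"copy_number": r.condition.copy_number,
               "light_umol_m2_s": r.condition.light_intensity}
        row.update({name: getattr(r.params, name) for name in PARAM_NAMES})
        row["objective"] = r.objective_value
        row["seed"] = r.seed
        rows.append(row)
    df = pd.DataFrame(rows, columns=FIT_COLUMNS).sort_values(
        ["copy_number", "light_umol_m2_s"], ignore_index=True)
    write_trajectories(df, path, header)  # same comment-header convention


def read_fit_report(path: str | Path) -> list[FitResult]:
    df = pd.read_csv(path, comment="#")
    results = []
    for _, row in df.iterrows():
        results.append(FitResult(
            params=KineticParams(**{name: float(row[name]) for name in PARAM_NAMES}),
            objective_value=float(row["objective"]),
            n_evaluations=0,
            seed=int(row["seed"]),
            converged=True,
            condition=Condition(float(row["light_umol_m2_s"]), int(row["copy_number"])),
        ))
    return results


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration, filling stage defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = {
        "seed": 0,
        "bounds": dict(DEFAULT_BOUNDS),
        "weights": {"od": 1.0, "protein": 1.0},
        "pso": {},
        "gp": {"restarts": 8},
        "scan": {"intensity_min": 0.0, "intensity_max": 70.0, "intensity_step": 2.5,
                 "horizon_h": 24.0},
    }
    for key, val in raw.items():
        if isinstance(val, dict) and key in cfg and isinstance(cfg[key], dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if "bounds" in raw:
        cfg["bounds"] = {k: tuple(v) for k, v in raw["bounds"].items()}
    return cfg


def pso_settings_from_config(cfg: dict) -> PSOSettings:
    return PSOSettings(seed=cfg.get("seed", 0), **cfg.get("pso", {}))


def provenance_header(cfg: dict, version: str) -> str:
    """Deterministic comment header recording seed, config hash, version."""
    digest = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]
    return (f"# optoferm v{version}\n"
            f"# config_sha256 {digest}\n"
            f"# seed {cfg.get('seed', 0)}\n")
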