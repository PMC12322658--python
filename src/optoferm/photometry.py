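"""Plate-reader corrections and light-unit conversion.

Fluorescent-protein readouts from a plate reader mix signal from the
reporter with autofluorescence of the medium and the cells themselves.
Two standard corrections are provided:

* :func:`normalized_fluorescence_per_od` — per-OD expression, blanking
  both the medium and a non-fluorescent wild-type control grown under the
  same condition;
* :func:`total_fluorescence` — total signal with the wild-type control
  subtracted.

Blue-light doses are specified as photon flux density (μmol photons
m⁻² s⁻¹, what a quantum meter reads); :func:`photon_flux_to_irradiance`
converts to an energy flux (W/m²) via the photon energy E = hc/λ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.constants import Avogadro, Planck, speed_of_light

__all__ = [
    "PlateReading",
    "normalized_fluorescence_per_od",
    "total_fluorescence",
    "photon_flux_to_irradiance",
    "read_plate_table",
    "normalize_plate_table",
]

#: Roles a well can play in the correction formulas.
ROLES = ("strain", "media_blank", "no_fluor_control")

#: OD above which a single read leaves the typical plate reader's linear
#: range and should have been diluted (flagged, not corrected).
DEFAULT_LINEAR_OD_MAX = 8.0


@dataclass(frozen=True)
class PlateReading:
    """One well: raw fluorescence and OD plus its role and condition tag."""

    fluorescence: float
    od: float
    role: str = "strain"
    condition: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


def normalized_fluorescence_per_od(
    strain: PlateReading, media: PlateReading, control: PlateReading
) -> float:
    """Background-corrected fluorescence per OD.

    Subtracts the media blank from both the strain and a no-fluorophore
    control (wild type) measured under the same condition, divides each by
    its blank-corrected OD, and returns the difference::

        (F_s - F_m)/(OD_s - OD_m) - (F_c - F_m)/(OD_c - OD_m)

    The result is invariant to a common additive offset on all three
    fluorescence readings and may legitimately be negative for wells
    dimmer than the control; no clamping is applied here.
    """
    d_strain = strain.od - media.od
    d_ctrl = control.od - media.od
    if d_strain <= 0:
        raise ValueError(
            f"strain OD ({strain.od}) must exceed media blank OD ({media.od})"
        )
    if d_ctrl <= 0:
        raise ValueError(
            f"control OD ({control.od}) must exceed media blank OD ({media.od})"
        )
    return (strain.fluorescence - media.fluorescence) / d_strain - (
        control.fluorescence - media.fluorescence
    ) / d_ctrl


def total_fluorescence(strain_raw: float, control_raw: float) -> float:
    """Total reporter signal: raw strain reading minus the wild-type control."""
    return strain_raw - control_raw


def photon_flux_to_irradiance(flux: float, wavelength_nm: float) -> float:
    """Convert photon flux density (μmol m⁻² s⁻¹) to irradiance (W/m²).

    Each mole of photons at wavelength λ carries N_A·h·c/λ joules; the
    conversion is exactly linear in flux and inversely proportional to
    wavelength.  Physical constants are CODATA values; callers round for
    display (e.g. 70 μmol m⁻² s⁻¹ of ~462 nm blue light is ~18 W/m²).
    """
    if flux < 0:
        raise ValueError(f"photon flux must be >= 0, got {flux}")
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    energy_per_mol = Avogadro * Planck * speed_of_light / (wavelength_nm * 1e-9)
    return flux * 1e-6 * energy_per_mol


# ---------------------------------------------------------------------------
# Plate-table I/O
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ("well", "role", "fluorescence", "od", "condition")


def read_plate_table(
    path: str | Path, *, linear_od_max: float = DEFAULT_LINEAR_OD_MAX
) -> pd.DataFrame:
    """Read a raw plate export (CSV with columns well, role, fluorescence,
    od, condition) and flag wells above the instrument's linear OD range.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table {path} missing columns: {missing}")
    bad = ~df["role"].isin(ROLES)
    if bad.any():
        raise ValueError(f"unknown roles in plate table: {sorted(df.loc[bad, 'role'].unique())}")
    df["od_above_linear_range"] = df["od"] > linear_od_max
    return df


def normalize_plate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply both corrections to every strain well, per condition group.

    Each condition group must contain exactly one media blank and one
    no-fluorophore control; rows may carry a time-point label inside the
    condition tag (paired-by-time mode) or share a single blank across the
    plate (one group).  Returns one row per strain well with columns
    ``fluorescence_per_od`` and ``total_fluorescence``.
    """
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        blanks = grp[grp["role"] == "media_blank"]
        ctrls = grp[grp["role"] == "no_fluor_control"]
        if len(blanks) != 1 or len(ctrls) != 1:
            raise ValueError(
                f"condition {cond!r} needs exactly one media_blank and one "
                f"no_fluor_control (got {len(blanks)} and {len(ctrls)})"
            )
        media = PlateReading(float(blanks["fluorescence"].iloc[0]), float(blanks["od"].iloc[0]), "media_blank", cond)
        control = PlateReading(float(ctrls["fluorescence"].iloc[0]), float(ctrls["od"].iloc[0]), "no_fluor_control", cond)
        for _, row in grp[grp["role"] == "strain"].iterrows():
            strain = PlateReading(float(row["fluorescence"]), float(row["od"]), "strain", cond)
            out.append({
                "well": row["well"],
                "condition": cond,
                "fluorescence_per_od": normalized_fluorescence_per_od(strain, media, control),
                "total_fluorescence": total_fluorescence(strain.fluorescence, control.fluorescence),
            })
    return pd.DataFrame(out, columns=["well", "condition", "fluorescence_per_od", "total_fluorescence"])
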