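"""Closed-form viscoelasticity relations.

Converts fitted displacement amplitudes into the absolute shear modulus via
the calibrated volumetric force constant, |G| = F_vol * V / (3*pi*D*p_hat)
= F_vol * D^2 / (18 * p_hat), and |G| into Young's modulus E = 2(1+v)|G|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "shear_modulus",
    "youngs_modulus",
    "expected_modulus_ratio",
    "coefficient_of_variation",
    "tracks_to_observations",
]


def shear_modulus(amplitude_m: float, diameter_m: float, f_volumetric: float) -> float:
    """Absolute shear modulus |G| (Pa) from a fitted displacement amplitude.

    |G| = F_vol * D^2 / (18 * p_hat). A zero amplitude means the stiffness is
    unmeasurable (the SNR-failure mode of stiff matrices) and is an error.
    """
    if amplitude_m <= 0:
        raise ValueError("displacement amplitude must be positive; zero amplitude signals SNR failure")
    if diameter_m <= 0 or f_volumetric <= 0:
        raise ValueError("diameter and volumetric force constant must be positive")
    return f_volumetric * diameter_m**2 / (18.0 * amplitude_m)


def youngs_modulus(g_pa, poisson_ratio: float):
    """Young's modulus E = 2(1+v)|G| (Pa); maps SDs of |G| by the same factor."""
    if not 0.0 <= poisson_ratio <= 0.5:
        raise ValueError(f"Poisson ratio must be in [0, 0.5], got {poisson_ratio}")
    out = 2.0 * (1.0 + poisson_ratio) * np.asarray(g_pa, dtype=float)
    return float(out) if out.ndim == 0 else out


def expected_modulus_ratio(d1_m: float, d2_m: float, fv1: float, fv2: float) -> float:
    """Ratio of |G| reported by sphere size 2 vs size 1 at equal displacement.

    (fv2/fv1)*(d2/d1)^2 — the square-law force advantage of larger spheres.
    """
    if min(d1_m, d2_m, fv1, fv2) <= 0:
        raise ValueError("diameters and force constants must be positive")
    return (fv2 / fv1) * (d2_m / d1_m) ** 2


def coefficient_of_variation(mean: float, sd: float) -> float:
    """c_v = sd / mean, the conventional sample-to-sample variation metric."""
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    return sd / mean


def tracks_to_observations(
    fit_table: pd.DataFrame,
    f_volumetric_by_diameter: dict[float, float] | float,
    poisson_low: float = 0.37,
    poisson_high: float = 0.50,
) -> pd.DataFrame:
    """Compose fitted amplitudes into one (|G|, phi) observation per repeat.

    ``f_volumetric_by_diameter`` maps nominal sphere diameter in um to the
    calibrated force constant for that size (a scalar applies one constant to
    everything). The Young's-modulus range for both Poisson bounds is
    attached. Rows that cannot be converted (missing calibration, zero
    amplitude) are returned separately in the ``error`` column.
    """
    rows = []
    for _, r in fit_table.iterrows():
        out = {c: r[c] for c in ("matrix", "sample", "holder", "location", "sphere", "repeat")}
        out["diameter_um"] = r["diameter_um"]
        err = ""
        try:
            if np.isscalar(f_volumetric_by_diameter):
                fv = float(f_volumetric_by_diameter)
            else:
                key = _nearest_key(f_volumetric_by_diameter, r["diameter_um"])
                fv = f_volumetric_by_diameter[key]
            g = shear_modulus(r["amplitude_nm"] * 1e-9, r["diameter_um"] * 1e-6, fv)
            out["abs_shear_modulus_pa"] = g
            out["phase_deg"] = r["phase_deg"]
            out["youngs_modulus_low_kpa"] = youngs_modulus(g, poisson_low) / 1e3
            out["youngs_modulus_high_kpa"] = youngs_modulus(g, poisson_high) / 1e3
            if not 0.0 <= r["phase_deg"] <= 90.0:
                err = "phase outside [0, 90] deg"
        except (ValueError, KeyError) as exc:
            out["abs_shear_modulus_pa"] = np.nan
            out["phase_deg"] = r.get("phase_deg", np.nan)
            err = str(exc)
        out["error"] = err
        rows.append(out)
    return pd.DataFrame(rows)


def _nearest_key(mapping: dict[float, float], diameter_um: float) -> float:
    """Pick the calibration entry for the nominal size class of a sphere.

    Measured diameters scatter around the nominal 30/100 um classes; the
    entry closest on a log scale is used, but only within a factor 1.5 —
    beyond that the sphere has no valid calibration.
    """
    best = min(mapping, key=lambda k: abs(np.log(k) - np.log(diameter_um)))
    if not (1 / 1.5 <= diameter_um / best <= 1.5):
        raise KeyError(f"no calibration constant for diameter {diameter_um} um")
    return best
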