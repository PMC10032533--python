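"""Displacement-track processing: reference correction and sinusoid fitting.

The drive frequency is known exactly, so amplitude/phase estimation is linear
least squares in the sin/cos basis — convex, deterministic, and exact to
round-off on noiseless data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import DriveConfig, SinusoidFit, TrackSeries

__all__ = [
    "relative_displacement",
    "fit_sinusoid",
    "fit_tracks",
    "velocity_amplitude",
    "qc_filter",
    "QCResult",
]


def relative_displacement(
    magnetic_positions: np.ndarray,
    reference_positions: list[np.ndarray] | np.ndarray,
    times_s: np.ndarray,
    hierarchy,
    sphere,
    drive: DriveConfig,
) -> TrackSeries:
    """Subtract the mean reference-sphere position from a magnetic track.

    Removes mounting-related and environmental common-mode motion: the output
    displacement is (magnetic − mean of references), re-zeroed to the first
    sample. All tracks must share the time base.
    """
    mag = np.asarray(magnetic_positions, dtype=float)
    if isinstance(reference_positions, np.ndarray) and reference_positions.ndim == 1:
        refs = [reference_positions]
    else:
        refs = [np.asarray(r, dtype=float) for r in reference_positions]
    if len(refs) == 0:
        raise ValueError("at least one reference track is required to remove common-mode motion")
    for r in refs:
        if r.shape != mag.shape:
            raise ValueError("magnetic and reference tracks must share a common time base")
    rel = mag - np.mean(refs, axis=0)
    rel = rel - rel[0]
    return TrackSeries(times_s=np.asarray(times_s, float), displacement_m=rel,
                       hierarchy=hierarchy, sphere=sphere, drive=drive)


def fit_sinusoid(track: TrackSeries, include_drift: bool = True) -> SinusoidFit:
    """Fit p_hat * sin(2*pi*f*t - phi) [+ c0 + c1*t] at the known drive frequency.

    Solved via the linear basis a*sin(wt) + b*cos(wt) with p_hat = sqrt(a^2+b^2)
    and phi = atan2(-b, a), so that displacement lagging the force is a
    positive phase. A constant offset is always estimated; the linear drift
    term is on by default. Residual SD uses n - n_params degrees of freedom.
    """
    t = track.times_s
    y = track.displacement_m
    w = track.drive.omega
    if track.duration_s < track.drive.period_s - 1e-12:
        raise ValueError("need at least one full drive period of data to fit")
    cols = [np.sin(w * t), np.cos(w * t), np.ones_like(t)]
    if include_drift:
        cols.append(t)
    X = np.column_stack(cols)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"too few points ({n}) for {k}-parameter sinusoid fit")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c0 = coef[0], coef[1], coef[2]
    c1 = coef[3] if include_drift else 0.0
    resid = y - X @ coef
    dof = max(n - k, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    amp = float(np.hypot(a, b))
    if amp == 0.0 or sst == 0.0:
        return SinusoidFit(amplitude_m=0.0, phase_deg=float("nan"), residual_sd_m=resid_sd,
                           fit_r2=r2, snr=0.0, phase_defined=False,
                           drift_slope_m_per_s=float(c1), offset_m=float(c0),
                           hierarchy=track.hierarchy, sphere=track.sphere)
    phase = math.degrees(math.atan2(-b, a))
    phase = wrap_phase_deg(phase)
    snr = amp / resid_sd if resid_sd > 0 else float("inf")
    return SinusoidFit(amplitude_m=amp, phase_deg=phase, residual_sd_m=resid_sd,
                       fit_r2=r2, snr=snr, phase_defined=True,
                       drift_slope_m_per_s=float(c1), offset_m=float(c0),
                       hierarchy=track.hierarchy, sphere=track.sphere)


def wrap_phase_deg(phase: float) -> float:
    """Wrap a phase angle to the canonical interval [-180, 180)."""
    return float((phase + 180.0) % 360.0 - 180.0)


def velocity_amplitude(fit: SinusoidFit, drive: DriveConfig) -> float:
    """Velocity amplitude v_hat = 2*pi*f * p_hat of the fitted sinusoid (m/s)."""
    return drive.omega * fit.amplitude_m


def fit_tracks(tracks: list[TrackSeries], include_drift: bool = True) -> pd.DataFrame:
    """Fit every track and return the tidy per-repeat fit table."""
    rows = []
    for tr in tracks:
        fit = fit_sinusoid(tr, include_drift=include_drift)
        h = tr.hierarchy
        rows.append({
            "matrix": h.matrix_id, "sample": h.sample_id, "holder": h.holder_id,
            "location": h.location_id, "sphere": h.sphere_id, "repeat": h.repeat_id,
            "diameter_um": tr.sphere.diameter_m * 1e6,
            "amplitude_nm": fit.amplitude_m * 1e9,
            "phase_deg": fit.phase_deg,
            "residual_sd_nm": fit.residual_sd_m * 1e9,
            "snr": fit.snr, "r2": fit.fit_r2,
        })
    return pd.DataFrame(rows)


@dataclass
class QCResult:
    accepted: pd.DataFrame
    rejected: pd.DataFrame  # carries a 'qc_reason' column


def qc_filter(fits: pd.DataFrame, min_snr: float = 3.0, min_r2: float = 0.5) -> QCResult:
    """Partition a fit table into accepted/rejected rows with reasons.

    Low displacement signal-to-noise is the failure mode that makes stiff
    matrices unanalyzable, so every rejection is recorded, never dropped.
    """
    if min_snr < 0 or min_r2 < 0:
        raise ValueError("QC thresholds must be non-negative")
    reasons = []
    for _, row in fits.iterrows():
        why = []
        if not row["snr"] >= min_snr:  # NaN fails too
            why.append(f"snr<{min_snr}")
        if not row["r2"] >= min_r2:
            why.append(f"r2<{min_r2}")
        reasons.append(";".join(why))
    reasons = pd.Series(reasons, index=fits.index, name="qc_reason")
    bad = reasons != ""
    rejected = fits[bad].copy()
    rejected["qc_reason"] = reasons[bad]
    return QCResult(accepted=fits[~bad].copy(), rejected=rejected)
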