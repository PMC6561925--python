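"""Traveling-wave quantification.

A multi-electrode stimulation condition whose contacts carry different field
phases displaces the spatial maximum of the field magnitude over the cycle.
This module measures that displacement three ways: a dissimilarity index
between normalized per-contact field time-courses, a spatial-variability
index of the per-time-step rescaled magnitude map, and a linear regression
of field phase on contact position yielding the spatial frequency r
(deg/mm) and propagation speed c = f/r (mm/ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "DissimilarityResult",
    "WaveFit",
    "normalize_timecourses",
    "dissimilarity_index",
    "spatial_variability_index",
    "fit_phase_gradient",
    "wave_speed",
    "detect_wave",
    "fit_wave",
    "unwrap_track_phases",
]

#: spatial-frequency threshold (deg/mm) above which a wave is detected
DETECTION_THRESHOLD_DEG_PER_MM = 1.0


def normalize_timecourses(e_matrix: np.ndarray, signed: bool = False):
    """Normalize each contact's field time-course to its own maximum.

    Default uses absolute values (``|E(t)| / max|E|``), mapping each contact
    into [0, 1]; ``signed=True`` keeps the sign (range [-1, 1]).  Returns
    ``(normalized, valid)`` where ``valid`` flags contacts with a nonzero
    maximum; all-zero contacts are NaN-filled and excluded.
    """
    e = np.asarray(e_matrix, dtype=float)
    mag = e if signed else np.abs(e)
    peak = np.max(np.abs(e), axis=-1, keepdims=True)
    valid = peak[:, 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(peak > 0, mag / peak, np.nan)
    return norm, valid


@dataclass(frozen=True)
class DissimilarityResult:
    index: float
    per_track: dict
    n_pairs: int

    def __post_init__(self):
        if self.index < 0:
            raise ValueError("dissimilarity index must be nonnegative")


def dissimilarity_index(normalized: np.ndarray, track_labels=None) -> DissimilarityResult:
    """Mean squared difference between normalized contact time-courses.

    For every unordered contact pair within a track, the squared difference
    of their normalized traces is averaged over time; pair values are
    averaged within each track and the track means averaged across tracks.
    Zero exactly when all contacts share one normalized trace, i.e. when
    the spatial pattern is stationary in time.
    """
    norm = np.asarray(normalized, dtype=float)
    n = norm.shape[0]
    if track_labels is None:
        track_labels = [0] * n
    labels = np.asarray(track_labels)
    per_track = {}
    total_pairs = 0
    for tid in dict.fromkeys(labels.tolist()):
        idx = [i for i in np.flatnonzero(labels == tid) if not np.isnan(norm[i]).all()]
        if len(idx) < 2:
            raise ValueError(f"track {tid!r}: need >=2 valid contacts")
        vals = [np.mean((norm[i] - norm[j]) ** 2) for i, j in combinations(idx, 2)]
        per_track[tid] = float(np.mean(vals))
        total_pairs += len(vals)
    return DissimilarityResult(
        index=float(np.mean(list(per_track.values()))),
        per_track=per_track,
        n_pairs=total_pairs,
    )


def spatial_variability_index(magnitude: np.ndarray, rtol: float = 1e-12):
    """Per-location SD over time of the per-time-step min-max rescaled map.

    At every time step the magnitude across locations is rescaled to
    [0, 1]; the standard deviation of the rescaled value across time is then
    computed at each location.  Degenerate steps -- all locations equal
    within ``rtol`` of the matrix's global maximum, e.g. the carrier's zero
    crossing where the whole map collapses to rounding residue -- carry no
    spatial information and are skipped.

    Returns ``(sd_map, max_sd, n_skipped)``.
    """
    mag = np.asarray(magnitude, dtype=float)
    if mag.ndim != 2 or mag.shape[1] < 2:
        raise ValueError("need a (locations, time) matrix with >=2 time steps")
    lo = mag.min(axis=0, keepdims=True)
    hi = mag.max(axis=0, keepdims=True)
    span = hi - lo
    keep = span[0] > rtol * max(mag.max(), 0.0)
    n_skipped = int(np.sum(~keep))
    if keep.sum() < 2:
        return np.zeros(mag.shape[0]), 0.0, n_skipped
    rescaled = (mag[:, keep] - lo[:, keep]) / span[:, keep]
    sd_map = rescaled.std(axis=1)
    return sd_map, float(sd_map.max()), n_skipped


def unwrap_track_phases(phi_deg: np.ndarray) -> np.ndarray:
    """Sequential unwrap of field phases along a track, period 180 degrees.

    A field phase is physically defined modulo 360, but a sign flip of the
    along-track component contributes a spurious 180-degree jump; each phase
    is therefore replaced by the representative ``phi + k*180`` nearest the
    previous contact's unwrapped value.  NaN (undefined) entries are kept
    and skipped as anchors.
    """
    phi = np.asarray(phi_deg, dtype=float).copy()
    prev = np.nan
    for i in range(phi.size):
        if np.isnan(phi[i]):
            continue
        if not np.isnan(prev):
            phi[i] += 180.0 * np.round((prev - phi[i]) / 180.0)
        prev = phi[i]
    return phi


def fit_phase_gradient(phi_deg, coordinates_mm):
    """OLS regression of unwrapped field phase on along-track position.

    Fits ``phi(x) = r*x + b``; returns ``(r, b, R^2)`` with r in deg/mm.
    Needs at least three contacts with defined phase.
    """
    phi = np.asarray(phi_deg, dtype=float)
    x = np.asarray(coordinates_mm, dtype=float)
    if phi.shape != x.shape:
        raise ValueError("phases and coordinates must have equal length")
    phi = unwrap_track_phases(phi)
    mask = ~np.isnan(phi)
    if mask.sum() < 3:
        raise ValueError("need >=3 contacts with defined phase")
    phi, x = phi[mask], x[mask]
    r, b = np.polyfit(x, phi, 1)
    resid = phi - (r * x + b)
    sst = np.sum((phi - phi.mean()) ** 2)
    r2 = 1.0 if sst == 0 else 1.0 - np.sum(resid**2) / sst
    return float(r), float(b), float(r2)


def wave_speed(r_deg_per_mm: float, f_stim_hz: float) -> float:
    """Propagation speed c = f/r in mm/ms (unsigned).

    The temporal frequency in deg/ms is ``360 * f_stim / 1000``; a zero
    spatial frequency means no propagating maximum and raises.
    """
    if r_deg_per_mm == 0:
        raise ValueError("r = 0: stationary pattern, no propagation speed")
    f_deg_per_ms = 360.0 * f_stim_hz / 1000.0
    return abs(f_deg_per_ms / r_deg_per_mm)


def detect_wave(r_deg_per_mm: float, threshold: float = DETECTION_THRESHOLD_DEG_PER_MM) -> bool:
    """A spatial phase gradient of at least 1 deg/mm counts as a wave."""
    return bool(abs(r_deg_per_mm) >= threshold)


@dataclass(frozen=True)
class WaveFit:
    """Phase-gradient regression summary for one condition and track."""

    r_deg_per_mm: float
    b_deg: float
    f_deg_per_ms: float
    c_mm_per_ms: float  # NaN when r == 0
    r_squared: float
    detected: bool
    direction: int  # sign of r; 0 for a stationary pattern


def fit_wave(
    phi_deg,
    coordinates_mm,
    f_stim_hz: float,
    threshold: float = DETECTION_THRESHOLD_DEG_PER_MM,
) -> WaveFit:
    """Convenience wrapper: regression, speed and detection in one call."""
    r, b, r2 = fit_phase_gradient(phi_deg, coordinates_mm)
    f_deg_per_ms = 360.0 * f_stim_hz / 1000.0
    c = wave_speed(r, f_stim_hz) if r != 0 else float("nan")
    return WaveFit(
        r_deg_per_mm=r,
        b_deg=b,
        f_deg_per_ms=f_deg_per_ms,
        c_mm_per_ms=c,
        r_squared=r2,
        detected=detect_wave(r, threshold),
        direction=int(np.sign(r)),
    )
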