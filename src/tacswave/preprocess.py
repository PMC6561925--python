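"""Preprocessing chain: zero-phase bandpass, decimation, epoching,
demeaning, bad-contact interpolation and amplitude rescaling.

The chain order is filter -> downsample -> epoch -> demean -> interpolate ->
rescale; for sinusoidal stimulation artifacts every step is linear, so the
order of demeaning and rescaling is immaterial and is fixed here for
determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .recordings import RecordingSet

__all__ = [
    "PreprocessConfig",
    "bandpass_zero_phase",
    "downsample",
    "extract_epochs",
    "demean",
    "interpolate_contacts",
    "rescale_to_reference",
    "preprocess_session",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Defaults follow common stimulation-artifact practice: 5-20 Hz
    fourth-order zero-phase Butterworth, decimation to 1 kHz, and rescaling
    to a 1 mA peak-to-zero reference current (x10 for a 0.1 mA session)."""

    low_hz: float = 5.0
    high_hz: float = 20.0
    order: int = 4
    target_rate_hz: float = 1000.0
    exclude_contacts: tuple = ()      # dropped from analysis entirely
    interpolate_contacts: tuple = ()  # replaced by neighbor means
    reference_amplitude_ma: float = 1.0

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz < self.target_rate_hz / 2):
            raise ValueError("need 0 < low < high < target_rate/2")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        object.__setattr__(self, "exclude_contacts", tuple(self.exclude_contacts))
        object.__setattr__(self, "interpolate_contacts", tuple(self.interpolate_contacts))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_contacts"] = list(self.exclude_contacts)
        d["interpolate_contacts"] = list(self.interpolate_contacts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        for k in ("exclude_contacts", "interpolate_contacts"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _effective_impulse_len(rate_hz: float, low_hz: float) -> int:
    # a bandpass settles over a few periods of its lowest passband frequency
    return int(np.ceil(rate_hz / low_hz))


def bandpass_zero_phase(x: np.ndarray, rate_hz: float, config: PreprocessConfig) -> np.ndarray:
    """Forward-reverse Butterworth bandpass (zero phase distortion).

    Input may be a 1-D trace or an (n_channels, n_samples) matrix; the last
    axis is time.  Edges are handled by reflective padding of three times
    the filter's effective impulse length, so the input must be longer than
    that padding.
    """
    x = np.asarray(x, dtype=float)
    padlen = 3 * _effective_impulse_len(rate_hz, config.low_hz)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"input of {x.shape[-1]} samples is shorter than the filter warm-up "
            f"({padlen} samples at {rate_hz} Hz)"
        )
    sos = sps.butter(
        config.order, [config.low_hz, config.high_hz], btype="band", fs=rate_hz, output="sos"
    )
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def downsample(x: np.ndarray, rate_hz: float, target_rate_hz: float) -> np.ndarray:
    """Anti-aliased rate conversion along the last axis (polyphase FIR)."""
    if target_rate_hz > rate_hz:
        raise ValueError("target rate must not exceed the input rate")
    if target_rate_hz == rate_hz:
        return np.asarray(x, dtype=float)
    frac = Fraction(target_rate_hz / rate_hz).limit_denominator(10000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator, axis=-1)


def extract_epochs(data: dict, rate_hz: float, ramp_s: float, epoch_s: float) -> dict:
    """Cut the steady (ramp-free) segment out of each condition matrix.

    ``data`` maps condition theta to (n_contacts, n_samples); the steady
    segment spans ``[ramp_s, ramp_s + epoch_s)``.
    """
    if ramp_s < 0 or epoch_s <= 0:
        raise ValueError("epoch boundaries invalid (need ramp_s >= 0, epoch_s > 0)")
    start = int(round(ramp_s * rate_hz))
    stop = start + int(round(epoch_s * rate_hz))
    out = {}
    for theta, mat in data.items():
        if mat.shape[-1] < stop:
            raise ValueError(
                f"condition {theta}: {mat.shape[-1]} samples, epoch needs {stop}"
            )
        out[theta] = mat[..., start:stop]
    return out


def demean(x: np.ndarray) -> np.ndarray:
    """Remove the per-channel mean (last axis)."""
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=-1, keepdims=True)


def interpolate_contacts(matrix: np.ndarray, bad_indices, track_labels=None) -> np.ndarray:
    """Replace bad contacts by the mean of their adjacent good neighbors.

    Neighbors are adjacent rows within the same track (all rows one track if
    ``track_labels`` is None).  End contacts copy their single neighbor.
    Runs of adjacent bad contacts are filled outside-in: each pass fills
    every bad contact that currently has at least one good neighbor, until
    none remain.  A track whose contacts are all bad raises.
    """
    mat = np.array(matrix, dtype=float)
    n = mat.shape[0]
    if track_labels is None:
        track_labels = [0] * n
    bad = np.zeros(n, dtype=bool)
    bad[list(bad_indices)] = True
    labels = np.asarray(track_labels)
    for tid in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == tid)
        if bad[idx].all():
            raise ValueError(f"track {tid!r}: all contacts bad, nothing to interpolate from")
        remaining = set(np.flatnonzero(bad[idx]))
        while remaining:
            filled = []
            for j in sorted(remaining):
                i = idx[j]
                neighbors = []
                if j > 0 and idx[j - 1] not in [idx[k] for k in remaining]:
                    neighbors.append(idx[j - 1])
                if j < idx.size - 1 and idx[j + 1] not in [idx[k] for k in remaining]:
                    neighbors.append(idx[j + 1])
                if neighbors:
                    mat[i] = np.mean([mat[k] for k in neighbors], axis=0)
                    filled.append(j)
            if not filled:  # cannot happen given the all-bad check, but be safe
                raise ValueError(f"track {tid!r}: isolated bad contacts")
            remaining.difference_update(filled)
    return mat


def rescale_to_reference(matrix: np.ndarray, session_amplitude_ma: float, reference_amplitude_ma: float = 1.0) -> np.ndarray:
    """Scale voltages to the reporting-convention reference current.

    A 0.1 mA session is multiplied by 10 to express fields per 1 mA
    peak-to-zero; valid because conduction is Ohmic (linear in current).
    """
    if session_amplitude_ma <= 0:
        raise ValueError("session amplitude must be positive")
    return np.asarray(matrix, dtype=float) * (reference_amplitude_ma / session_amplitude_ma)


def preprocess_session(rs: RecordingSet, config: PreprocessConfig | None = None) -> RecordingSet:
    """Full chain on a raw session; returns epoched data at the target rate.

    Contacts listed in ``exclude_contacts`` are interpolated like bad
    contacts (the geometry is kept intact so downstream spacing stays
    uniform); ``interpolate_contacts`` are replaced by neighbor means.
    """
    config = config or PreprocessConfig()
    proto = rs.protocol
    labels = rs.geometry.track_labels()
    bad = tuple(config.exclude_contacts) + tuple(config.interpolate_contacts)
    out = {}
    for theta, mat in rs.data.items():
        x = bandpass_zero_phase(mat, rs.rate_hz, config)
        x = downsample(x, rs.rate_hz, config.target_rate_hz)
        x = extract_epochs({theta: x}, config.target_rate_hz, proto.ramp_s, proto.epoch_s)[theta]
        x = demean(x)
        if bad:
            x = interpolate_contacts(x, bad, track_labels=labels)
        x = rescale_to_reference(x, proto.amplitude_ma, config.reference_amplitude_ma)
        out[theta] = x
    n_keep = next(iter(out.values())).shape[-1]
    provenance = dict(rs.provenance)
    provenance["preprocess"] = config.to_dict()
    return RecordingSet(
        data=out,
        time_ms=np.arange(n_keep) / config.target_rate_hz * 1000.0,
        rate_hz=config.target_rate_hz,
        geometry=rs.geometry,
        protocol=proto,
        provenance=provenance,
    )
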