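"""Synthetic depth-electrode recording generator and dataset I/O.

Renders forward-modeled phasor fields into noisy, protocol-faithful voltage
time series -- the stand-in for intracranial stereo-EEG recorded during a
multi-electrode stimulation sweep -- and reads/writes the on-disk dataset
format (one CSV of samples per condition plus a JSON sidecar).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .conductor import (
    ElectrodeMontage,
    Medium,
    RecordingGeometry,
    coupling_profile,
    simulate_phasor_field,
)

__all__ = ["Protocol", "NoiseModel", "RecordingSet", "generate_session", "write_dataset", "read_dataset"]

SCHEMA_VERSION = "1"


def default_sweep() -> tuple:
    """0 to 360 degrees in 15-degree steps: 25 phase conditions."""
    return tuple(float(t) for t in range(0, 361, 15))


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol: 10 Hz, 0.1 mA peak-to-zero, 25 phase
    conditions (0:15:360), 30 s epochs flanked by 5 s ramps, digitized at
    5 kHz and analyzed at 1 kHz."""

    frequency_hz: float = 10.0
    amplitude_ma: float = 0.1
    sweep_deg: tuple = field(default_factory=default_sweep)
    epoch_s: float = 30.0
    ramp_s: float = 5.0
    native_rate_hz: float = 5000.0
    analysis_rate_hz: float = 1000.0

    def __post_init__(self):
        sweep = tuple(float(t) for t in self.sweep_deg)
        if len(set(sweep)) != len(sweep) or list(sweep) != sorted(sweep):
            raise ValueError("condition sweep must be unique and sorted")
        if self.native_rate_hz <= 0 or self.analysis_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.native_rate_hz < self.analysis_rate_hz:
            raise ValueError("native rate must be >= analysis rate")
        if self.frequency_hz <= 0 or self.amplitude_ma < 0:
            raise ValueError("invalid stimulation parameters")
        if self.epoch_s <= 0 or self.ramp_s < 0:
            raise ValueError("invalid epoch/ramp durations")
        object.__setattr__(self, "sweep_deg", sweep)

    @property
    def n_conditions(self) -> int:
        return len(self.sweep_deg)

    @property
    def cycle_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sweep_deg"] = list(self.sweep_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        d = dict(d)
        if "sweep_deg" in d:
            d["sweep_deg"] = tuple(d["sweep_deg"])
        return cls(**d)


@dataclass(frozen=True)
class NoiseModel:
    """Additive recording noise: broadband white noise, mains interference
    at a fixed frequency, and slow baseline drift (low-pass-filtered noise).

    Amplitudes are in mV; defaults approximate a clean intracranial
    recording (tens of microvolts of broadband noise) against mV-scale
    stimulation artifacts.  All randomness is driven by ``seed``.
    """

    white_sd_mv: float = 0.02
    line_amp_mv: float = 0.05
    line_freq_hz: float = 60.0
    drift_sd_mv: float = 0.1
    drift_corner_hz: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.white_sd_mv, self.line_amp_mv, self.drift_sd_mv) < 0:
            raise ValueError("noise amplitudes must be nonnegative")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        return cls(white_sd_mv=0.0, line_amp_mv=0.0, drift_sd_mv=0.0, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        return cls(**d)


@dataclass
class RecordingSet:
    """Per-condition contact x time voltage matrices plus session metadata.

    ``data`` maps condition theta (degrees) to an (n_contacts, n_samples)
    array in mV.  All conditions share the geometry, sampling rate and time
    axis.
    """

    data: dict
    time_ms: np.ndarray
    rate_hz: float
    geometry: RecordingGeometry
    protocol: Protocol
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.geometry.n_contacts
        for theta, mat in self.data.items():
            if mat.shape != (n, self.time_ms.size):
                raise ValueError(
                    f"condition {theta}: matrix shape {mat.shape} does not match "
                    f"({n} contacts, {self.time_ms.size} samples)"
                )

    @property
    def conditions(self):
        return list(self.data.keys())


def _ramp_envelope(t_s: np.ndarray, ramp_s: float, epoch_s: float) -> np.ndarray:
    """Linear ramp up, steady plateau, linear ramp down."""
    total = 2 * ramp_s + epoch_s
    env = np.ones_like(t_s)
    if ramp_s > 0:
        env = np.minimum(env, t_s / ramp_s)
        env = np.minimum(env, (total - t_s) / ramp_s)
    return np.clip(env, 0.0, 1.0)


def _render_noise(noise: NoiseModel, rng: np.random.Generator, n_contacts: int, t_s: np.ndarray, rate_hz: float) -> np.ndarray:
    out = np.zeros((n_contacts, t_s.size))
    if noise.white_sd_mv > 0:
        out += rng.normal(0.0, noise.white_sd_mv, out.shape)
    if noise.line_amp_mv > 0:
        phases = rng.uniform(0, 2 * np.pi, n_contacts)
        out += noise.line_amp_mv * np.sin(
            2 * np.pi * noise.line_freq_hz * t_s[None, :] + phases[:, None]
        )
    if noise.drift_sd_mv > 0 and noise.drift_corner_hz < rate_hz / 2:
        raw = rng.normal(0.0, 1.0, out.shape)
        sos = sps.butter(2, noise.drift_corner_hz, btype="low", fs=rate_hz, output="sos")
        drift = sps.sosfiltfilt(sos, raw, axis=1)
        sd = drift.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out += noise.drift_sd_mv * drift / sd
    return out


def generate_session(
    montage: ElectrodeMontage,
    geometry: RecordingGeometry,
    medium: Medium,
    protocol: Protocol,
    noise: NoiseModel,
) -> RecordingSet:
    """Simulate one full recording session at the native sampling rate.

    Each sweep condition yields one epoch: a steady segment whose noiseless
    per-contact trace is exactly the forward-modeled phasor rendered in the
    time domain, flanked by linear amplitude ramps.  Identical seeds give
    bit-identical output.
    """
    rate = protocol.native_rate_hz
    n_samples = int(round((protocol.epoch_s + 2 * protocol.ramp_s) * rate))
    t_s = np.arange(n_samples) / rate
    env = _ramp_envelope(t_s, protocol.ramp_s, protocol.epoch_s)
    # phase reference t=0 at epoch (plateau) onset so steady traces match the phasor
    t_stim_ms = (t_s - protocol.ramp_s) * 1000.0
    rng = np.random.default_rng(noise.seed)
    couplings = coupling_profile(montage, geometry, medium)

    data = {}
    for theta in protocol.sweep_deg:
        pf = simulate_phasor_field(
            montage, geometry, medium, theta, protocol.frequency_hz, couplings=couplings
        )
        clean = env[None, :] * pf.v_timecourse(t_stim_ms)
        data[theta] = clean + _render_noise(noise, rng, geometry.n_contacts, t_s, rate)

    return RecordingSet(
        data=data,
        time_ms=t_s * 1000.0,
        rate_hz=rate,
        geometry=geometry,
        protocol=protocol,
        provenance={
            "seed": noise.seed,
            "montage": montage.to_dict(),
            "noise": noise.to_dict(),
            "medium_sigma_s_per_m": medium.sigma_s_per_m,
        },
    )


def _condition_filename(index: int, theta: float) -> str:
    return f"cond_{index:02d}_theta_{theta:g}.csv"


def write_dataset(rs: RecordingSet, path) -> None:
    """Write a session: one samples-by-contacts CSV per condition plus a
    JSON sidecar (``session.json``) and the geometry CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    labels = rs.geometry.track_labels()
    columns = [f"{tid}_c{i}" for i, tid in enumerate(labels)]
    files = []
    for idx, theta in enumerate(rs.conditions):
        fname = _condition_filename(idx, theta)
        pd.DataFrame(rs.data[theta].T, columns=columns).to_csv(path / fname, index=False)
        files.append({"theta_deg": theta, "file": fname})
    rs.geometry.to_csv(path / "geometry.csv")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "rate_hz": rs.rate_hz,
        "n_samples": int(rs.time_ms.size),
        "n_contacts": rs.geometry.n_contacts,
        "protocol": rs.protocol.to_dict(),
        "conditions": files,
        "provenance": rs.provenance,
    }
    with open(path / "session.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_dataset(path) -> RecordingSet:
    """Read a session written by :func:`write_dataset`.

    Raises on a missing sidecar, an unknown schema version, or a dimension
    mismatch between a condition CSV and the sidecar.
    """
    path = Path(path)
    sidecar_path = path / "session.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no session.json found in {path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    version = sidecar.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported dataset schema version {version!r}; supported: {SCHEMA_VERSION!r}"
        )
    geometry = RecordingGeometry.from_csv(path / "geometry.csv")
    n_samples = sidecar["n_samples"]
    n_contacts = sidecar["n_contacts"]
    if geometry.n_contacts != n_contacts:
        raise ValueError("geometry.csv contact count does not match sidecar")
    data = {}
    for entry in sidecar["conditions"]:
        df = pd.read_csv(path / entry["file"])
        mat = df.to_numpy().T
        if mat.shape != (n_contacts, n_samples):
            raise ValueError(
                f"condition file {entry['file']}: shape {mat.shape} does not match "
                f"sidecar ({n_contacts}, {n_samples})"
            )
        data[float(entry["theta_deg"])] = mat
    rate = float(sidecar["rate_hz"])
    return RecordingSet(
        data=data,
        time_ms=np.arange(n_samples) / rate * 1000.0,
        rate_hz=rate,
        geometry=geometry,
        protocol=Protocol.from_dict(sidecar["protocol"]),
        provenance=sidecar.get("provenance", {}),
    )
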