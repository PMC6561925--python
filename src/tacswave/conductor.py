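"""Analytic volume-conductor forward model.

Maps a scalp stimulation montage plus depth-electrode recording geometry to
per-contact coupling coefficients and phasor fields.  The conductor is a
homogeneous semi-infinite half-space with point current sources on its
boundary, for which the potential of a unit source is ``V = I / (2 pi sigma r)``.
This keeps the two properties every downstream conclusion relies on --
linearity in the injected currents and quasi-static (instantaneous)
conduction -- while staying closed-form.

Units: positions in mm, currents in mA (peak-to-zero), conductivity in S/m,
voltages in mV, fields in mV/mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .phasor import Phasor, wrap_phase_deg

__all__ = [
    "Medium",
    "StimElectrode",
    "ElectrodeMontage",
    "Track",
    "RecordingGeometry",
    "CouplingProfile",
    "PhasorField",
    "lead_potential",
    "coupling_profile",
    "return_current",
    "simulate_phasor_field",
    "dose_metrics",
]


@dataclass(frozen=True)
class Medium:
    """Homogeneous conducting half-space.

    Default conductivity is gray matter, 0.275 S/m.
    """

    sigma_s_per_m: float = 0.275
    kind: str = "half-space"

    def __post_init__(self):
        if self.sigma_s_per_m <= 0:
            raise ValueError("conductivity must be positive")
        if self.kind != "half-space":
            raise ValueError(f"unsupported medium kind: {self.kind!r}")


@dataclass(frozen=True)
class StimElectrode:
    label: str
    position_mm: tuple
    role: str  # "active" | "return"
    amplitude_ma: float = 0.0

    def __post_init__(self):
        if self.role not in ("active", "return"):
            raise ValueError(f"electrode role must be 'active' or 'return', got {self.role!r}")
        if self.amplitude_ma < 0:
            raise ValueError("current amplitude must be nonnegative")
        object.__setattr__(self, "position_mm", tuple(float(v) for v in self.position_mm))


@dataclass(frozen=True)
class ElectrodeMontage:
    """Scalp stimulation montage: two active electrodes plus one return.

    ``area_cm2`` is the contact area of each stimulation pad (default
    3.14 cm^2, a 1 cm-radius round pad).  The return electrode carries no
    prescribed current: it picks up whatever phasor current the active
    electrodes do not cancel, computed per condition by
    :func:`return_current`.
    """

    electrodes: tuple
    area_cm2: float = 3.14

    def __post_init__(self):
        elecs = tuple(self.electrodes)
        if self.area_cm2 <= 0:
            raise ValueError("electrode area must be positive")
        returns = [e for e in elecs if e.role == "return"]
        actives = [e for e in elecs if e.role == "active"]
        if len(returns) != 1:
            raise ValueError("montage must contain exactly one return electrode")
        if len(actives) != 2:
            raise ValueError("montage must contain exactly two active electrodes")
        object.__setattr__(self, "electrodes", elecs)

    @property
    def active(self):
        return [e for e in self.electrodes if e.role == "active"]

    @property
    def return_electrode(self):
        return next(e for e in self.electrodes if e.role == "return")

    def to_dict(self) -> dict:
        return {
            "area_cm2": self.area_cm2,
            "electrodes": [
                {
                    "label": e.label,
                    "position_mm": list(e.position_mm),
                    "role": e.role,
                    "amplitude_ma": e.amplitude_ma,
                }
                for e in self.electrodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeMontage":
        return cls(
            electrodes=tuple(
                StimElectrode(
                    label=e["label"],
                    position_mm=tuple(e["position_mm"]),
                    role=e["role"],
                    amplitude_ma=e.get("amplitude_ma", 0.0),
                )
                for e in d["electrodes"]
            ),
            area_cm2=d.get("area_cm2", 3.14),
        )

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ElectrodeMontage":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Track:
    """One depth electrode: an ordered run of contacts at uniform spacing."""

    track_id: str
    positions_mm: np.ndarray  # (n_contacts, 3)

    def __post_init__(self):
        pos = np.asarray(self.positions_mm, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
            raise ValueError("a track needs >=2 contacts with 3-D positions")
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError(f"track {self.track_id!r} has repeated contact positions")
        if np.max(np.abs(steps - steps[0])) > 1e-6 * steps[0]:
            raise ValueError(f"track {self.track_id!r} has non-uniform contact spacing")
        object.__setattr__(self, "positions_mm", pos)

    @property
    def n_contacts(self) -> int:
        return self.positions_mm.shape[0]

    @property
    def spacing_mm(self) -> float:
        return float(np.linalg.norm(self.positions_mm[1] - self.positions_mm[0]))

    def directions(self) -> np.ndarray:
        """Unit along-track direction at each contact (anterior -> posterior).

        Central differences interior, one-sided at the ends; for a straight
        track every row is the same unit vector.
        """
        pos = self.positions_mm
        d = np.empty_like(pos)
        d[0] = pos[1] - pos[0]
        d[-1] = pos[-1] - pos[-2]
        if pos.shape[0] > 2:
            d[1:-1] = pos[2:] - pos[:-2]
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        return d / norms


@dataclass(frozen=True)
class RecordingGeometry:
    """Ordered depth-electrode tracks, contacts ordered anterior to posterior."""

    tracks: tuple
    anterior_to_posterior: bool = True

    def __post_init__(self):
        object.__setattr__(self, "tracks", tuple(self.tracks))
        if not self.tracks:
            raise ValueError("geometry needs at least one track")

    @property
    def n_contacts(self) -> int:
        return sum(t.n_contacts for t in self.tracks)

    def all_positions(self) -> np.ndarray:
        return np.vstack([t.positions_mm for t in self.tracks])

    def track_labels(self):
        """Per-contact track id, concatenated in track order."""
        out = []
        for t in self.tracks:
            out.extend([t.track_id] * t.n_contacts)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for i, p in enumerate(t.positions_mm):
                rows.append((t.track_id, i, p[0], p[1], p[2]))
        return pd.DataFrame(rows, columns=["track_id", "contact_index", "x_mm", "y_mm", "z_mm"])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RecordingGeometry":
        tracks = []
        for tid, grp in df.groupby("track_id", sort=False):
            grp = grp.sort_values("contact_index")
            tracks.append(Track(str(tid), grp[["x_mm", "y_mm", "z_mm"]].to_numpy()))
        return cls(tuple(tracks))

    @classmethod
    def from_csv(cls, path) -> "RecordingGeometry":
        return cls.from_frame(pd.read_csv(path))


def lead_potential(source_position_mm, observation_position_mm, medium: Medium) -> float:
    """Voltage (mV) per unit current (mA) of a boundary point source.

    ``V = I / (2 pi sigma r)`` for a point source on the surface of a
    half-space; with r in mm and sigma in S/m this evaluates to
    ``1000 / (2 pi sigma r_mm)`` mV/mA.
    """
    r = float(np.linalg.norm(np.asarray(observation_position_mm, float) - np.asarray(source_position_mm, float)))
    if r == 0:
        raise ValueError("observation point coincides with the source (r = 0)")
    return 1000.0 / (2.0 * np.pi * medium.sigma_s_per_m * r)


@dataclass(frozen=True)
class CouplingProfile:
    """Per-contact, per-source transfer coefficients.

    ``v`` has units mV/mA, ``e`` mV/mm per mA along the local track
    direction with the sign convention ``E = -dV/ds`` (s increasing
    anterior -> posterior, so positive field points posterior).
    Columns are ordered [active_1, active_2, return].
    """

    v: np.ndarray  # (n_contacts, n_sources)
    e: np.ndarray  # (n_contacts, n_sources)
    source_labels: tuple
    geometry: RecordingGeometry

    def v_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.v, columns=list(self.source_labels))

    def e_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.e, columns=list(self.source_labels))


def coupling_profile(
    montage: ElectrodeMontage, geometry: RecordingGeometry, medium: Medium
) -> CouplingProfile:
    """Analytic V and along-track E couplings of every montage electrode.

    The field coupling is the negative directional derivative of the
    half-space kernel along the local track direction:
    ``E = k (d . u) / r^3`` with ``k = 1000 / (2 pi sigma)`` and
    ``d = contact - source``.
    """
    sources = list(montage.active) + [montage.return_electrode]
    k = 1000.0 / (2.0 * np.pi * medium.sigma_s_per_m)
    v_rows, e_rows = [], []
    for track in geometry.tracks:
        pos = track.positions_mm
        dirs = track.directions()
        for s in sources:
            d = pos - np.asarray(s.position_mm)
            r = np.linalg.norm(d, axis=1)
            if np.any(r == 0):
                raise ValueError(
                    f"contact coincides with electrode {s.label!r} (r = 0)"
                )
        v = np.column_stack(
            [
                k / np.linalg.norm(pos - np.asarray(s.position_mm), axis=1)
                for s in sources
            ]
        )
        e = np.column_stack(
            [
                k
                * np.sum((pos - np.asarray(s.position_mm)) * dirs, axis=1)
                / np.linalg.norm(pos - np.asarray(s.position_mm), axis=1) ** 3
                for s in sources
            ]
        )
        v_rows.append(v)
        e_rows.append(e)
    return CouplingProfile(
        v=np.vstack(v_rows),
        e=np.vstack(e_rows),
        source_labels=tuple(s.label for s in sources),
        geometry=geometry,
    )


def return_current(montage: ElectrodeMontage, condition_theta_deg: float) -> Phasor:
    """Phasor current (mA) the return electrode must sink.

    With active currents ``I1`` at phase 0 and ``I2`` at the condition
    phase theta, Kirchhoff's law forces the return to carry
    ``-(I1 + I2 e^{i theta})``.
    """
    a1, a2 = montage.active
    z = -(
        a1.amplitude_ma
        + a2.amplitude_ma * np.exp(1j * np.radians(condition_theta_deg))
    )
    return Phasor.from_complex(z, floor=1e-12 * (a1.amplitude_ma + a2.amplitude_ma))


@dataclass(frozen=True)
class PhasorField:
    """Per-contact complex amplitudes of voltage (mV) and along-track field
    (mV/mm) for one stimulation condition."""

    v: np.ndarray  # complex, (n_contacts,)
    e: np.ndarray  # complex, (n_contacts,)
    geometry: RecordingGeometry
    condition_theta_deg: float
    frequency_hz: float

    @property
    def v_magnitude(self):
        return np.abs(self.v)

    @property
    def e_magnitude(self):
        return np.abs(self.e)

    @property
    def v_phase_deg(self):
        return wrap_phase_deg(np.degrees(np.angle(self.v)))

    @property
    def e_phase_deg(self):
        return wrap_phase_deg(np.degrees(np.angle(self.e)))

    def v_timecourse(self, times_ms) -> np.ndarray:
        """Noiseless voltage matrix (n_contacts, n_times) in mV."""
        w = 2.0 * np.pi * self.frequency_hz * np.asarray(times_ms, float) / 1000.0
        return np.real(self.v[:, None] * np.exp(1j * w[None, :]))

    def e_timecourse(self, times_ms) -> np.ndarray:
        """Noiseless along-track field matrix (n_contacts, n_times) in mV/mm."""
        w = 2.0 * np.pi * self.frequency_hz * np.asarray(times_ms, float) / 1000.0
        return np.real(self.e[:, None] * np.exp(1j * w[None, :]))


def simulate_phasor_field(
    montage: ElectrodeMontage,
    geometry: RecordingGeometry,
    medium: Medium,
    condition_theta_deg: float,
    frequency_hz: float = 10.0,
    couplings: CouplingProfile | None = None,
) -> PhasorField:
    """Forward-model the per-contact V and E phasors for one condition.

    The first active electrode is the phase reference (0 deg), the second
    carries the condition phase theta, and the return carries the computed
    complement.  Pass a precomputed ``couplings`` profile to amortize the
    geometry work across a condition sweep.
    """
    if not (0.0 <= condition_theta_deg <= 360.0):
        raise ValueError("condition theta must lie in [0, 360] degrees")
    if couplings is None:
        couplings = coupling_profile(montage, geometry, medium)
    a1, a2 = montage.active
    i_ret = return_current(montage, condition_theta_deg)
    currents = np.array(
        [
            a1.amplitude_ma,
            a2.amplitude_ma * np.exp(1j * np.radians(condition_theta_deg)),
            i_ret.to_complex(),
        ]
    )
    return PhasorField(
        v=couplings.v @ currents,
        e=couplings.e @ currents,
        geometry=geometry,
        condition_theta_deg=condition_theta_deg,
        frequency_hz=frequency_hz,
    )


def dose_metrics(montage: ElectrodeMontage, epoch_duration_s: float):
    """RMS current density (A/m^2) and per-condition charge density (C/m^2).

    For a sinusoidal current of peak-to-zero amplitude I the RMS current is
    ``I / sqrt(2)``; dividing by the pad area gives the current density, and
    multiplying the density by the epoch duration gives the charge density
    delivered per condition.
    """
    if montage.area_cm2 <= 0:
        raise ValueError("electrode area must be positive")
    amp_ma = montage.active[0].amplitude_ma
    i_rms_a = amp_ma * 1e-3 / np.sqrt(2.0)
    area_m2 = montage.area_cm2 * 1e-4
    current_density = i_rms_a / area_m2
    charge_density = current_density * epoch_duration_s
    return current_density, charge_density
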