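"""Preset montages, geometries and idealized coupling fixtures.

Three presets cover the study designs the package targets:

* ``symmetric_line`` -- a mirror-symmetric three-electrode montage over a
  single straight depth track, the oracle-friendly configuration in which
  the 0- and 180-degree conditions are exactly stationary in space.
* ``subject1_like`` -- three depth tracks of 12/10/10 contacts at 5 mm
  spacing under an anterior/posterior active pair with a lateral return.
* ``rotated_control`` -- the same recording tracks with the montage rotated
  90 degrees about the vertical axis, emulating a control experiment with a
  perpendicular field.

The module also provides an idealized *end-driven* coupling fixture in
which the two end contacts of a track are each coupled to exactly one
active electrode and the coupling rotates monotonically in between; under a
90-degree condition this yields the textbook 50/25/25 split of
unidirectional/inward/outward field orientations.
"""

from __future__ import annotations

import numpy as np

from .conductor import ElectrodeMontage, Medium, RecordingGeometry, StimElectrode, Track

__all__ = [
    "PRESETS",
    "make_montage",
    "make_geometry",
    "preset",
    "end_driven_couplings",
    "end_driven_e_phasors",
    "end_driven_e_matrix",
    "midpoint_cycle_times_ms",
]

PRESETS = ("symmetric_line", "subject1_like", "rotated_control")


def _straight_track(track_id, n, x_start, y, z, spacing=5.0):
    x = x_start + spacing * np.arange(n)
    pos = np.column_stack([x, np.full(n, float(y)), np.full(n, float(z))])
    return Track(track_id, pos)


def make_montage(name: str) -> ElectrodeMontage:
    if name in ("symmetric_line", "subject1_like"):
        electrodes = (
            StimElectrode("anterior", (-70.0, 0.0, 0.0), "active", 0.1),
            StimElectrode("posterior", (70.0, 0.0, 0.0), "active", 0.1),
            StimElectrode("return", (0.0, 80.0, 0.0), "return"),
        )
    elif name == "rotated_control":
        # montage rotated 90 degrees about z: field perpendicular to the main run
        electrodes = (
            StimElectrode("anterior", (0.0, -70.0, 0.0), "active", 0.1),
            StimElectrode("posterior", (0.0, 70.0, 0.0), "active", 0.1),
            StimElectrode("return", (-80.0, 0.0, 0.0), "return"),
        )
    else:
        raise KeyError(f"unknown preset {name!r}; known presets: {PRESETS}")
    return ElectrodeMontage(electrodes)


def make_geometry(name: str) -> RecordingGeometry:
    if name == "symmetric_line":
        # 12 contacts at 5 mm spacing, mirror-symmetric about the midplane
        return RecordingGeometry((_straight_track("e1", 12, -27.5, 0.0, 15.0),))
    if name in ("subject1_like", "rotated_control"):
        return RecordingGeometry(
            (
                _straight_track("e1", 12, -30.0, 5.0, 12.0),
                _straight_track("e2", 10, -25.0, -8.0, 18.0),
                _straight_track("e3", 10, -20.0, 0.0, 25.0),
            )
        )
    raise KeyError(f"unknown preset {name!r}; known presets: {PRESETS}")


def preset(name: str):
    """Montage, geometry and medium for a named preset."""
    return make_montage(name), make_geometry(name), Medium()


def end_driven_couplings(n_contacts: int = 12) -> np.ndarray:
    """Mirror-symmetric coupling matrix with purely end-driven extremes.

    Row i couples contact i to the two active sources as
    ``(cos a_i, sin a_i)`` with ``a_i`` running linearly from 0 to 90
    degrees: the anterior end responds only to source 1, the posterior end
    only to source 2, with unit field amplitude and monotone phase rotation
    in between.
    """
    if n_contacts < 2:
        raise ValueError("need at least two contacts")
    a = np.radians(np.linspace(0.0, 90.0, n_contacts))
    return np.column_stack([np.cos(a), np.sin(a)])


def end_driven_e_phasors(theta_deg: float, n_contacts: int = 12) -> np.ndarray:
    """Complex field amplitudes of the end-driven fixture for one condition."""
    c = end_driven_couplings(n_contacts)
    currents = np.array([1.0, np.exp(1j * np.radians(theta_deg))])
    return c @ currents


def midpoint_cycle_times_ms(f_stim_hz: float, rate_hz: float, n_cycles: int = 1) -> np.ndarray:
    """Sample times centered within each sampling interval.

    Midpoint sampling is the natural quadrature for cycle fractions: no
    sample lands exactly on a zero crossing of the carrier, so discrete
    orientation fractions match their continuous-time values.
    """
    n = int(round(n_cycles * rate_hz / f_stim_hz))
    return (np.arange(n) + 0.5) / rate_hz * 1000.0


def end_driven_e_matrix(
    theta_deg: float,
    n_contacts: int = 12,
    f_stim_hz: float = 10.0,
    rate_hz: float = 1000.0,
    n_cycles: int = 1,
) -> np.ndarray:
    """Time-domain field matrix (contacts x samples) of the end-driven
    fixture, sampled at interval midpoints over whole cycles."""
    z = end_driven_e_phasors(theta_deg, n_contacts)
    t_ms = midpoint_cycle_times_ms(f_stim_hz, rate_hz, n_cycles)
    w = 2.0 * np.pi * f_stim_hz * t_ms / 1000.0
    return np.real(z[:, None] * np.exp(1j * w[None, :]))
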