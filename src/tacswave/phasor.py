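"""Phasor algebra for superposed same-frequency sinusoidal sources.

In the quasi-static regime the voltage (and field) produced by several
sinusoidal current sources of a common frequency is itself a sinusoid at
that frequency, so every location in the conductor is fully described by a
complex amplitude -- a *phasor*.  This module implements that algebra and is
the analytic oracle against which every simulated and estimated quantity in
the package is checked.

Conventions
-----------
* Cosine reference: a phasor ``(A, phi)`` represents ``A*cos(2*pi*f*t + phi)``.
* Phases are in degrees, wrapped to ``(-180, +180]``; positive = phase lead.
* A zero-magnitude phasor has no meaningful phase and carries an explicit
  ``defined=False`` flag instead of a sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Phasor",
    "SourceSet",
    "wrap_phase_deg",
    "superpose",
    "two_source_amplitude",
    "same_sign_fraction",
    "waveform",
]

#: relative floor below which a superposition is treated as exact cancellation
_CANCEL_RTOL = 1e-12


def wrap_phase_deg(phi):
    """Wrap angles in degrees to the interval ``(-180, +180]``."""
    phi = np.asarray(phi, dtype=float)
    wrapped = (phi + 180.0) % 360.0 - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class Phasor:
    """Complex amplitude of a sinusoid: magnitude plus phase in degrees.

    Parameters
    ----------
    magnitude : float
        Nonnegative amplitude in the units of the represented quantity
        (mV for voltage, mV/mm for field).
    phase_deg : float
        Phase in degrees, wrapped to ``(-180, 180]``.  Ignored (stored as 0)
        when ``defined`` is False.
    defined : bool
        False when the magnitude is zero and the phase is meaningless.
    """

    magnitude: float
    phase_deg: float = 0.0
    defined: bool = True

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("phasor magnitude must be nonnegative")
        object.__setattr__(self, "phase_deg", wrap_phase_deg(self.phase_deg) if self.defined else 0.0)

    @classmethod
    def from_complex(cls, z: complex, floor: float = 0.0) -> "Phasor":
        mag = abs(z)
        if mag <= floor:
            return cls(0.0, 0.0, defined=False)
        return cls(mag, np.degrees(np.angle(z)))

    def to_complex(self) -> complex:
        return self.magnitude * np.exp(1j * np.radians(self.phase_deg))

    def to_json_triple(self):
        """Serialize as the (magnitude, phase_deg, defined) triple."""
        return [self.magnitude, self.phase_deg, self.defined]


@dataclass(frozen=True)
class SourceSet:
    """An ordered set of same-frequency sinusoidal current sources.

    ``amplitudes_ma`` are peak-to-zero amplitudes in mA; ``phases_deg`` the
    per-source phases.  The inter-source phase shift is the experimental
    condition variable in a multi-electrode stimulation sweep.
    """

    amplitudes_ma: tuple = field(default=())
    phases_deg: tuple = field(default=())
    frequency_hz: float = 10.0

    def __post_init__(self):
        amps = tuple(float(a) for a in self.amplitudes_ma)
        phis = tuple(float(p) for p in self.phases_deg)
        if len(amps) != len(phis):
            raise ValueError("amplitudes and phases must have equal length")
        if len(amps) < 2:
            raise ValueError("a source set needs at least two sources")
        if any(a < 0 for a in amps):
            raise ValueError("current amplitudes must be nonnegative")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        object.__setattr__(self, "amplitudes_ma", amps)
        object.__setattr__(self, "phases_deg", phis)

    def __len__(self):
        return len(self.amplitudes_ma)

    def complex_currents(self) -> np.ndarray:
        return np.asarray(self.amplitudes_ma) * np.exp(
            1j * np.radians(np.asarray(self.phases_deg))
        )


def superpose(couplings: Sequence[float], sources: SourceSet) -> Phasor:
    """Phasor of ``sum_k c_k * I_k * cos(w t + theta_k)``.

    ``couplings`` are signed transfer coefficients (e.g. mV per mA) of each
    source to one observation point.  Exact cancellation (all-zero result)
    yields a zero-magnitude phasor with an undefined phase.
    """
    c = np.asarray(couplings, dtype=float)
    if c.shape != (len(sources),):
        raise ValueError(
            f"expected {len(sources)} couplings, got shape {c.shape}"
        )
    z = np.sum(c * sources.complex_currents())
    scale = np.sum(np.abs(c) * np.asarray(sources.amplitudes_ma))
    return Phasor.from_complex(z, floor=_CANCEL_RTOL * scale)


def two_source_amplitude(a: float, b: float, theta_deg: float) -> float:
    """Amplitude of ``a*cos(wt) + b*cos(wt + theta)``.

    Closed form ``sqrt(a^2 + b^2 + 2 a b cos(theta))``; symmetric under
    ``theta -> 360 - theta``.  ``a`` and ``b`` may be signed.
    """
    val = a * a + b * b + 2.0 * a * b * np.cos(np.radians(theta_deg))
    return float(np.sqrt(max(val, 0.0)))


def same_sign_fraction(delta_phi_deg: float) -> float:
    """Fraction of a cycle two equal-frequency sinusoids share a sign.

    For a phase offset ``d`` (wrapped to [0, 180] degrees) the two waveforms
    have equal sign for a fraction ``1 - d/180`` of every cycle: 1 when in
    phase, 0 in anti-phase and 0.5 at quadrature.
    """
    d = abs(wrap_phase_deg(delta_phi_deg))
    return 1.0 - d / 180.0


def waveform(p: Phasor, frequency_hz: float, times_ms) -> np.ndarray:
    """Evaluate the time-domain sinusoid of a phasor at times in ms."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    if not p.defined:
        if p.magnitude > 0:
            raise ValueError("cannot render a phasor with undefined phase and nonzero magnitude")
        return np.zeros_like(np.asarray(times_ms, dtype=float))
    t_s = np.asarray(times_ms, dtype=float) / 1000.0
    return p.magnitude * np.cos(2.0 * np.pi * frequency_hz * t_s + np.radians(p.phase_deg))
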