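"""Spectral phase/amplitude extraction, E-field computation, RMS magnitude,
phase differences and instantaneous field-directionality classification.

The along-track field component is ``E = -dV/ds`` with s increasing
anterior -> posterior, so a positive value points posterior.  At any instant
the sign pattern of E along a track classifies the field as unidirectional
(all signs equal), inward (anterior contacts positive, posterior negative:
the field converges toward the middle) or outward (the reverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasor import wrap_phase_deg
from .conductor import RecordingGeometry

__all__ = [
    "SpectralEstimate",
    "ConditionSummary",
    "extract_phase_amplitude",
    "extract_spectra",
    "compute_efield",
    "rms_magnitude",
    "phase_difference",
    "directionality_fractions",
    "summarize_condition",
]

FFT_PAD_LENGTH = 32768  # 2**15


@dataclass(frozen=True)
class SpectralEstimate:
    """Per-contact amplitude and phase at the stimulation frequency.

    ``phase_deg`` entries are NaN where ``defined`` is False (amplitude
    below the floor relative to the track maximum).
    """

    amplitude: np.ndarray
    phase_deg: np.ndarray
    defined: np.ndarray
    frequency_hz: float


def _whole_cycle_count(n_samples: int, rate_hz: float, f_hz: float) -> int:
    return int(np.floor(n_samples * f_hz / rate_hz))


def extract_phase_amplitude(x: np.ndarray, rate_hz: float, f_stim_hz: float, mode: str = "exact"):
    """Amplitude and phase (degrees) of one trace at the stimulation frequency.

    mode="exact" (default): complex projection onto ``exp(-i w t)`` over the
    largest whole number of stimulation cycles -- exact at f_stim regardless
    of bin placement.  mode="fft_bin": zero-pad to 32768 samples (2**15; or
    the next power of two if longer) and read the FFT bin nearest f_stim;
    this mirrors a common literal procedure but incurs leakage whenever
    f_stim falls between bins.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if f_stim_hz >= rate_hz / 2:
        raise ValueError("stimulation frequency must be below Nyquist")
    if mode == "exact":
        n_cyc = _whole_cycle_count(x.shape[-1], rate_hz, f_stim_hz)
        if n_cyc < 1:
            raise ValueError("need at least one whole stimulation cycle")
        n = int(round(n_cyc * rate_hz / f_stim_hz))
        t = np.arange(n) / rate_hz
        basis = np.exp(-2j * np.pi * f_stim_hz * t)
        z = 2.0 * (x[:, :n] @ basis) / n
    elif mode == "fft_bin":
        n = x.shape[-1]
        nfft = FFT_PAD_LENGTH
        while nfft < n:
            nfft *= 2
        spec = np.fft.rfft(x, n=nfft, axis=-1)
        freqs = np.fft.rfftfreq(nfft, d=1.0 / rate_hz)
        k = int(np.argmin(np.abs(freqs - f_stim_hz)))
        z = 2.0 * spec[:, k] / n
    else:
        raise ValueError(f"unknown mode {mode!r}")
    amp = np.abs(z)
    phase = np.atleast_1d(wrap_phase_deg(np.degrees(np.angle(z))))
    if np.asarray(x).ndim == 1 or amp.size == 1:
        return float(amp[0]), float(phase[0])
    return amp, phase


def extract_spectra(
    matrix: np.ndarray,
    rate_hz: float,
    f_stim_hz: float,
    mode: str = "exact",
    floor_rel: float = 1e-9,
) -> SpectralEstimate:
    """Per-contact spectral estimate for a contact x time matrix.

    Phases are flagged undefined where the amplitude falls below
    ``floor_rel`` times the maximum amplitude across contacts.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    amp, phase = extract_phase_amplitude(matrix, rate_hz, f_stim_hz, mode=mode)
    amp = np.atleast_1d(amp)
    phase = np.atleast_1d(np.asarray(phase, dtype=float))
    floor = floor_rel * (amp.max() if amp.size else 0.0)
    defined = amp > floor
    phase = np.where(defined, phase, np.nan)
    return SpectralEstimate(amplitude=amp, phase_deg=phase, defined=defined, frequency_hz=f_stim_hz)


def compute_efield(v_matrix: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Along-track field from voltages: ``E = -dV/ds`` by numerical gradient.

    Central differences at interior contacts, one-sided at the ends
    (with two contacts both rows carry the single one-sided estimate).
    Axis 0 is contacts ordered anterior -> posterior; units mV/mm.
    """
    v = np.asarray(v_matrix, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("need at least two contacts to form a gradient")
    if spacing_mm <= 0:
        raise ValueError("contact spacing must be positive")
    return -np.gradient(v, spacing_mm, axis=0)


def rms_magnitude(x: np.ndarray, rate_hz: float, f_stim_hz: float) -> float:
    """Root-mean-square per whole stimulation cycle, averaged over cycles.

    The trailing partial cycle is dropped; equals amplitude/sqrt(2) for a
    pure sinusoid.  Works on a trace (returns a float) or a contact x time
    matrix (returns per-contact values).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    n_cyc = _whole_cycle_count(n, rate_hz, f_stim_hz)
    if n_cyc < 1:
        raise ValueError("trace shorter than one stimulation cycle")
    spc = rate_hz / f_stim_hz
    edges = np.round(np.arange(n_cyc + 1) * spc).astype(int)
    vals = [
        np.sqrt(np.mean(x[..., edges[i]:edges[i + 1]] ** 2, axis=-1))
        for i in range(n_cyc)
    ]
    out = np.mean(vals, axis=0)
    return float(out) if np.ndim(out) == 0 else out


def phase_difference(phi_anterior_deg: float, phi_posterior_deg: float) -> float:
    """Signed anterior-minus-posterior phase difference wrapped to (-180, 180].

    NaN (undefined) inputs propagate to a NaN output.
    """
    if np.isnan(phi_anterior_deg) or np.isnan(phi_posterior_deg):
        return float("nan")
    return float(wrap_phase_deg(phi_anterior_deg - phi_posterior_deg))


@dataclass(frozen=True)
class DirectionalityFractions:
    unidirectional: float
    inward: float
    outward: float
    n_counted: int
    n_excluded: int

    def as_tuple(self):
        return (self.unidirectional, self.inward, self.outward)


def directionality_fractions(
    e_matrix: np.ndarray,
    rate_hz: float,
    f_stim_hz: float,
    floor_rel: float = 1e-6,
) -> DirectionalityFractions:
    """Fractions of time the field is unidirectional / inward / outward.

    Evaluated over whole stimulation cycles.  Per time sample the sign
    pattern along the track decides the class; samples with |E| below
    ``floor_rel`` times that contact's own maximum are sign-agnostic.  The
    classification uses the dominant-pair rule: the first and last contacts
    with a determinate sign decide -- equal signs mean unidirectional,
    anterior-positive/posterior-negative means inward (converging), the
    reverse means outward.  All-agnostic samples are excluded from the
    denominator and reported.
    """
    e = np.asarray(e_matrix, dtype=float)
    if e.shape[0] < 2:
        raise ValueError("need at least two contacts")
    n = e.shape[-1]
    n_cyc = _whole_cycle_count(n, rate_hz, f_stim_hz)
    if n_cyc < 1:
        raise ValueError("need at least one whole stimulation cycle")
    n_keep = int(round(n_cyc * rate_hz / f_stim_hz))
    e = e[:, :n_keep]
    floor = floor_rel * np.max(np.abs(e), axis=1, keepdims=True)
    signs = np.where(np.abs(e) > floor, np.sign(e), 0.0)

    uni = inward = outward = excluded = 0
    for t in range(n_keep):
        col = signs[:, t]
        nz = np.flatnonzero(col)
        if nz.size == 0:
            excluded += 1
            continue
        a, p = col[nz[0]], col[nz[-1]]
        if a == p:
            uni += 1
        elif a > 0 > p:
            inward += 1
        else:
            outward += 1
    counted = n_keep - excluded
    if counted == 0:
        raise ValueError("all samples were sign-agnostic (zero field)")
    return DirectionalityFractions(
        unidirectional=uni / counted,
        inward=inward / counted,
        outward=outward / counted,
        n_counted=counted,
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class ConditionSummary:
    """Derived per-condition quantities.

    Scalar phase differences and the superficial/deep ratio are per-track
    values averaged across tracks (circular mean for phases); the per-track
    values are retained in the ``*_by_track`` mappings.
    """

    theta_deg: float
    voltage_range_mv: float
    rms_e: np.ndarray
    dphi_v_deg: float
    dphi_e_deg: float
    superficial_deep_ratio: float
    fractions: DirectionalityFractions
    dphi_v_by_track: dict = field(default_factory=dict)
    dphi_e_by_track: dict = field(default_factory=dict)
    ratio_by_track: dict = field(default_factory=dict)

    def __post_init__(self):
        f = self.fractions
        total = f.unidirectional + f.inward + f.outward
        if abs(total - 1.0) > 1e-9:
            raise ValueError("directionality fractions must sum to 1")
        if self.voltage_range_mv < 0:
            raise ValueError("voltage range must be nonnegative")


def _circular_mean_deg(angles):
    angles = np.asarray(angles, dtype=float)
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        return float("nan")
    z = np.exp(1j * np.radians(angles)).mean()
    return float(wrap_phase_deg(np.degrees(np.angle(z))))


def summarize_condition(
    spectra_v: SpectralEstimate,
    spectra_e: SpectralEstimate,
    e_matrix: np.ndarray,
    geometry: RecordingGeometry,
    theta_deg: float,
    rate_hz: float,
    f_stim_hz: float,
) -> ConditionSummary:
    """Populate the per-condition summary from per-contact spectra and the
    field time-course.

    Voltage range is max - min of per-contact voltage amplitudes across all
    contacts; the phase differences subtract the most posterior from the
    most anterior contact of each track; the superficial/deep ratio divides
    the RMS field at a track's first analyzed contact by that at its last.
    """
    labels = np.asarray(geometry.track_labels())
    v_amp = spectra_v.amplitude
    rms_e = rms_magnitude(e_matrix, rate_hz, f_stim_hz)
    dphi_v, dphi_e, ratios = {}, {}, {}
    for t in geometry.tracks:
        idx = np.flatnonzero(labels == t.track_id)
        first, last = idx[0], idx[-1]
        dphi_v[t.track_id] = phase_difference(spectra_v.phase_deg[first], spectra_v.phase_deg[last])
        dphi_e[t.track_id] = phase_difference(spectra_e.phase_deg[first], spectra_e.phase_deg[last])
        ratios[t.track_id] = float(rms_e[first] / rms_e[last]) if rms_e[last] > 0 else float("nan")
    fractions = directionality_fractions(e_matrix, rate_hz, f_stim_hz)
    return ConditionSummary(
        theta_deg=theta_deg,
        voltage_range_mv=float(v_amp.max() - v_amp.min()),
        rms_e=np.asarray(rms_e),
        dphi_v_deg=_circular_mean_deg(list(dphi_v.values())),
        dphi_e_deg=_circular_mean_deg(list(dphi_e.values())),
        superficial_deep_ratio=float(np.nanmean(list(ratios.values()))),
        fractions=fractions,
        dphi_v_by_track=dphi_v,
        dphi_e_by_track=dphi_e,
        ratio_by_track=ratios,
    )
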