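"""End-to-end orchestration: simulate -> preprocess -> analyze -> wave -> fit.

A run is fully reproducible from a :class:`RunConfig` plus its seed; every
output directory receives a ``report.txt`` carrying the config hash, seed
and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conductor import ElectrodeMontage, Medium, RecordingGeometry
from .fields import extract_spectra, compute_efield, summarize_condition
from .fixtures import PRESETS, preset
from .preprocess import PreprocessConfig, preprocess_session
from .recordings import NoiseModel, Protocol, RecordingSet, generate_session, write_dataset
from .statfits import brown_forsythe, fit_condition_curve, kruskal_wallis, watson_williams
from .waves import dissimilarity_index, fit_wave, normalize_timecourses, spatial_variability_index

logger = logging.getLogger("tacswave")

__all__ = ["RunConfig", "make_fixtures", "run_pipeline", "analyze_session", "wave_session", "fit_session"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one full pipeline run."""

    preset_name: str = "symmetric_line"
    medium_sigma_s_per_m: float = 0.275
    protocol: Protocol = field(default_factory=Protocol)
    noise: NoiseModel = field(default_factory=NoiseModel)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral_mode: str = "exact"
    wave_threshold_deg_per_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.preset_name not in PRESETS:
            raise ValueError(
                f"config field 'preset_name': unknown preset {self.preset_name!r}; "
                f"known presets: {PRESETS}"
            )
        if self.spectral_mode not in ("exact", "fft_bin"):
            raise ValueError("config field 'spectral_mode': must be 'exact' or 'fft_bin'")
        # the seed overrides whatever the noise model carried
        object.__setattr__(self, "noise", NoiseModel(**{**self.noise.to_dict(), "seed": self.seed}))

    def to_dict(self) -> dict:
        return {
            "preset_name": self.preset_name,
            "medium_sigma_s_per_m": self.medium_sigma_s_per_m,
            "protocol": self.protocol.to_dict(),
            "noise": self.noise.to_dict(),
            "preprocess": self.preprocess.to_dict(),
            "spectral_mode": self.spectral_mode,
            "wave_threshold_deg_per_mm": self.wave_threshold_deg_per_mm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {
            "preset_name", "medium_sigma_s_per_m", "protocol", "noise",
            "preprocess", "spectral_mode", "wave_threshold_deg_per_mm", "seed",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "protocol" in d:
            d["protocol"] = Protocol.from_dict(d["protocol"])
        if "noise" in d:
            d["noise"] = NoiseModel.from_dict(d["noise"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig.from_dict(d["preprocess"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def make_fixtures(name: str, seed: int = 0, protocol: Protocol | None = None, noise: NoiseModel | None = None):
    """Build a preset's config and simulate its dataset.

    Returns ``(config, recording_set)``; the recording set is at the native
    sampling rate.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known presets: {PRESETS}")
    config = RunConfig(
        preset_name=name,
        protocol=protocol or Protocol(),
        noise=noise or NoiseModel(seed=seed),
        seed=seed,
    )
    montage, geometry, medium = preset(name)
    medium = Medium(sigma_s_per_m=config.medium_sigma_s_per_m)
    rs = generate_session(montage, geometry, medium, config.protocol, config.noise)
    return config, rs


def _split_tracks(matrix: np.ndarray, geometry: RecordingGeometry):
    labels = np.asarray(geometry.track_labels())
    for t in geometry.tracks:
        yield t, matrix[labels == t.track_id]


def session_efield(matrix: np.ndarray, geometry: RecordingGeometry) -> np.ndarray:
    """Stack per-track along-track fields for a full contact x time matrix."""
    return np.vstack([compute_efield(sub, t.spacing_mm) for t, sub in _split_tracks(matrix, geometry)])


def analyze_session(rs: RecordingSet, spectral_mode: str = "exact"):
    """Per-condition spectra and summaries for a preprocessed session.

    Returns ``(summaries, summary_frame, per_contact_frame)``.
    """
    f0 = rs.protocol.frequency_hz
    summaries, contact_rows = [], []
    for theta in rs.conditions:
        v = rs.data[theta]
        e = session_efield(v, rs.geometry)
        sv = extract_spectra(v, rs.rate_hz, f0, mode=spectral_mode)
        se = extract_spectra(e, rs.rate_hz, f0, mode=spectral_mode)
        summary = summarize_condition(sv, se, e, rs.geometry, theta, rs.rate_hz, f0)
        summaries.append(summary)
        labels = rs.geometry.track_labels()
        for i in range(rs.geometry.n_contacts):
            contact_rows.append(
                {
                    "theta_deg": theta,
                    "track_id": labels[i],
                    "contact": i,
                    "v_amplitude_mv": sv.amplitude[i],
                    "v_phase_deg": sv.phase_deg[i],
                    "e_amplitude_mv_per_mm": se.amplitude[i],
                    "e_phase_deg": se.phase_deg[i],
                    "rms_e_mv_per_mm": summary.rms_e[i],
                }
            )
        logger.info("analyzed condition theta=%g (%d contacts)", theta, rs.geometry.n_contacts)
    frame = pd.DataFrame(
        {
            "theta_deg": [s.theta_deg for s in summaries],
            "voltage_range_mv": [s.voltage_range_mv for s in summaries],
            "rms_e_mean_mv_per_mm": [float(np.mean(s.rms_e)) for s in summaries],
            "rms_e_max_mv_per_mm": [float(np.max(s.rms_e)) for s in summaries],
            "dphi_v_deg": [s.dphi_v_deg for s in summaries],
            "dphi_e_deg": [s.dphi_e_deg for s in summaries],
            "superficial_deep_ratio": [s.superficial_deep_ratio for s in summaries],
            "frac_unidirectional": [s.fractions.unidirectional for s in summaries],
            "frac_inward": [s.fractions.inward for s in summaries],
            "frac_outward": [s.fractions.outward for s in summaries],
        }
    )
    return summaries, frame, pd.DataFrame(contact_rows)


def wave_session(rs: RecordingSet, spectral_mode: str = "exact", threshold: float = 1.0):
    """Traveling-wave metrics per condition.

    Returns ``(condition_frame, track_frame)``: the first holds the
    dissimilarity index and maximum spatial-variability SD per condition,
    the second the per-track phase-gradient fits (r, b, R^2, c, detected).
    """
    f0 = rs.protocol.frequency_hz
    labels = np.asarray(rs.geometry.track_labels())
    cond_rows, track_rows = [], []
    for theta in rs.conditions:
        v = rs.data[theta]
        e = session_efield(v, rs.geometry)
        norm, _ = normalize_timecourses(e)
        dis = dissimilarity_index(norm, track_labels=labels)
        _, max_sd, n_skipped = spatial_variability_index(np.abs(e))
        cond_rows.append(
            {
                "theta_deg": theta,
                "dissimilarity": dis.index,
                "max_rescaled_sd": max_sd,
                "n_degenerate_steps": n_skipped,
            }
        )
        se = extract_spectra(e, rs.rate_hz, f0, mode=spectral_mode)
        for t in rs.geometry.tracks:
            idx = np.flatnonzero(labels == t.track_id)
            x = np.arange(idx.size) * t.spacing_mm
            fit = fit_wave(se.phase_deg[idx], x, f0, threshold=threshold)
            track_rows.append(
                {
                    "theta_deg": theta,
                    "track_id": t.track_id,
                    "r_deg_per_mm": fit.r_deg_per_mm,
                    "b_deg": fit.b_deg,
                    "r_squared": fit.r_squared,
                    "c_mm_per_ms": fit.c_mm_per_ms,
                    "detected": fit.detected,
                    "direction": fit.direction,
                }
            )
    return pd.DataFrame(cond_rows), pd.DataFrame(track_rows)


def fit_session(summary: pd.DataFrame, per_contact: pd.DataFrame):
    """Condition-curve fits and group tests on an analyzed session.

    Fits the linear and fixed-period sinusoidal models to voltage range and
    mean field RMS versus condition, and runs the three group tests with
    contacts as replicates within condition groups: Kruskal-Wallis on field
    RMS, Brown-Forsythe on voltage amplitudes, Watson-Williams on voltage
    phases.
    """
    theta = summary["theta_deg"].to_numpy()
    fit_rows = []
    for target in ("voltage_range_mv", "rms_e_mean_mv_per_mm"):
        y = summary[target].to_numpy()
        for kind in ("linear", "sinusoid"):
            cf = fit_condition_curve(theta, y, kind=kind)
            fit_rows.append(
                {
                    "target": target,
                    "kind": kind,
                    "sse": cf.sse,
                    "r_squared": cf.r_squared,
                    "r_squared_adj": cf.r_squared_adj,
                    **{f"coef_{k}": v for k, v in cf.coefficients.items()},
                }
            )
    groups = per_contact.groupby("theta_deg", sort=True)
    rms_groups = [g["rms_e_mv_per_mm"].to_numpy() for _, g in groups]
    amp_groups = [g["v_amplitude_mv"].to_numpy() for _, g in groups]
    phase_groups = [g["v_phase_deg"].dropna().to_numpy() for _, g in groups]
    tests = [
        kruskal_wallis(rms_groups),
        brown_forsythe(amp_groups),
        watson_williams(phase_groups),
    ]
    test_rows = [
        {
            "name": t.name,
            "statistic": t.statistic,
            "df1": t.df[0],
            "df2": t.df[1],
            "p_value": t.p_value,
        }
        for t in tests
    ]
    return pd.DataFrame(fit_rows), pd.DataFrame(test_rows)


def run_pipeline(config: RunConfig, out_dir, keep_raw: bool = False) -> dict:
    """Execute the full pipeline and write the report bundle.

    Writes ``summary.csv`` (one row per condition), ``per_contact.csv``,
    ``wave_conditions.csv``, ``wave_tracks.csv``, ``fits.csv``,
    ``tests.csv``, the echoed ``config.json`` and a ``report.txt`` with
    provenance; optionally the raw dataset under ``raw/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage, geometry, _ = preset(config.preset_name)
    medium = Medium(sigma_s_per_m=config.medium_sigma_s_per_m)

    logger.info("simulate: preset=%s seed=%d conditions=%d", config.preset_name, config.seed, config.protocol.n_conditions)
    raw = generate_session(montage, geometry, medium, config.protocol, config.noise)
    if keep_raw:
        write_dataset(raw, out / "raw")

    logger.info("preprocess: %d conditions @ %g Hz -> %g Hz", len(raw.conditions), raw.rate_hz, config.preprocess.target_rate_hz)
    pre = preprocess_session(raw, config.preprocess)

    logger.info("analyze: spectral_mode=%s", config.spectral_mode)
    _, summary, per_contact = analyze_session(pre, spectral_mode=config.spectral_mode)
    wave_cond, wave_tracks = wave_session(
        pre, spectral_mode=config.spectral_mode, threshold=config.wave_threshold_deg_per_mm
    )
    fits, tests = fit_session(summary, per_contact)

    summary.to_csv(out / "summary.csv", index=False)
    per_contact.to_csv(out / "per_contact.csv", index=False)
    wave_cond.to_csv(out / "wave_conditions.csv", index=False)
    wave_tracks.to_csv(out / "wave_tracks.csv", index=False)
    fits.to_csv(out / "fits.csv", index=False)
    tests.to_csv(out / "tests.csv", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        fh.write(
            "tacswave pipeline report\n"
            f"package version: {__version__}\n"
            f"config hash: {config.config_hash()}\n"
            f"seed: {config.seed}\n"
            f"preset: {config.preset_name}\n"
            f"conditions: {config.protocol.n_conditions}\n"
            f"contacts: {geometry.n_contacts}\n"
            f"summary rows: {len(summary)}\n"
        )
    return {
        "summary": summary,
        "per_contact": per_contact,
        "wave_conditions": wave_cond,
        "wave_tracks": wave_tracks,
        "fits": fits,
        "tests": tests,
    }
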