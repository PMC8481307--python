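"""Synthetic multi-session cohort generator.

Emulates the statistical structure the fingerprinting analysis relies on,
without any claim of biophysical realism:

* subject-specific band-limited power topographies — per subject, ROI and
  band a log-amplitude ``mu_b + u`` with ``u ~ N(0, sigma_between)``, plus an
  independent per-session drift ``N(0, sigma_within)``;
* subject-specific inter-ROI coupling — shared band-limited latent carriers
  mixed into every ROI with persistent subject-specific weights (plus the
  same session drift), producing stable individual envelope-correlation
  patterns;
* an individual alpha rhythm — the alpha-band carrier is band-passed in a
  narrow +/-1 Hz window around a subject-specific peak frequency;
* additive white sensor noise;
* an "empty-room" analog carrying the cohort's average spectral profile but
  no subject-specific structure;
* demographics linearly coupled to a planted subset of (ROI, band)
  amplitude features, with artifact RMS values independent of identity.

Carriers are white noise shaped by the same FIR filter bank as the analysis
path, so generator and analyzer agree on band definitions by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import BandDefinition, CANONICAL_BANDS, CohortRecording
from .features import bandpass, design_bandpass

__all__ = ["SyntheticConfig", "generate_cohort", "generate_empty_room"]

_SD = Union[float, Sequence[float]]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort; defaults mirror the study conditions
    (68 cortical ROIs, 600 Hz sampling, ~5 min sessions, canonical bands)."""

    n_subjects: int = 20
    n_sessions: int = 2
    n_rois: int = 68
    fs: float = 600.0
    duration: float = 300.0  # seconds per session
    bands: Tuple[BandDefinition, ...] = CANONICAL_BANDS
    sigma_between: _SD = 0.5  # between-subject log-amplitude SD (per band or scalar)
    sigma_within: _SD = 0.1  # between-session log-amplitude SD
    n_latents: int = 5  # shared carriers generating inter-ROI coupling
    coupling_sd: float = 0.5  # SD of subject-specific coupling weights
    noise_sd: float = 0.25  # additive white-noise SD
    alpha_peak_mean: float = 10.0  # Hz
    alpha_peak_sd: float = 1.0  # Hz
    demographic_effect: float = 1.0  # planted linear coupling strength
    n_planted: int = 5  # number of (ROI, band) features driving demographics
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fs", "duration", "coupling_sd", "noise_sd",
            "alpha_peak_mean", "alpha_peak_sd", "demographic_effect",
        ):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite value for field {name!r}: {v}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for b in self.bands:
            if not (b.f_lo < b.f_hi):
                raise ValueError(f"band {b.name!r}: f_lo must be < f_hi")
        for name in ("coupling_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma_between", "sigma_within"):
            arr = self._per_band(getattr(self, name))
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"non-finite value for field {name!r}")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be >= 0")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration * fs must yield an integer sample count")
        if self.n_latents > 0 and not self.bands:
            raise ValueError("n_latents > 0 requires a non-empty band list")

    def _per_band(self, sd: _SD) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(sd, dtype=float))
        if arr.size == 1:
            return np.full(len(self.bands), arr[0])
        if arr.size != len(self.bands):
            raise ValueError("per-band SD length must match the number of bands")
        return arr

    @property
    def n_times(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def mean_log_amplitude(self) -> np.ndarray:
        """Band mean log-amplitudes: coarse high-frequency roll-off with a
        prominent alpha rhythm (no exact 1/f claim)."""
        mu = np.empty(len(self.bands))
        for i, b in enumerate(self.bands):
            amp = b.center ** -0.5
            if b.name == "alpha":
                amp *= 2.0
            mu[i] = np.log(amp)
        return mu


def _unit_carrier(rng: np.random.Generator, n: int, band: BandDefinition, fs: float) -> np.ndarray:
    """Band-limited unit-variance (in expectation) noise carrier.

    Normalized by the filter's theoretical white-noise gain sqrt(sum(h^2)),
    not the realized sample std: realized normalization would couple the
    power of disjoint time segments (their variances must average to one),
    planting a spurious anti-identity signal in split-half analyses.
    """
    x = bandpass(rng.standard_normal(n), band, fs)
    gain = float(np.sqrt(np.sum(design_bandpass(band, fs) ** 2)))
    return x / gain if gain > 0 else x


def _latent_band(cfg: SyntheticConfig, k: int) -> BandDefinition:
    # latent carriers cycle through the band list
    return cfg.bands[k % len(cfg.bands)]


def _coupling_drift_sd(cfg: SyntheticConfig) -> float:
    # session drift on coupling weights scales with the mean within-session
    # amplitude drift, keeping "drift" one knob across both feature families
    return cfg.coupling_sd * float(np.mean(cfg._per_band(cfg.sigma_within)))


def generate_cohort(
    config: SyntheticConfig,
) -> Tuple[CohortRecording, pd.DataFrame, pd.DataFrame]:
    """Simulate (recording, demographics, artifacts) for one cohort.

    Deterministic given (config, seed). The demographics table carries the
    planted-coupling ground truth in ``df.attrs["planted"]`` (feature
    indices/weights in ROI-major (ROI, band) order and the latent score per
    subject) for recovery experiments.
    """
    cfg = config
    n_b = len(cfg.bands)
    sig_b = cfg._per_band(cfg.sigma_between)
    sig_w = cfg._per_band(cfg.sigma_within)
    mu = cfg.mean_log_amplitude
    n_t = cfg.n_times

    root = np.random.SeedSequence(cfg.seed)
    ss_amp, ss_sig, ss_demo, ss_art = root.spawn(4)
    rng_amp = np.random.default_rng(ss_amp)
    rng_sig = np.random.default_rng(ss_sig)

    # subject-level structure (persistent across sessions)
    u = rng_amp.standard_normal((cfg.n_subjects, cfg.n_rois, n_b)) * sig_b  # log-amp
    w = rng_amp.standard_normal((cfg.n_subjects, cfg.n_rois, cfg.n_latents)) * cfg.coupling_sd
    alpha_peak = cfg.alpha_peak_mean + cfg.alpha_peak_sd * rng_amp.standard_normal(cfg.n_subjects)
    # keep the individual alpha window inside (0, Nyquist)
    alpha_peak = np.clip(alpha_peak, 2.0, cfg.fs / 2 - 2.0)
    drift_w_sd = _coupling_drift_sd(cfg)

    data = np.zeros((cfg.n_subjects, cfg.n_sessions, cfg.n_rois, n_t))
    for i in range(cfg.n_subjects):
        for s in range(cfg.n_sessions):
            log_amp = mu + u[i] + rng_sig.standard_normal((cfg.n_rois, n_b)) * sig_w
            amp = np.exp(log_amp)  # (R, B)
            x = np.zeros((cfg.n_rois, n_t))
            for bi, band in enumerate(cfg.bands):
                eff = band
                if band.name == "alpha":
                    pk = float(alpha_peak[i])
                    eff = BandDefinition("alpha", pk - 1.0, pk + 1.0)
                carriers = np.vstack(
                    [_unit_carrier(rng_sig, n_t, eff, cfg.fs) for _ in range(cfg.n_rois)]
                )
                x += amp[:, bi : bi + 1] * carriers
            for k in range(cfg.n_latents):
                latent = _unit_carrier(rng_sig, n_t, _latent_band(cfg, k), cfg.fs)
                wk = w[i, :, k] + drift_w_sd * rng_sig.standard_normal(cfg.n_rois)
                x += wk[:, None] * latent[None, :]
            if cfg.noise_sd > 0:
                x += cfg.noise_sd * rng_sig.standard_normal((cfg.n_rois, n_t))
            data[i, s] = x

    subject_ids = [f"sub{i:03d}" for i in range(cfg.n_subjects)]
    recording = CohortRecording(
        data=data,
        fs=cfg.fs,
        subject_ids=subject_ids,
        session_ids=[f"ses{s}" for s in range(cfg.n_sessions)],
        roi_labels=[f"roi{r:03d}" for r in range(cfg.n_rois)],
    )

    demographics = _generate_demographics(cfg, u, np.random.default_rng(ss_demo), subject_ids)
    artifacts = _generate_artifacts(cfg, np.random.default_rng(ss_art), subject_ids)
    return recording, demographics, artifacts


def _generate_demographics(
    cfg: SyntheticConfig,
    u: np.ndarray,
    rng: np.random.Generator,
    subject_ids: Sequence[str],
) -> pd.DataFrame:
    n = cfg.n_subjects
    n_feat = cfg.n_rois * len(cfg.bands)
    n_planted = min(cfg.n_planted, n_feat)
    planted_idx = np.sort(rng.choice(n_feat, size=n_planted, replace=False))
    weights = rng.standard_normal(n_planted)
    weights /= np.linalg.norm(weights)

    flat_u = u.reshape(n, n_feat)  # ROI-major (ROI, band) order
    z = flat_u[:, planted_idx] @ weights
    zsd = z.std(ddof=1)
    z = (z - z.mean()) / zsd if zsd > 0 else np.zeros(n)

    eff = cfg.demographic_effect
    scale = math.sqrt(eff**2 + 1.0)
    age_score = (eff * z + rng.standard_normal(n)) / scale
    clin_score = (eff * z + rng.standard_normal(n)) / scale
    age = np.clip(np.round(45.0 + 13.0 * age_score), 18, 73).astype(int)
    clinical = (clin_score > np.median(clin_score)).astype(int)
    sex = rng.integers(0, 2, size=n)
    handedness = rng.integers(0, 2, size=n)

    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "handedness": handedness,
            "clinical_status": clinical,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    band_names = [b.name for b in cfg.bands]
    df.attrs["planted"] = {
        "feature_indices": planted_idx.tolist(),  # into ROI-major (ROI, band) vector
        "feature_labels": [
            f"roi{idx // len(cfg.bands):03d}/{band_names[idx % len(cfg.bands)]}"
            for idx in planted_idx
        ],
        "weights": weights.tolist(),
        "latent": z.tolist(),
        "coupled_columns": ["age", "clinical_status"],
    }
    return df


def _generate_artifacts(
    cfg: SyntheticConfig, rng: np.random.Generator, subject_ids: Sequence[str]
) -> pd.DataFrame:
    n = cfg.n_subjects
    return pd.DataFrame(
        {
            "rms_cardiac": rng.lognormal(0.0, 0.3, size=n),
            "rms_ocular": rng.lognormal(0.0, 0.3, size=n),
            "rms_motion": rng.lognormal(0.0, 0.3, size=n),
            "scan_duration": cfg.duration * rng.uniform(0.92, 1.0, size=n),
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )


def generate_empty_room(config: SyntheticConfig) -> CohortRecording:
    """One no-subject pseudo-recording per subject-session slot.

    Every pseudo-recording carries the same deterministic band-amplitude
    profile, chosen so its expected PSD equals the cohort's mean PSD:
    amplitude ``exp(mu_b + sigma_between^2 + sigma_within^2)`` matches the
    log-normal power mean, and latent-coupling power is folded in as
    ``n_latents_b * coupling_sd^2`` per band. No per-recording random
    structure persists, so no identity signal exists.
    """
    cfg = config
    n_b = len(cfg.bands)
    sig_b = cfg._per_band(cfg.sigma_between)
    sig_w = cfg._per_band(cfg.sigma_within)
    mu = cfg.mean_log_amplitude
    n_t = cfg.n_times

    # expected per-band power for a cohort ROI signal
    band_power = np.exp(2 * mu + 2 * sig_b**2 + 2 * sig_w**2)
    if n_b:
        n_latents_per_band = np.zeros(n_b)
        for k in range(cfg.n_latents):
            n_latents_per_band[k % n_b] += 1
        band_power += n_latents_per_band * cfg.coupling_sd**2
    amp = np.sqrt(band_power)

    root = np.random.SeedSequence(cfg.seed)
    # distinct stream from generate_cohort's four spawns
    rng = np.random.default_rng(root.spawn(5)[4])

    data = np.zeros((cfg.n_subjects, cfg.n_sessions, cfg.n_rois, n_t))
    for i in range(cfg.n_subjects):
        for s in range(cfg.n_sessions):
            x = np.zeros((cfg.n_rois, n_t))
            for bi, band in enumerate(cfg.bands):
                eff = band
                if band.name == "alpha":
                    # cohort-average alpha rhythm: narrow carrier at the
                    # population mean peak (no subject specificity)
                    pk = float(np.clip(cfg.alpha_peak_mean, 2.0, cfg.fs / 2 - 2.0))
                    eff = BandDefinition("alpha", pk - 1.0, pk + 1.0)
                carriers = np.vstack(
                    [_unit_carrier(rng, n_t, eff, cfg.fs) for _ in range(cfg.n_rois)]
                )
                x += amp[bi] * carriers
            if cfg.noise_sd > 0:
                x += cfg.noise_sd * rng.standard_normal((cfg.n_rois, n_t))
            data[i, s] = x

    return CohortRecording(
        data=data,
        fs=cfg.fs,
        subject_ids=[f"sub{i:03d}" for i in range(cfg.n_subjects)],
        session_ids=[f"ses{s}" for s in range(cfg.n_sessions)],
        roi_labels=[f"roi{r:03d}" for r in range(cfg.n_rois)],
    )
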