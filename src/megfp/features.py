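"""Feature extraction: band-pass filter bank, Hilbert envelopes, AEC
connectomes, Welch PSD profiles, vectorization and dataset segmentation.

Two feature families are produced per subject and dataset:

* connectome features — band-limited amplitude envelope correlation (AEC):
  each ROI signal is band-passed, Hilbert-transformed, and the Pearson
  correlation between every pair of envelope magnitudes forms a symmetric
  R x R matrix whose upper triangle is the feature vector;
* spectral features — Welch power spectral densities per ROI (2 s windows,
  50% overlap, 0-150 Hz at 0.5 Hz resolution), concatenated across ROIs.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .containers import (
    BandDefinition,
    CohortRecording,
    Connectome,
    FeatureMatrix,
    PsdProfile,
)

__all__ = [
    "design_bandpass",
    "bandpass",
    "envelope",
    "aec_connectome",
    "welch_psd",
    "band_power",
    "vectorize",
    "edge_labels",
    "segment",
    "extract_features",
]


def _transition_width(band: BandDefinition) -> float:
    # narrow transition for low bands, capped at 2 Hz for sharpness near
    # adjacent band edges (e.g. 10 Hz must be >=40 dB down in the beta band)
    return min(2.0, max(0.5, 0.5 * band.f_lo))


def design_bandpass(band: BandDefinition, fs: float) -> np.ndarray:
    """Symmetric (linear-phase) FIR band-pass taps for one band.

    Hamming-window design: ~53 dB stop-band attenuation, <0.1 dB pass-band
    ripple. The taps are symmetric, so a centred single-pass application is
    exactly zero-phase.
    """
    if band.f_hi >= fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_hi} Hz reaches or exceeds "
            f"Nyquist ({fs / 2} Hz)"
        )
    width = _transition_width(band)
    numtaps = int(np.ceil(3.3 * fs / width))
    numtaps += 1 - numtaps % 2  # odd => exactly symmetric around one tap
    return sps.firwin(numtaps, [band.f_lo, band.f_hi], pass_zero=False, fs=fs, window="hamming")


def bandpass(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis; output length equals input.

    Edge transients are suppressed by odd-reflection padding of half the
    filter length on each side before centred FFT convolution.
    """
    x = np.asarray(x, dtype=float)
    taps = design_bandpass(band, fs)
    half = taps.size // 2
    if x.shape[-1] <= taps.size:
        raise ValueError(
            f"signal too short for band {band.name!r}: {x.shape[-1]} samples "
            f"<= {taps.size} filter taps"
        )
    pad = [(0, 0)] * (x.ndim - 1) + [(half, half)]
    xp = np.pad(x, pad, mode="reflect", reflect_type="odd")
    shape = [1] * (x.ndim - 1) + [taps.size]
    y = sps.fftconvolve(xp, taps.reshape(shape), mode="same", axes=-1)
    return y[..., half : half + x.shape[-1]]


def envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert envelope), last axis = time."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("envelope input contains non-finite samples")
    return np.abs(sps.hilbert(x, axis=-1))


def _orthogonalize(y: np.ndarray, ref: np.ndarray) -> np.ndarray:
    # remove the component of y collinear with ref (time-domain leakage proxy)
    denom = float(ref @ ref)
    if denom == 0.0:
        return y
    return y - (float(y @ ref) / denom) * ref


def aec_connectome(
    roi_ts: np.ndarray,
    band: Optional[BandDefinition],
    fs: float,
    orthogonalize: bool = False,
) -> Connectome:
    """Amplitude envelope correlation between every ROI pair.

    Parameters
    ----------
    roi_ts : (R, T) array
        One timeseries per ROI.
    band : BandDefinition or None
        Band-pass before envelope extraction; None means broadband (no
        filtering).
    orthogonalize : bool
        Pairwise signal orthogonalization before envelope extraction
        (leakage-corrected AEC variant); both regression directions are
        averaged. Off by default.

    Zero-variance envelopes make the affected correlations undefined; they
    are reported as NaN with a warning, never silently zero.
    """
    roi_ts = np.atleast_2d(np.asarray(roi_ts, dtype=float))
    n_roi = roi_ts.shape[0]
    if n_roi < 2:
        raise ValueError("AEC needs at least 2 ROIs")
    filtered = bandpass(roi_ts, band, fs) if band is not None else roi_ts

    if not orthogonalize:
        env = envelope(filtered)
        sd = env.std(axis=-1)
        bad = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(env)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} ROI(s) with constant envelope; their AEC "
                "entries are undefined (NaN)"
            )
            c[bad, :] = np.nan
            c[:, bad] = np.nan
        np.fill_diagonal(c, 1.0)
    else:
        c = np.eye(n_roi)
        for i in range(n_roi):
            for j in range(i + 1, n_roi):
                ei = envelope(_orthogonalize(filtered[i], filtered[j]))
                ej = envelope(_orthogonalize(filtered[j], filtered[i]))
                e0 = envelope(filtered[i])
                e1 = envelope(filtered[j])
                if min(e0.std(), e1.std(), ei.std(), ej.std()) == 0:
                    warnings.warn(f"constant envelope for ROI pair ({i}, {j}); AEC undefined")
                    c[i, j] = c[j, i] = np.nan
                    continue
                r_ij = np.corrcoef(e0, ej)[0, 1]
                r_ji = np.corrcoef(e1, ei)[0, 1]
                c[i, j] = c[j, i] = 0.5 * (r_ij + r_ji)

    roi_labels = [f"roi{r:03d}" for r in range(n_roi)]
    return Connectome(values=c, roi_labels=roi_labels, band=band)


def welch_psd(
    roi_ts: np.ndarray,
    fs: float,
    fmax: Optional[float] = 150.0,
) -> PsdProfile:
    """Welch PSD per ROI: Hann windows of 2 s, 50% overlap, one-sided.

    The grid step is 1/(2 s) = 0.5 Hz; frequencies are reported up to
    ``fmax`` (default 150 Hz) or Nyquist, whichever is lower. Pass
    ``fmax=None`` for the full one-sided grid (useful for Parseval-style
    power accounting).
    """
    roi_ts = np.atleast_2d(np.asarray(roi_ts, dtype=float))
    nperseg = int(round(2.0 * fs))
    if roi_ts.shape[-1] < nperseg:
        raise ValueError(
            f"recording too short for Welch estimation: {roi_ts.shape[-1]} "
            f"samples < one 2 s window ({nperseg} samples)"
        )
    freqs, psd = sps.welch(
        roi_ts, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    if fmax is not None:
        keep = freqs <= fmax + 1e-9
        freqs, psd = freqs[keep], psd[..., keep]
    roi_labels = [f"roi{r:03d}" for r in range(roi_ts.shape[0])]
    return PsdProfile(values=psd, freqs=freqs, roi_labels=roi_labels)


def _band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.f_lo - 1e-9) & (freqs <= band.f_hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band.name!r} has no bins on the frequency grid")
    return mask


def band_power(
    psd: PsdProfile, bands: Sequence[BandDefinition], log: bool = True
) -> Tuple[np.ndarray, List[str]]:
    """Integrated power per (ROI, band); ROI-major order.

    Returns the flat vector and matching labels ``roi/band``. ``log`` applies
    log10 after integration (floor 1e-300 guards all-zero signals).
    """
    vals = []
    labels = []
    df = float(np.median(np.diff(psd.freqs)))
    for r, roi in enumerate(psd.roi_labels):
        for band in bands:
            mask = _band_bins(psd.freqs, band)
            p = float(psd.values[r, mask].sum() * df)
            vals.append(np.log10(max(p, 1e-300)) if log else p)
            labels.append(f"{roi}/{band.name}")
    return np.asarray(vals), labels


def edge_labels(roi_labels: Sequence[str]) -> List[str]:
    """Lexicographic (i < j) upper-triangle edge labels, row-major order."""
    return [
        f"{roi_labels[i]}--{roi_labels[j]}"
        for i in range(len(roi_labels))
        for j in range(i + 1, len(roi_labels))
    ]


def vectorize(
    features, band: Optional[BandDefinition] = None
) -> Tuple[np.ndarray, List[str]]:
    """Flatten a Connectome or PsdProfile into one feature-vector row.

    Connectome -> upper triangle excluding the diagonal in row-major
    (lexicographic i < j) order, length R(R-1)/2. PsdProfile -> per-ROI PSD
    bins concatenated ROI-major; with ``band`` given, only that band's bins.
    """
    if isinstance(features, Connectome):
        r = features.values.shape[0]
        iu = np.triu_indices(r, k=1)
        return features.values[iu], edge_labels(features.roi_labels)
    if isinstance(features, PsdProfile):
        freqs = features.freqs
        mask = _band_bins(freqs, band) if band is not None else np.ones_like(freqs, bool)
        vals = features.values[:, mask].ravel()
        labels = [
            f"{roi}/{f:g}Hz" for roi in features.roi_labels for f in freqs[mask]
        ]
        return vals, labels
    raise TypeError(f"cannot vectorize {type(features).__name__}")


def unvectorize_connectome(vec: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of connectome vectorization: rebuild the symmetric matrix."""
    m = np.eye(n_rois)
    iu = np.triu_indices(n_rois, k=1)
    m[iu] = vec
    m[(iu[1], iu[0])] = vec
    return m


def segment(recording: CohortRecording, scheme: str) -> Dict[str, CohortRecording]:
    """Split a recording into the datasets of a differentiation challenge.

    Schemes
    -------
    ``sessions``      one full dataset per session (keys ``ses{i}/full``)
    ``within_halves`` two equal non-overlapping halves per session
                      (keys ``ses{i}/half{1,2}``)
    ``segments_30s``  three non-overlapping 30 s segments per session taken
                      from the start, leftover discarded
                      (keys ``ses{i}/seg{1,2,3}``)
    """
    out: Dict[str, CohortRecording] = {}
    n = recording.n_times
    if scheme == "sessions":
        for s in range(recording.n_sessions):
            out[f"ses{s}/full"] = recording.select_session(s)
        return out
    if scheme == "within_halves":
        half = n // 2
        for s in range(recording.n_sessions):
            ses = recording.select_session(s)
            out[f"ses{s}/half1"] = ses.slice_time(0, half)
            out[f"ses{s}/half2"] = ses.slice_time(half, 2 * half)
        return out
    if scheme == "segments_30s":
        seg = int(round(30.0 * recording.fs))
        if n < 3 * seg:
            raise ValueError(
                f"scheme 'segments_30s' needs >= {3 * seg / recording.fs:.0f} s "
                f"per session, recording has {recording.duration:.0f} s"
            )
        for s in range(recording.n_sessions):
            ses = recording.select_session(s)
            for k in range(3):
                out[f"ses{s}/seg{k + 1}"] = ses.slice_time(k * seg, (k + 1) * seg)
        return out
    raise ValueError(f"unknown segmentation scheme {scheme!r}")


def extract_features(
    dataset: CohortRecording,
    kind: str,
    band: Optional[BandDefinition] = None,
    orthogonalize: bool = False,
    log_psd: bool = False,
    dataset_id: str = "",
) -> FeatureMatrix:
    """Per-subject feature vectors for one dataset (single-session slice).

    kind ``connectome`` -> vectorized band-limited AEC matrix; kind
    ``spectral`` -> vectorized PSD profile (band-restricted bins when a band
    is given; raw power per Hz, or log10 with ``log_psd``).
    """
    if dataset.n_sessions != 1:
        raise ValueError("extract_features expects a single-session dataset slice")
    rows = []
    labels: List[str] = []
    for i in range(dataset.n_subjects):
        ts = dataset.data[i, 0]
        if kind == "connectome":
            vec, labels = vectorize(aec_connectome(ts, band, dataset.fs, orthogonalize))
        elif kind == "spectral":
            psd = welch_psd(ts, dataset.fs)
            if log_psd:
                psd.values = np.log10(np.maximum(psd.values, 1e-300))
            vec, labels = vectorize(psd, band)
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
        rows.append(vec)
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_labels=labels,
        subject_ids=list(dataset.subject_ids),
        dataset_id=dataset_id,
    )
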