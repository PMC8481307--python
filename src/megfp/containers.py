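"""Shared in-memory containers for cohort recordings and derived features.

The analysis operates on a fixed progression of objects: a
:class:`CohortRecording` (subject x session x ROI x time array of
source-localised electrophysiological signals), per-dataset
:class:`FeatureMatrix` objects (one feature vector per subject), and the
asymmetric :class:`SimilarityMatrix` relating two datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: Canonical neurophysiological band set.
CANONICAL_BANDS: Tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
    BandDefinition("high_gamma", 50.0, 150.0),
)


def band_by_name(name: str, bands: Sequence[BandDefinition] = CANONICAL_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


@dataclass
class CohortRecording:
    """Multi-subject, multi-session ROI timeseries.

    data has shape (n_subjects, n_sessions, n_rois, n_times); fs is the
    sampling rate in Hz. Arbitrary signal units.
    """

    data: np.ndarray
    fs: float
    subject_ids: Sequence[str]
    session_ids: Sequence[str]
    roi_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-d (subject, session, roi, time), got {self.data.shape}")
        n_sub, n_ses, n_roi, _ = self.data.shape
        if len(self.subject_ids) != n_sub:
            raise ValueError("subject_ids length mismatch")
        if len(self.session_ids) != n_ses:
            raise ValueError("session_ids length mismatch")
        if len(self.roi_labels) != n_roi:
            raise ValueError("roi_labels length mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.data.shape[1]

    @property
    def n_rois(self) -> int:
        return self.data.shape[2]

    @property
    def n_times(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def select_session(self, index: int) -> "CohortRecording":
        """A copy restricted to one session (session axis kept, length 1)."""
        return replace(
            self,
            data=self.data[:, index : index + 1],
            session_ids=[self.session_ids[index]],
        )

    def slice_time(self, start: int, stop: int) -> "CohortRecording":
        return replace(self, data=self.data[..., start:stop])


@dataclass
class Connectome:
    """Symmetric ROI x ROI amplitude-envelope-correlation matrix."""

    values: np.ndarray
    roi_labels: Sequence[str]
    band: Optional[BandDefinition] = None  # None => broadband

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = len(self.roi_labels)
        if self.values.shape != (r, r):
            raise ValueError("connectome shape must be (R, R)")


@dataclass
class PsdProfile:
    """Per-ROI Welch power spectral densities (power per Hz) on a common grid."""

    values: np.ndarray  # (R, F), >= 0 where defined
    freqs: np.ndarray  # Hz, strictly increasing
    roi_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.freqs.size:
            raise ValueError("values must be (R, F) matching freqs")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class FeatureMatrix:
    """One feature vector per subject for one dataset."""

    values: np.ndarray  # (n_subjects, n_features)
    feature_labels: Sequence[str]
    subject_ids: Sequence[str]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-d (subject x feature)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("one row per subject required")
        if self.values.shape[1] != len(self.feature_labels):
            raise ValueError("one label per feature required")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityMatrix:
    """Asymmetric subject x subject Pearson-correlation matrix between two datasets.

    Entry (i, j) correlates subject i's feature vector from dataset 1 with
    subject j's from dataset 2. NaN marks undefined (zero-variance) entries.
    """

    values: np.ndarray
    subject_ids: Sequence[str]
    dataset_pair: Tuple[str, str] = ("dataset1", "dataset2")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over subjects")
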