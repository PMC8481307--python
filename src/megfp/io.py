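"""File formats: HDF5 recordings, CSV tables and feature matrices."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .containers import CohortRecording, FeatureMatrix

__all__ = [
    "save_recording",
    "load_recording",
    "save_feature_matrix",
    "load_feature_matrix",
]

PathLike = Union[str, Path]


def save_recording(recording: CohortRecording, path: PathLike) -> None:
    """One HDF5 dataset per subject/session under sub-XXX/ses-YYY, with fs
    and labels stored as root attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = recording.fs
        f.attrs["subject_ids"] = list(recording.subject_ids)
        f.attrs["session_ids"] = list(recording.session_ids)
        f.attrs["roi_labels"] = list(recording.roi_labels)
        for i, sub in enumerate(recording.subject_ids):
            for s, ses in enumerate(recording.session_ids):
                f.create_dataset(f"{sub}/{ses}", data=recording.data[i, s])


def load_recording(path: PathLike) -> CohortRecording:
    with h5py.File(path, "r") as f:
        subject_ids = [str(s) for s in f.attrs["subject_ids"]]
        session_ids = [str(s) for s in f.attrs["session_ids"]]
        roi_labels = [str(s) for s in f.attrs["roi_labels"]]
        data = np.stack(
            [
                np.stack([f[f"{sub}/{ses}"][()] for ses in session_ids])
                for sub in subject_ids
            ]
        )
        return CohortRecording(
            data=data,
            fs=float(f.attrs["fs"]),
            subject_ids=subject_ids,
            session_ids=session_ids,
            roi_labels=roi_labels,
        )


def save_feature_matrix(fm: FeatureMatrix, path: PathLike) -> None:
    df = pd.DataFrame(
        fm.values,
        index=pd.Index(list(fm.subject_ids), name="subject_id"),
        columns=list(fm.feature_labels),
    )
    df.to_csv(path)


def load_feature_matrix(path: PathLike, dataset_id: str = "") -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    return FeatureMatrix(
        values=df.to_numpy(float),
        feature_labels=[str(c) for c in df.columns],
        subject_ids=[str(i) for i in df.index],
        dataset_id=dataset_id or Path(path).stem,
    )
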