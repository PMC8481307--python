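"""Feature-level contribution metrics across two datasets of one cohort.

Three edgewise measures quantify what each feature (a connectome edge or a
ROI x frequency power bin) contributes to telling individuals apart:

* ICC — one-way random-effects intraclass correlation, ICC(1,1), with
  subjects as targets and the two datasets as the k = 2 repeated measures:
  ICC = (MSB - MSW) / (MSB + (k - 1) MSW). High ICC = the feature is stable
  within individuals relative to the cohort spread.
* group consistency Phi(e) — after normalizing each subject's feature
  vector to unit Euclidean norm in each dataset, the mean over subjects of
  the product phi1_i(e) * phi2_i(e): cohort-wide stability of a feature.
* differential power DP(e) — for each subject the empirical probability
  that a cross-subject product beats the within-subject product; low
  probabilities mean the feature separates that subject from everyone else,
  and DP(e) = sum_i -ln P_i(e) aggregates them.
"""

from __future__ import annotations

import warnings
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

__all__ = [
    "icc_per_feature",
    "group_consistency",
    "differential_power",
    "reliability_table",
]

ArrayLike = Union[np.ndarray, FeatureMatrix]


def _values(F: ArrayLike) -> np.ndarray:
    return F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)


def _paired(F1: ArrayLike, F2: ArrayLike) -> Tuple[np.ndarray, np.ndarray]:
    x1, x2 = _values(F1), _values(F2)
    if x1.shape != x2.shape:
        raise ValueError("datasets must have matching (subject x feature) shapes")
    if isinstance(F1, FeatureMatrix) and isinstance(F2, FeatureMatrix):
        if list(F1.subject_ids) != list(F2.subject_ids):
            raise ValueError("datasets must cover the same subjects in the same order")
    return x1, x2


def icc_per_feature(F1: ArrayLike, F2: ArrayLike) -> np.ndarray:
    """ICC(1,1) per feature from the one-way ANOVA decomposition (k = 2).

    Zero total variance for a feature leaves its ICC undefined (NaN, with a
    warning).
    """
    x1, x2 = _paired(F1, F2)
    n = x1.shape[0]
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    k = 2
    x = np.stack([x1, x2])  # (k, n, features)
    grand = x.mean(axis=(0, 1))
    subj_mean = x.mean(axis=0)  # (n, features)
    ssb = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ssw = ((x - subj_mean) ** 2).sum(axis=(0, 1))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    undefined = denom == 0
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} feature(s) with zero total variance; ICC undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(undefined, np.nan, (msb - msw) / np.where(undefined, 1.0, denom))
    return icc


def _unit_rows(x: np.ndarray, label: str) -> Tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(x, axis=1)
    bad = norms == 0
    if bad.any():
        warnings.warn(f"{label}: {int(bad.sum())} zero-norm subject vector(s) excluded")
    safe = np.where(bad, 1.0, norms)
    return x / safe[:, None], bad


def _normalized_pair(F1: ArrayLike, F2: ArrayLike) -> Tuple[np.ndarray, np.ndarray]:
    x1, x2 = _paired(F1, F2)
    p1, bad1 = _unit_rows(x1, "dataset 1")
    p2, bad2 = _unit_rows(x2, "dataset 2")
    keep = ~(bad1 | bad2)
    return p1[keep], p2[keep]


def group_consistency(F1: ArrayLike, F2: ArrayLike) -> np.ndarray:
    """Phi(e) = mean over subjects of phi1_i(e) * phi2_i(e) on unit-norm rows."""
    p1, p2 = _normalized_pair(F1, F2)
    if p1.shape[0] == 0:
        raise ValueError("no subjects with nonzero feature vectors")
    return (p1 * p2).mean(axis=0)


def differential_power(F1: ArrayLike, F2: ArrayLike) -> np.ndarray:
    """DP(e) = sum_i -ln P_i(e) on unit-norm rows.

    P_i(e) is the fraction of other subjects j for which
    phi1_i(e) phi2_j(e) > phi1_i(e) phi2_i(e) or
    phi1_j(e) phi2_i(e) > phi1_i(e) phi2_i(e), clipped below at
    1/(2(N-1)) so the logarithm stays finite.
    """
    p1, p2 = _normalized_pair(F1, F2)
    n = p1.shape[0]
    if n < 3:
        raise ValueError("differential power needs at least 3 subjects")
    floor = 1.0 / (2 * (n - 1))
    within = p1 * p2  # (n, E)
    dp = np.zeros(p1.shape[1])
    for i in range(n):
        others = np.delete(np.arange(n), i)
        # (n-1, E): cross products in both pairing directions
        beat = (p1[i][None, :] * p2[others] > within[i][None, :]) | (
            p1[others] * p2[i][None, :] > within[i][None, :]
        )
        p = beat.mean(axis=0)
        dp += -np.log(np.clip(p, floor, None))
    return dp


def reliability_table(F1: FeatureMatrix, F2: FeatureMatrix) -> pd.DataFrame:
    """All three metrics per feature, indexed by feature label."""
    return pd.DataFrame(
        {
            "icc": icc_per_feature(F1, F2),
            "group_consistency": group_consistency(F1, F2),
            "differential_power": differential_power(F1, F2),
        },
        index=pd.Index(list(F1.feature_labels), name="feature"),
    )
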