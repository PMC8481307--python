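"""Confound correlations and PLS correlation analysis.

The PLS ("partial least squares correlation") relates a demographic matrix
X (subjects x demographic variables) to a neural feature matrix Y
(subjects x features). Both blocks are column z-scored; the cross-block
correlation R = X'Y / (n - 1) is decomposed by SVD, R = U S V'. Each latent
variable (LV) pairs a demographic salience (column of U) with a neural
salience (column of V) and a singular value measuring the covariance it
captures. Significance comes from permuting the rows of X (null: no
X-Y relationship); stability from bootstrap resampling of subjects, with
Procrustes alignment of each resample's saliences to the original before
standard errors are taken. The bootstrap ratio of a neural weight is its
original salience divided by its bootstrap standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import FeatureMatrix

__all__ = [
    "confound_correlations",
    "pls_fit",
    "pls_permutation",
    "pls_bootstrap",
    "demographics_matrix",
    "PLSResult",
]

_BOOT_RATIO_CAP = 1e6


def confound_correlations(
    scores: Union[pd.Series, pd.DataFrame],
    confounds: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r and two-sided p between each score and each confound.

    p-values use the t-distribution with n - 2 degrees of freedom; no
    multiple-comparison correction. Pairs with zero variance on either side
    are reported with NaN r/p rather than dropped.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame(scores.name or "score")
    rows = []
    for score_name in scores.columns:
        for conf_name in confounds.columns:
            pair = pd.concat(
                [scores[score_name], confounds[conf_name]], axis=1, join="inner"
            ).dropna()
            n = len(pair)
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if n < 3 or x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"correlation ({score_name}, {conf_name}) undefined "
                    f"(n={n} or zero variance)"
                )
                rows.append((score_name, conf_name, np.nan, np.nan, n))
                continue
            r, p = sstats.pearsonr(x, y)
            rows.append((score_name, conf_name, float(r), float(p), n))
    return pd.DataFrame(rows, columns=["score", "confound", "r", "p", "n"])


def demographics_matrix(demographics: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    """Numeric demographic block: binary columns become centered +/-0.5 codes,
    continuous columns pass through (z-scoring happens inside pls_fit)."""
    cols = []
    names = []
    for name in demographics.columns:
        col = demographics[name].to_numpy(float)
        uniq = np.unique(col)
        if uniq.size == 2:
            col = np.where(col == uniq.max(), 0.5, -0.5)
        cols.append(col)
        names.append(str(name))
    return np.column_stack(cols), names


@dataclass
class PLSResult:
    singular_values: np.ndarray  # (L,), descending
    demographic_saliences: np.ndarray  # (n_demo, L)
    neural_saliences: np.ndarray  # (n_features, L)
    x_scores: np.ndarray  # (n, L)
    y_scores: np.ndarray  # (n, L)
    demographic_names: List[str] = field(default_factory=list)
    feature_labels: List[str] = field(default_factory=list)
    p_perm: Optional[np.ndarray] = None
    bootstrap_ratio: Optional[np.ndarray] = None  # (n_features, L)
    ci95: Optional[np.ndarray] = None  # (n_demo, L, 2)
    n_boot_dropped: int = 0


def _zscore_columns(m: np.ndarray, what: str, names: Optional[Sequence[str]] = None) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    sd = m.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        which = (
            [names[i] for i in np.flatnonzero(const)] if names is not None
            else np.flatnonzero(const).tolist()
        )
        raise ValueError(f"constant column(s) in {what}: {which}")
    return (m - m.mean(axis=0)) / sd


def _as_blocks(
    X: Union[np.ndarray, pd.DataFrame],
    Y: Union[np.ndarray, FeatureMatrix],
) -> Tuple[np.ndarray, List[str], np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        x, x_names = demographics_matrix(X)
    else:
        x = np.atleast_2d(np.asarray(X, dtype=float))
        x = x.T if x.shape[0] == 1 else x
        x_names = [f"x{j}" for j in range(x.shape[1])]
    if isinstance(Y, FeatureMatrix):
        y, y_names = Y.values, list(Y.feature_labels)
    else:
        y = np.atleast_2d(np.asarray(Y, dtype=float))
        y = y.T if y.shape[0] == 1 else y
        y_names = [f"y{j}" for j in range(y.shape[1])]
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must describe the same subjects")
    return x, x_names, y, y_names


def pls_fit(
    X: Union[np.ndarray, pd.DataFrame],
    Y: Union[np.ndarray, FeatureMatrix],
) -> PLSResult:
    """Correlation-mode PLS: SVD of the z-scored cross-block matrix."""
    x, x_names, y, y_names = _as_blocks(X, Y)
    n = x.shape[0]
    xz = _zscore_columns(x, "X", x_names)
    yz = _zscore_columns(y, "Y", y_names)
    r = xz.T @ yz / (n - 1)
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    v = vt.T
    return PLSResult(
        singular_values=s,
        demographic_saliences=u,
        neural_saliences=v,
        x_scores=xz @ u,
        y_scores=yz @ v,
        demographic_names=x_names,
        feature_labels=y_names,
    )


def pls_permutation(
    X: Union[np.ndarray, pd.DataFrame],
    Y: Union[np.ndarray, FeatureMatrix],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Permutation p-value per LV.

    Each permutation shuffles the rows of the demographic block and refits;
    p_k = (1 + #{permuted S_k >= observed S_k}) / (n_perm + 1). The add-one
    form keeps p strictly positive.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, x_names, y, _ = _as_blocks(X, Y)
    n = x.shape[0]
    xz = _zscore_columns(x, "X", x_names)
    yz = _zscore_columns(y, "Y")
    s_obs = np.linalg.svd(xz.T @ yz / (n - 1), compute_uv=False)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s_perm = np.linalg.svd(xz[perm].T @ yz / (n - 1), compute_uv=False)
        exceed += s_perm >= s_obs
    return (1.0 + exceed) / (n_perm + 1.0)


def _procrustes_rotation(u_orig: np.ndarray, u_boot: np.ndarray) -> np.ndarray:
    """Orthogonal rotation Q minimizing ||u_orig - u_boot @ Q||_F."""
    p, _, qt = np.linalg.svd(u_boot.T @ u_orig)
    return p @ qt


def pls_bootstrap(
    X: Union[np.ndarray, pd.DataFrame],
    Y: Union[np.ndarray, FeatureMatrix],
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    fit: Optional[PLSResult] = None,
) -> PLSResult:
    """Bootstrap ratios for neural saliences and 95% CIs for demographic ones.

    Subjects are resampled with replacement; each resample's saliences are
    aligned to the original by a Procrustes rotation (sign/order
    indeterminacy of the SVD) before standard errors are estimated.
    Resamples with a constant column are dropped and counted. Near-zero
    bootstrap SEs (degenerate deterministic links) are capped: the ratio is
    reported at +/-1e6 with a warning.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    res = fit if fit is not None else pls_fit(X, Y)
    x, x_names, y, _ = _as_blocks(X, Y)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    u_samples = []
    v_samples = []
    dropped = 0
    while len(u_samples) < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            boot = pls_fit(x[idx], y[idx])
        except ValueError:
            dropped += 1
            if dropped > 10 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        q = _procrustes_rotation(res.demographic_saliences, boot.demographic_saliences)
        u_samples.append(boot.demographic_saliences @ q)
        v_samples.append(boot.neural_saliences @ q)
    u_arr = np.stack(u_samples)  # (n_boot, n_demo, L)
    v_arr = np.stack(v_samples)  # (n_boot, n_features, L)
    v_se = v_arr.std(axis=0, ddof=1)
    tiny = v_se < 1e-12
    if tiny.any():
        warnings.warn(
            f"{int(tiny.sum())} neural weight(s) with ~zero bootstrap SE; "
            f"ratios capped at +/-{_BOOT_RATIO_CAP:g}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = res.neural_saliences / v_se
    ratio = np.where(
        tiny, np.sign(res.neural_saliences) * _BOOT_RATIO_CAP, ratio
    )
    ci = np.stack(
        [np.percentile(u_arr, 2.5, axis=0), np.percentile(u_arr, 97.5, axis=0)],
        axis=-1,
    )
    res.bootstrap_ratio = ratio
    res.ci95 = ci
    res.n_boot_dropped = dropped
    return res
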