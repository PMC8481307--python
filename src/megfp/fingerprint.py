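"""Correlational identification ("fingerprinting") and differentiability.

Given two feature datasets over the same cohort, a probe subject from one
dataset is matched to the cohort member of the other dataset whose feature
vector correlates most strongly with the probe; the fraction of subjects
matched to themselves is the differentiation accuracy. Per-participant
differentiability D_self(i) is the z-score of the self-correlation A[i, i]
relative to subject i's correlations with everyone else.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, SimilarityMatrix

__all__ = [
    "similarity",
    "identify",
    "differentiability",
    "run_challenge",
    "challenge_pairs",
    "FingerprintResult",
    "ChallengeResult",
]

logger = logging.getLogger(__name__)


@dataclass
class FingerprintResult:
    """Identification outcome for one similarity matrix and probe direction."""

    predicted_id: List[Optional[str]]
    correct: np.ndarray  # bool per identifiable subject position, NaN-safe
    accuracy: float
    direction: str  # "rows": probe = dataset-1 vectors; "columns": dataset-2
    n_ties: int = 0
    unidentifiable: List[str] = field(default_factory=list)


@dataclass
class PairResult:
    pair: Tuple[str, str]
    by_direction: Dict[str, FingerprintResult]
    dself: pd.DataFrame
    similarity: SimilarityMatrix


@dataclass
class ChallengeResult:
    challenge: str
    pairs: List[PairResult]

    def accuracies(self, direction: str = "rows") -> List[float]:
        return [p.by_direction[direction].accuracy for p in self.pairs]

    def mean_accuracy(self, direction: str = "rows") -> float:
        return float(np.mean(self.accuracies(direction)))


def _row_normalize(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = norms == 0
    safe = np.where(bad, 1.0, norms)
    return centered / safe[:, None], bad


def similarity(F1: FeatureMatrix, F2: FeatureMatrix) -> SimilarityMatrix:
    """A[i, j] = Pearson correlation of F1 row i with F2 row j.

    Requires identical subject sets in identical order. Zero-variance rows
    yield undefined (NaN) correlations with a warning.
    """
    if list(F1.subject_ids) != list(F2.subject_ids):
        raise ValueError("feature matrices must cover the same subjects in the same order")
    if F1.n_features != F2.n_features:
        raise ValueError("feature matrices must share one feature space")
    x1, bad1 = _row_normalize(F1.values)
    x2, bad2 = _row_normalize(F2.values)
    a = x1 @ x2.T
    if bad1.any() or bad2.any():
        warnings.warn(
            "zero-variance feature row(s); their correlations are undefined"
        )
        a[bad1, :] = np.nan
        a[:, bad2] = np.nan
    return SimilarityMatrix(
        values=a,
        subject_ids=list(F1.subject_ids),
        dataset_pair=(F1.dataset_id or "dataset1", F2.dataset_id or "dataset2"),
    )


def identify(A: SimilarityMatrix, direction: str = "rows") -> FingerprintResult:
    """Match each probe to its highest-correlation cohort entry.

    direction "rows": probes are dataset-1 subjects, candidates run along
    each row; "columns" swaps the roles. Ties break deterministically toward
    the lowest index (counted). Subjects whose probe vector is entirely
    undefined are marked unidentifiable and excluded from the accuracy
    denominator.
    """
    if direction not in ("rows", "columns"):
        raise ValueError("direction must be 'rows' or 'columns'")
    a = A.values if direction == "rows" else A.values.T
    ids = list(A.subject_ids)
    n = len(ids)
    predicted: List[Optional[str]] = []
    correct = []
    unidentifiable = []
    n_ties = 0
    for i in range(n):
        row = a[i]
        finite = np.isfinite(row)
        if not finite.any():
            predicted.append(None)
            unidentifiable.append(ids[i])
            continue
        best = np.nanmax(row)
        hits = np.flatnonzero(finite & (row == best))
        if hits.size > 1:
            n_ties += 1
        j = int(hits[0])
        predicted.append(ids[j])
        correct.append(j == i)
    correct_arr = np.asarray(correct, dtype=bool)
    accuracy = float(correct_arr.mean()) if correct_arr.size else float("nan")
    if n_ties:
        logger.info("identify: %d tie(s) broken toward the lowest index", n_ties)
    if unidentifiable:
        logger.warning("identify: %d unidentifiable subject(s)", len(unidentifiable))
    return FingerprintResult(
        predicted_id=predicted,
        correct=correct_arr,
        accuracy=accuracy,
        direction=direction,
        n_ties=n_ties,
        unidentifiable=unidentifiable,
    )


def differentiability(
    A: SimilarityMatrix, include_self_in_null: bool = False
) -> pd.DataFrame:
    """Per-subject differentiability D_self(i) = (A[i,i] - mu_i) / sigma_i.

    mu_i and sigma_i are the mean and sample (n-1) standard deviation of
    subject i's row correlations to the *other* cohort members (the
    diagonal term joins the null only with ``include_self_in_null``).
    Returns a DataFrame indexed by subject with columns d_self, corr_self,
    mu_others, sigma_others; sigma_i = 0 or insufficient data yields NaN.
    """
    a = A.values
    n = a.shape[0]
    if n < 3:
        raise ValueError("differentiability needs at least 3 subjects")
    rows = []
    for i in range(n):
        self_corr = a[i, i]
        others = np.delete(a[i], i) if not include_self_in_null else a[i]
        others = others[np.isfinite(others)]
        if others.size < 2 or not np.isfinite(self_corr):
            rows.append((np.nan, self_corr, np.nan, np.nan))
            continue
        mu = others.mean()
        sd = others.std(ddof=1)
        d = (self_corr - mu) / sd if sd > 0 else np.nan
        rows.append((d, self_corr, mu, sd))
    return pd.DataFrame(
        rows,
        columns=["d_self", "corr_self", "mu_others", "sigma_others"],
        index=pd.Index(list(A.subject_ids), name="subject_id"),
    )


def _key_parts(key: str) -> Tuple[str, str]:
    ses, _, part = key.partition("/")
    return ses, part


def challenge_pairs(dataset_ids: Sequence[str], challenge: str) -> List[Tuple[str, str]]:
    """Enumerate the ordered dataset pairs of a differentiation challenge.

    Dataset ids follow the ``ses{i}/{part}`` convention of
    :func:`megfp.features.segment`. ``within``/``within_short`` pair
    datasets inside each session; ``between`` pairs full sessions;
    ``between_short`` pairs every earlier-session segment with every
    later-session segment (3 x 3 = 9 pairs for two sessions of three
    segments). Both probe directions are evaluated downstream, so unordered
    pairs are listed once.
    """
    ids = sorted(dataset_ids)
    sessions: Dict[str, List[str]] = {}
    for d in ids:
        sessions.setdefault(_key_parts(d)[0], []).append(d)
    ses_names = sorted(sessions)
    pairs: List[Tuple[str, str]] = []
    if challenge in ("within", "within_short"):
        for ses in ses_names:
            for a, b in itertools.combinations(sessions[ses], 2):
                pairs.append((a, b))
    elif challenge == "between":
        for sa, sb in itertools.combinations(ses_names, 2):
            full_a = [d for d in sessions[sa] if _key_parts(d)[1] == "full"]
            full_b = [d for d in sessions[sb] if _key_parts(d)[1] == "full"]
            for a in full_a:
                for b in full_b:
                    pairs.append((a, b))
    elif challenge == "between_short":
        for sa, sb in itertools.combinations(ses_names, 2):
            for a in sessions[sa]:
                for b in sessions[sb]:
                    pairs.append((a, b))
    else:
        raise ValueError(f"unknown challenge {challenge!r}")
    if not pairs:
        raise ValueError(f"challenge {challenge!r}: no dataset pairs available")
    return pairs


def run_challenge(
    features_by_dataset: Mapping[str, FeatureMatrix],
    challenge: str,
    include_self_in_null: bool = False,
) -> ChallengeResult:
    """Run similarity -> identify (both directions) -> differentiability over
    every dataset pair of a challenge, aggregating per-pair accuracies.

    Subjects missing from either dataset of a pair are dropped (logged).
    """
    pairs = challenge_pairs(list(features_by_dataset), challenge)
    results = []
    for a, b in pairs:
        f1, f2 = features_by_dataset[a], features_by_dataset[b]
        common = [s for s in f1.subject_ids if s in set(f2.subject_ids)]
        if len(common) < len(f1.subject_ids) or len(common) < len(f2.subject_ids):
            dropped = (set(f1.subject_ids) | set(f2.subject_ids)) - set(common)
            logger.warning(
                "pair (%s, %s): dropping %d subject(s) without both datasets: %s",
                a, b, len(dropped), sorted(dropped),
            )
            f1 = _subset(f1, common)
            f2 = _subset(f2, common)
        elif list(f1.subject_ids) != list(f2.subject_ids):
            f2 = _subset(f2, list(f1.subject_ids))
        sim = similarity(f1, f2)
        sim.dataset_pair = (a, b)
        by_dir = {d: identify(sim, d) for d in ("rows", "columns")}
        dself = differentiability(sim, include_self_in_null=include_self_in_null)
        results.append(PairResult(pair=(a, b), by_direction=by_dir, dself=dself, similarity=sim))
    return ChallengeResult(challenge=challenge, pairs=results)


def _subset(fm: FeatureMatrix, subjects: Sequence[str]) -> FeatureMatrix:
    index = {s: i for i, s in enumerate(fm.subject_ids)}
    rows = [index[s] for s in subjects]
    return FeatureMatrix(
        values=fm.values[rows],
        feature_labels=list(fm.feature_labels),
        subject_ids=list(subjects),
        dataset_id=fm.dataset_id,
    )
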