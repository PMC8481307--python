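"""End-to-end orchestration: simulate -> segment -> features -> challenges
-> reliability -> confounds -> PLS, with a machine-readable JSON report.

A single global seed is fanned out to per-stage child seeds through a
counter-based ``numpy.random.SeedSequence`` scheme, so stages never share a
random stream and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import io as mio
from .containers import BandDefinition, CANONICAL_BANDS, CohortRecording, band_by_name
from .features import band_power, extract_features, segment, welch_psd
from .fingerprint import run_challenge
from .reliability import reliability_table
from .stats import confound_correlations, pls_bootstrap, pls_fit, pls_permutation
from .synthetic import SyntheticConfig, generate_cohort, generate_empty_room

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

_CHALLENGE_SCHEME = {
    "within": "within_halves",
    "within_short": "segments_30s",
    "between": "sessions",
    "between_short": "segments_30s",
}


class SimulateBlock(BaseModel):
    """Synthetic-cohort parameters (mirrors SyntheticConfig)."""

    n_subjects: int = 20
    n_sessions: int = 2
    n_rois: int = 68
    fs: float = 600.0
    duration: float = 300.0
    bands: Optional[List[str]] = None  # subset of canonical band names
    sigma_between: float = 0.5
    sigma_within: float = 0.1
    n_latents: int = 5
    coupling_sd: float = 0.5
    noise_sd: float = 0.25
    alpha_peak_mean: float = 10.0
    alpha_peak_sd: float = 1.0
    demographic_effect: float = 1.0
    empty_room: bool = False  # replace the cohort by its empty-room analog


class RunConfig(BaseModel):
    """Pinned pipeline configuration; defaults match the documented design."""

    out_dir: Optional[str] = None
    recording_path: Optional[str] = None  # HDF5 input; or simulate block
    simulate: Optional[SimulateBlock] = SimulateBlock()
    feature_types: List[str] = Field(default_factory=lambda: ["connectome", "spectral"])
    band_names: List[str] = Field(default_factory=lambda: ["broadband"])
    challenges: List[str] = Field(default_factory=lambda: ["within"])
    orthogonalize: bool = False
    log_psd: bool = False
    include_self_in_null: bool = False
    run_reliability: bool = True
    run_confounds: bool = True
    run_pls: bool = False
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0


class AccuracyEntry(BaseModel):
    feature_type: str
    band: str
    challenge: str
    pair: Tuple[str, str]
    direction: str
    accuracy: float
    n_ties: int


class ChallengeSummary(BaseModel):
    feature_type: str
    band: str
    challenge: str
    mean_accuracy_rows: float
    mean_accuracy_columns: float
    dself_mean: Optional[float] = None


class ConfoundEntry(BaseModel):
    score: str
    confound: str
    r: Optional[float]
    p: Optional[float]
    n: int


class PLSSummary(BaseModel):
    singular_values: List[float]
    p_perm: List[float]
    demographic_names: List[str]
    lv1_demographic_salience: List[float]
    lv1_top_features: List[str]
    n_boot_dropped: int = 0


class RunReport(BaseModel):
    """Schema-backed bundle of everything one pipeline run computed."""

    config: RunConfig
    seeds: Dict[str, int]
    accuracies: List[AccuracyEntry]
    challenge_summaries: List[ChallengeSummary]
    reliability_medians: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    confounds: List[ConfoundEntry] = Field(default_factory=list)
    pls: Optional[PLSSummary] = None


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as f:
        return RunConfig.model_validate(yaml.safe_load(f) or {})


def _stage_seed(root: int, counter: int) -> int:
    return int(np.random.SeedSequence((root, counter)).generate_state(1)[0] % (2**31))


def _resolve_bands(names: List[str]) -> List[Optional[BandDefinition]]:
    return [None if n == "broadband" else band_by_name(n) for n in names]


def _simulate(cfg: RunConfig) -> Tuple[CohortRecording, pd.DataFrame, pd.DataFrame]:
    sim = cfg.simulate
    assert sim is not None
    band_objs = (
        CANONICAL_BANDS
        if sim.bands is None
        else tuple(band_by_name(n) for n in sim.bands)
    )
    scfg = SyntheticConfig(
        n_subjects=sim.n_subjects,
        n_sessions=sim.n_sessions,
        n_rois=sim.n_rois,
        fs=sim.fs,
        duration=sim.duration,
        bands=band_objs,
        sigma_between=sim.sigma_between,
        sigma_within=sim.sigma_within,
        n_latents=sim.n_latents,
        coupling_sd=sim.coupling_sd,
        noise_sd=sim.noise_sd,
        alpha_peak_mean=sim.alpha_peak_mean,
        alpha_peak_sd=sim.alpha_peak_sd,
        demographic_effect=sim.demographic_effect,
        seed=_stage_seed(cfg.seed, 0),
    )
    recording, demographics, artifacts = generate_cohort(scfg)
    if sim.empty_room:
        recording = generate_empty_room(scfg)
    return recording, demographics, artifacts


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every configured stage; optionally persist artifacts under
    ``cfg.out_dir`` (report.json, tables, manifest)."""
    seeds = {"simulate": _stage_seed(cfg.seed, 0),
             "pls_perm": _stage_seed(cfg.seed, 1),
             "pls_boot": _stage_seed(cfg.seed, 2)}
    out = Path(cfg.out_dir) if cfg.out_dir else None
    manifest: List[str] = []
    if out:
        out.mkdir(parents=True, exist_ok=True)

    demographics = artifacts = None
    if cfg.recording_path:
        recording = mio.load_recording(cfg.recording_path)
    elif cfg.simulate is not None:
        recording, demographics, artifacts = _simulate(cfg)
    else:
        raise ValueError("config needs either recording_path or a simulate block")

    if out:
        mio.save_recording(recording, out / "recording.h5")
        manifest.append("recording.h5")
        if demographics is not None:
            demographics.to_csv(out / "demographics.csv")
            artifacts.to_csv(out / "artifacts.csv")
            manifest += ["demographics.csv", "artifacts.csv"]

    bands = _resolve_bands(cfg.band_names)
    accuracies: List[AccuracyEntry] = []
    summaries: List[ChallengeSummary] = []
    reliability_medians: Dict[str, Dict[str, float]] = {}
    dself_by_type: Dict[str, pd.Series] = {}

    for challenge in cfg.challenges:
        datasets = segment(recording, _CHALLENGE_SCHEME[challenge])
        for ftype in cfg.feature_types:
            for band, bname in zip(bands, cfg.band_names):
                feats = {
                    key: extract_features(
                        ds, ftype, band,
                        orthogonalize=cfg.orthogonalize,
                        log_psd=cfg.log_psd,
                        dataset_id=key,
                    )
                    for key, ds in datasets.items()
                }
                result = run_challenge(
                    feats, challenge, include_self_in_null=cfg.include_self_in_null
                )
                for pair_res in result.pairs:
                    for direction, fr in pair_res.by_direction.items():
                        accuracies.append(
                            AccuracyEntry(
                                feature_type=ftype, band=bname, challenge=challenge,
                                pair=pair_res.pair, direction=direction,
                                accuracy=fr.accuracy, n_ties=fr.n_ties,
                            )
                        )
                dself_all = pd.concat([p.dself["d_self"] for p in result.pairs])
                dself_mean = float(dself_all.groupby(level=0).mean().mean())
                summaries.append(
                    ChallengeSummary(
                        feature_type=ftype, band=bname, challenge=challenge,
                        mean_accuracy_rows=result.mean_accuracy("rows"),
                        mean_accuracy_columns=result.mean_accuracy("columns"),
                        dself_mean=dself_mean,
                    )
                )
                if challenge == "within" and bname == cfg.band_names[0]:
                    dself_by_type[ftype] = (
                        result.pairs[0].dself["d_self"].rename(f"dself_{ftype}")
                    )
                    if cfg.run_reliability:
                        a, b = result.pairs[0].pair
                        table = reliability_table(feats[a], feats[b])
                        reliability_medians[ftype] = {
                            col: float(table[col].median()) for col in table.columns
                        }
                        if out:
                            fname = f"reliability_{ftype}.csv"
                            table.to_csv(out / fname)
                            manifest.append(fname)
                if out:
                    for pair_res in result.pairs:
                        tag = f"{challenge}_{ftype}_{bname}_" + "_".join(
                            p.replace("/", "-") for p in pair_res.pair
                        )
                        pair_res.dself.to_csv(out / f"dself_{tag}.csv")
                        manifest.append(f"dself_{tag}.csv")

    confounds: List[ConfoundEntry] = []
    if cfg.run_confounds and artifacts is not None and dself_by_type:
        scores = pd.DataFrame(dself_by_type)
        table = confound_correlations(scores, artifacts)
        confounds = [
            ConfoundEntry(
                score=row.score, confound=row.confound,
                r=None if pd.isna(row.r) else float(row.r),
                p=None if pd.isna(row.p) else float(row.p),
                n=int(row.n),
            )
            for row in table.itertuples()
        ]

    pls_summary = None
    if cfg.run_pls and demographics is not None:
        sim = cfg.simulate
        band_objs = (
            CANONICAL_BANDS if sim is None or sim.bands is None
            else tuple(band_by_name(n) for n in sim.bands)
        )
        rows, labels = [], []
        for i in range(recording.n_subjects):
            psd = welch_psd(recording.data[i, 0], recording.fs)
            vec, labels = band_power(psd, band_objs, log=True)
            rows.append(vec)
        y = np.vstack(rows)
        fit = pls_fit(demographics, y)
        p_perm = pls_permutation(demographics, y, n_perm=cfg.n_perm, seed=seeds["pls_perm"])
        fit = pls_bootstrap(demographics, y, n_boot=cfg.n_boot, seed=seeds["pls_boot"], fit=fit)
        order = np.argsort(-np.abs(fit.bootstrap_ratio[:, 0]))[:10]
        pls_summary = PLSSummary(
            singular_values=[float(s) for s in fit.singular_values],
            p_perm=[float(p) for p in p_perm],
            demographic_names=fit.demographic_names,
            lv1_demographic_salience=[float(v) for v in fit.demographic_saliences[:, 0]],
            lv1_top_features=[labels[j] for j in order],
            n_boot_dropped=fit.n_boot_dropped,
        )

    report = RunReport(
        config=cfg,
        seeds=seeds,
        accuracies=accuracies,
        challenge_summaries=summaries,
        reliability_medians=reliability_medians,
        confounds=confounds,
        pls=pls_summary,
    )
    if out:
        (out / "report.json").write_text(report.model_dump_json(indent=2))
        manifest.append("report.json")
        (out / "manifest.json").write_text(json.dumps(sorted(manifest), indent=2))
    return report
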