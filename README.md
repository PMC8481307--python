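# megfp

Connectome and spectral **fingerprinting of individuals** from multi-session,
multi-subject ROI electrophysiological timeseries (e.g. source-localised MEG
parcellated into cortical regions), with a synthetic cohort generator so the
whole analysis is testable without access-controlled recordings.

The package is aimed at researchers studying inter-individual variability of
resting-state brain activity: given two datasets per person (two halves of a
session, two sessions days apart, or short 30 s segments), can each person be
re-identified from their functional connectome or power spectrum alone, and
which features carry that individuality?

## The analysis

Two feature families are extracted per subject and dataset:

* **Connectome features** — band-limited amplitude envelope correlation
  (AEC): each ROI signal is band-passed (δ 1–4, θ 4–8, α 8–13, β 13–30,
  γ 30–50, high-γ 50–150 Hz), Hilbert-transformed, and the Pearson
  correlation between every pair of envelope magnitudes forms a symmetric
  R × R matrix; its upper triangle (R(R−1)/2 edges) is the feature vector.
* **Spectral features** — Welch power spectral densities per ROI (Hann
  windows of 2 s, 50 % overlap, 0–150 Hz at 0.5 Hz resolution),
  concatenated across ROIs.

**Identification.** For datasets 1 and 2 over the same cohort, the
similarity matrix A has entries A<sub>ij</sub> = corr(features of subject i
in dataset 1, subject j in dataset 2). Each probe is assigned the identity
of its highest-correlating candidate; accuracy is the fraction of subjects
matched to themselves. Per-participant **differentiability** is

&nbsp;&nbsp;&nbsp;&nbsp;D_self(i) = (A<sub>ii</sub> − μ<sub>i</sub>) / σ<sub>i</sub>,

the z-score of the self-correlation against subject i's correlations to all
*other* cohort members (sample SD).

**Feature reliability.** Per feature: one-way random-effects intraclass
correlation ICC(1,1) across the two datasets, plus the Finn-style edgewise
group consistency Φ(e) and differential power DP(e) on unit-norm feature
vectors.

**Demographics.** PLS correlation: SVD of the z-scored cross-block matrix
X'Y/(n−1) between demographics and neural features, with row-permutation
p-values per latent variable and bootstrap ratios / percentile CIs for the
saliences (Procrustes-aligned resamples).

The **synthetic cohort generator** plants exactly the structure these
statistics assume — subject-specific band-power topographies with
between-subject and between-session log-normal variance, subject-specific
inter-ROI coupling through shared band-limited latent carriers, an
individual alpha-peak frequency, additive sensor noise, an "empty-room"
analog with the cohort-average spectrum but no identity, and demographics
linearly coupled to a planted feature subset. See `docs/methods.md`.

## Worked example

```python
import numpy as np
from megfp import (CANONICAL_BANDS, SyntheticConfig, generate_cohort,
                   segment, run_challenge)
from megfp.features import extract_features

theta, alpha, beta = CANONICAL_BANDS[1:4]
cfg = SyntheticConfig(
    n_subjects=12, n_sessions=2, n_rois=8, fs=300.0, duration=60.0,
    bands=(theta, alpha, beta), sigma_between=0.5, sigma_within=0.1, seed=0,
)
recording, demographics, artifacts = generate_cohort(cfg)

datasets = segment(recording, "within_halves")
features = {key: extract_features(ds, "spectral", dataset_id=key)
            for key, ds in datasets.items()}
result = run_challenge(features, "within")
print(f"within-session spectral accuracy: {result.mean_accuracy():.3f}")
dself = result.pairs[0].dself["d_self"]
print(f"mean differentiability D_self:    {dself.mean():.2f}")
print(dself.head(3).round(2))
```

prints

```
within-session spectral accuracy: 1.000
mean differentiability D_self:    4.31
subject_id
sub000    7.56
sub001    2.69
sub002    8.60
Name: d_self, dtype: float64
```

Every subject in this 12-person cohort is re-identified from the spectral
profile of one half of their session using the other half (accuracy 1.0),
and the average self-correlation sits ~4.3 SDs above each subject's
correlations to the rest of the cohort.

A `megfp` command-line interface exposes the stages
(`simulate`, `extract-features`, `fingerprint`, `challenge`, `reliability`,
`pls`, `run`); `megfp run --config cfg.yaml` executes the full pipeline and
writes a schema-validated JSON report.

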