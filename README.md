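# doceeg

EEG complexity, connectivity and clinical-outcome analysis for comparing
two anesthetics — esketamine vs propofol — in patients with disorders of
consciousness (DoC), driven by a seeded synthetic-data generator that
stands in for (non-deposited) patient recordings.

It is written for clinical neurophysiologists and biostatisticians who
want a fully reproducible, tested version of this analysis family:

* **Permutation entropy (PE):** Shannon entropy of ordinal (rank-order)
  patterns of delay vectors, H = −Σ p_π log p_π / log(m!), normalised to
  [0, 1] (default m = 3, τ = 1). A depth-of-anesthesia complexity marker:
  broadband irregular EEG scores near 1, slow-wave-dominated EEG scores low.
* **Weighted phase lag index (wPLI):** per channel pair and frequency bin,
  |Σ_e Im S_xy| / Σ_e |Im S_xy| over Hanning-tapered cross-spectra of
  2-s epochs with 50% overlap, gated by phase-locking value (PLV > 0.1),
  averaged within the canonical bands (δ, θ, α, β, γ) and over all channel
  pairs into a whole-brain index. Insensitive to zero-lag
  (volume-conducted) coupling by construction.
* **Cluster-based permutation test:** pixelwise two-sample t over
  time-frequency maps, 4-connected suprathreshold clusters scored by mass
  (Σt) against a max-statistic null from random group relabelings;
  p_cluster = (1 + #{null ≥ |mass|})/(n_perm + 1).
* **Inference layer:** Shapiro-routed t / Mann–Whitney with effect sizes
  (Cohen's d, rank-biserial r), Fisher exact with Cramér's V,
  Benjamini–Hochberg FDR families, and confounder-adjusted logistic
  (aOR) / linear outcome models with likelihood-ratio comparison of
  EEG-augmented models.

The synthetic generator produces multichannel EEG with controllable
band-wise power and lagged cross-channel coupling (plus zero-lag leakage
and injectable artifacts) and clinical cohorts with the two-group
structure the analysis expects. See `docs/methods.md` for the full model
description and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale
(17 + 17 subjects, 16-channel 60-s recordings at 250 Hz, seed 7) and
write their tables under `results/`:

```sh
cd analysis
python 01_simulate.py      # cohort + per-subject/phase EEG fixtures
python 02_preprocess.py    # epoch keep-masks (audit)
python 03_complexity.py    # PE timecourses + group comparisons
python 04_connectivity.py  # band-wise wPLI profiles + comparisons
python 05_cluster_test.py  # time-frequency cluster permutation test
python 06_outcomes.py      # Table-1-style summary + adjusted models
```

`03_complexity.py` prints (seed 7):

```
maintenance PE: esketamine 0.774 vs propofol 0.752 (p_FDR=2.1e-06)
```

i.e. the esketamine profile preserves more broadband complexity during
anesthesia maintenance, with no preoperative or recovery difference
(p_FDR 0.49 and 0.83). `05_cluster_test.py` finds the matching spectral
structure:

```
13 clusters, 2 significant at p_cluster<0.05 (n_perm=500)
  sign +1: 5-45 Hz, mass 112084, p=0.002
  sign -1: 1-4 Hz, mass -3420, p=0.038
```

a positive cluster (esketamine > propofol power, covering the β band) and
a negative δ-band cluster (propofol slow-wave dominance). `06_outcomes.py`
fits the adjusted models on the same cohort:

```
adjusted OR (esketamine vs propofol): 21.07 [2.60, 170.56]
adjusted recovery-time effect: -4.42 min [-7.38, -1.45]
```

— at n = 34 the odds ratio is estimated with the wide CI such a cohort
deserves; the generating value (OR 6.84) is recovered tightly at large n
(see below).

The same pipeline is scriptable as a library or CLI
(`doceeg all --config cfg.yaml`), producing one deterministic JSON report
per config.

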