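# dmdcpp

Segment-wise dynamic-mode-decomposition (DMD) descriptors, class-specific
medoid dictionary learning, prototype-projection features, and strict
leave-one-subject-out (LOSO) evaluation for multichannel EEG dementia
classification — plus a PCA baseline, margin-based reliability statistics,
and a synthetic photic-stimulation EEG generator so the entire pipeline is
testable offline.

## Pipeline overview

1. **Segmentation** (`dmdcpp.segmentation`) — recordings are screened for at
   least 19 usable non-overlapping 2 s segments inside the stimulus
   interval; ten 20 s epochs (ten consecutive segments each) are placed at
   evenly spaced start indices.
2. **DMD** (`dmdcpp.dmd_core`) — per 2 s segment, delay-embedded (stack
   S=48) exact DMD with rank truncation R=100; channel-space modes are
   rectified by removing the complex across-channel mean.
3. **Stage 1 descriptors** (`dmdcpp.descriptor`) — modes with
   eigenfrequencies in [4, 40] Hz (one conjugate-pair representative) are
   sorted by frequency; channel-wise magnitudes are interpolated to a fixed
   width P=50, averaged over the epoch's segments, and min–max rescaled to
   [0, 1], giving a 19×50 image and its 950-dim vectorization.
4. **Stage 2 dictionaries** (`dmdcpp.dictionary`) — per class, divisive
   clustering of l2-normalized descriptor vectors (complete linkage under
   cosine dissimilarity; split thresholds tau_sup=11, n_min=10, h_stop=0.2)
   retains coherent groups whose medoids become dictionary atoms.
5. **Projection features** (`dmdcpp.projection_features`) — each epoch is
   encoded by cosine similarities to the atoms of both class dictionaries,
   then standardized with train-split statistics only.
6. **LOSO evaluation** (`dmdcpp.loso_pipeline`) — per held-out subject,
   dictionaries/features/classifier are re-fitted on the remaining
   subjects; a linear SVM (C=1) yields per-epoch labels and geometric
   margins; subjects are decided by majority vote (ties abstain); pooled
   confusion metrics, decided-subject accuracy, reject rate and Wilson 95%
   intervals are reported.
7. **Reliability** (`dmdcpp.reliability`) — per-subject margin descriptors
   (median |m|, IQR, sign consistency) grouped by outcome (TP/FP/TN/FN) and
   compared via median-gap permutation tests and Cliff's delta.
8. **PCA baseline** (`dmdcpp.pca_baseline`) — identical Stage 1 features,
   with train-fitted PCA retaining 95% variance replacing step 4–5.
9. **Synthetic data** (`dmdcpp.synthetic_data`) — 19-channel recordings
   with block-wise photic entrainment (5–30 Hz), posterior alpha, and pink
   noise; diagnostic class modulates only the sub-12 Hz gain and the
   per-segment phase-fragmentation probability.

## CLI

```bash
dmdcpp simulate --n-ad 8 --n-cn 8 --seed 42 --out scratch/cohort
dmdcpp epoch --recording scratch/cohort/AD01.npz
dmdcpp features --data scratch/cohort --out scratch/features.tsv
dmdcpp loso --data scratch/cohort --task ad-vs-cn --out scratch/results
dmdcpp loso --data scratch/cohort --task ad-vs-cn --features pca --out scratch/pca
dmdcpp all --n-ad 8 --n-cn 8 --seed 42 --out scratch/run   # simulate + run
```

`dmdcpp loso` writes `summary.json`, `margins.tsv`, `reliability.tsv`, and
the resolved `config.yaml` into the output directory. Pipeline parameters
can be set in a flat YAML file passed via `--config` (keys mirror
`dmdcpp.pipeline.RunConfig`).

## Module map

| module | role |
| --- | --- |
| `segmentation` | screening, 2 s grid, epoch placement, bundled cohort interval table |
| `dmd_core` | delay embedding, exact DMD, mode rectification |
| `descriptor` | band filtering, mode images, epoch descriptors |
| `dictionary` | cosine dissimilarity, divisive clustering, medoids, dictionaries |
| `projection_features` | cosine projection, feature tables, train-only standardization |
| `loso_pipeline` | folds, SVM margins, majority vote, pooled metrics, Wilson CI |
| `reliability` | margin descriptors, outcome groups, permutation tests, Cliff's delta |
| `pca_baseline` | 95%-variance PCA projection |
| `synthetic_data` | synthetic photic-stimulation EEG cohorts |
| `pipeline` / `cli` | configuration, orchestration, command-line interface |
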