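# boldcaps

Seed-based **co-activation pattern (CAP) analysis** of resting-state BOLD
fMRI, built around the spatio-temporal point process: instead of averaging
a seed-correlation map over a whole session, the continuous seed signal is
reduced to the discrete time points where it crosses an amplitude
threshold, and the whole-brain frames at those moments are clustered into
a small set of transient spatial states.

The package targets the posterior-cingulate (PCC) variant of this analysis
used to track default-mode-network reorganization across pharmacologically
modulated states of consciousness (wakefulness, sedation, unconsciousness,
recovery), and ships a synthetic cohort generator with planted ground
truth so every stage is testable without any data download.

## The method

For each session (one subject in one condition):

1. **Preprocess** — detrend (linear+quadratic), bandpass 0.005–0.1 Hz
   (zero-phase Butterworth), nuisance regression (global/WM/CSF means, six
   motion parameters), 8 mm FWHM Gaussian smoothing, then per-voxel
   z-scoring: `x_v(t) ← (x_v(t) − μ_v)/σ_v`.
2. **Motion QC** — framewise displacement
   `FD_t = Σ|Δd| + r·Σ|Δθ|` (r = 50 mm) and
   `DVARS_t = 100·RMS_v(x_v(t) − x_v(t−1))/x̄`; a frame is censored when
   *both* exceed 0.5 (mm, %BOLD).
3. **Point process** — the seed (a 6 mm cube at the PCC, MNI
   (0, −53, 26), or the designated cube on synthetic grids) is averaged,
   re-standardized, and frames with seed value > 1 SD are selected —
   for Gaussian signal about `1 − Φ(1) = 15.87 %` of time points.
4. **CAP clustering** — frames are centered, unit-normalized (so
   Euclidean k-means orders like `1 − r_Pearson`) and clustered with
   K = 8. Reference centroids fit once on an independent wakefulness
   cohort are then *kept fixed*, and each condition's frames are assigned
   to the nearest centroid, making cap index j comparable across
   conditions. `cap_j = mean of frames assigned to j`; the
   occupancy-weighted mean of the caps equals the seed-map grand mean
   exactly (the decomposition identity the method rests on).
5. **Group statistics** — per-subject cap maps enter random-effects
   one-sided t-tests; the consciousness profile is tested with the
   zero-sum contrast `[1.5, −0.5, −1.5, 0.5]` (W, S, U, R) collapsed
   within subject, with Benjamini–Hochberg FDR at q = 0.05.

## Worked example

A four-condition synthetic cohort in which two of four planted patterns
are progressively attenuated with depth of sedation and restored at
recovery:

```bash
boldcaps run --config examples/propofol_demo.yaml --out scratch/demo --seed 11
```

prints (excerpt):

```
spatial correlation with reference condition 'wakefulness':
           sedation  unconsciousness  recovery
cap_index
0          0.955216         0.895082  0.877800
1          0.976644         0.968781  0.980460
2          0.962849         0.941390  0.987247
3          0.930480         0.786104  0.946618
4          0.957480         0.950796  0.946863
5          0.964776         0.979188  0.972661
6          0.950172              NaN  0.984353
7          0.982806         0.970684  0.981480
```

Caps tied to preserved patterns stay near-identical across conditions
(r ≈ 0.95–0.98); the caps carrying the attenuated patterns lose similarity
with depth of sedation — cap 3 dips to 0.79 in unconsciousness and cap 6
empties entirely there (occupancy 0, hence no correlation), then both
recover. The report also lists per-cap occupancies per condition and, for
each cap, how many voxels survive the linear consciousness contrast at
FDR q = 0.05.

The same stages are available as composable pieces — sklearn-style
transformers (`TemporalBandpass`, `PolynomialDetrend`,
`NuisanceRegression`, `TemporalStandardize`), a clusterer (`CapKMeans`
with `fit` = free k-means, `predict` = fixed-centroid assignment) — and as
file-based CLI subcommands (`simulate`, `preprocess`, `qc`, `extract`,
`cluster`, `compare`, `report`).

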