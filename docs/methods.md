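# Methods

This document specifies the models implemented by `facesync`, the parameter
defaults and the reasoning behind them, the scope of the built-in simulation
studies, and the numerical conventions that make results reproducible.

## 1. Input data and preprocessing

### 1.1 Raw recordings

Input is "Trace-dialect" CSV: one row per captured webcam frame with a
timestamp, a participant identifier, optional grouping columns, a landmark
cell holding 68 X/Y pixel pairs as JSON (flat 136-vector `x1,y1,…` or nested
68×2), and optional emotion-classifier score columns. Column names are fully
configurable (`ColumnMap`); timestamps in seconds or milliseconds are
auto-detected from the median inter-frame gap (> 10 → milliseconds).

Parsing is total: malformed landmark cells (truncated JSON, wrong
cardinality, non-numeric or non-finite entries) become missing values and
are counted in a per-recording parse log; they are never raised as errors,
because real webcam exports routinely contain such rows.

### 1.2 Missingness screening

For a recording spanning `t_last − t_first` seconds at expected rate `f`,

```
missing fraction = 1 − n_valid / ((t_last − t_first) · f),  clamped to [0, 1]
```

Recordings whose fraction **strictly exceeds** `max_missing_fraction`
(default 0.5 — the threshold is user-set by design; 0.5 keeps any recording
in which at least half the expected frames survive) are excluded and logged.

### 1.3 Resampling and alignment

Valid frames are linearly interpolated onto a uniform grid at `target_rate`
(default 5 Hz, the typical mean webcam capture rate) spanning exactly the
recording's valid extent — no extrapolation. Group alignment offers two
policies:

- `common-overlap` (default): all recordings are re-gridded onto the
  phase-aligned grid (points at integer multiples of `1/rate`) covering the
  intersection of their spans; disjoint spans are an error.
- `fixed-duration`: each recording is truncated to a stated duration from
  its own start, with a relative time axis.

### 1.4 Head movement ("nose energy")

Per 1-second bin, the frame-to-frame Euclidean displacements of the nose tip
(landmark #34) are summed (path length; a `mean` variant exists) and scaled
from pixels to centimetres by `iod_cm / IOD_px`, where `IOD_px` is the median
over frames of the distance between the two eye-region centroids and
`iod_cm = 6.3` is the adult average inter-ocular distance. Consequently a
nose path of exactly one IOD within a bin reads exactly 6.3 cm, and the
measure is invariant to camera zoom.

### 1.5 Scalarisation

CorrCA operates on one scalar series per landmark. Two compressions of the
X/Y trajectory are provided:

- `vector_norm`: distance from the landmark's recording-mean position,
  `r(t) = √(x′(t)² + y′(t)²)` with `x′, y′` mean-centred over the recording;
- `motion_amplitude`: frame-to-frame displacement, `d(0) = 0`.

Both are invariant to rigid translation of the whole face.

## 2. SUSY — Surrogate Synchrony

Given two equal-length series, SUSY:

1. cuts them into consecutive non-overlapping segments of `segment_seconds`
   (default 5 s; a trailing partial segment is dropped; segments must hold at
   least 3 samples);
2. for each segment and each integer lag `τ ∈ [−L, L]` with
   `L = round(maxlag_seconds · rate)` (so the lag axis always has `2L + 1`
   entries), computes the Pearson correlation of the overlapping portions,
   each portion mean-centred over that overlap, and Fisher-Z transforms it
   (`z = atanh r`, with `r` clipped to `±(1 − 1e−7)`; zero-variance overlaps
   yield `z = 0`);
3. builds a null by circularly rotating one series by a random offset drawn
   uniformly from `[n, T − n]` samples (`n` = segment length), so every
   rotation displaces the series by at least one full segment while
   preserving its value multiset — hence its mean and SD — exactly;
4. summarises each dyad by the effect size
   `ES = (μ_real − μ_surrogate) / σ_surrogate`, where each surrogate
   replicate is first aggregated over segments × lags (signed mean by
   default; an absolute-mean variant exists) and μ/σ are taken over
   replicates (`n_surrogates` default 100).

Group analysis runs all `C(N, 2)` dyads with one seeded generator, so
results are bit-reproducible. Under the null (independent white noise) the
ES is centred on zero with approximately nominal 5% exceedance of the
`1.96 σ` band (verified over 200 seeds in the test suite).

### Window pooling: two deliberate semantics

Comparisons of real vs surrogate Z inside a time window use closed segment
intervals (`[first sample, last sample]` of each segment) and exist in two
modes:

- `within` — only segments fully inside the closed window. This is the
  default for *reporting window means* (`pooled_window_z`): a 70–80 s window
  under 5-s segmentation pools the two segments the synchrony event actually
  spans.
- `intersect` — every segment whose closed span touches the closed window.
  This is what the paired t-test (`real_vs_surrogate_test`) uses: the same
  window additionally includes the segment containing the sample at 80 s,
  giving 435 dyads × 3 segments × 1 lag = 1305 pairs and df = 1304.

Both semantics are exposed because they answer different questions (how
strong is synchrony where it occurs vs is there synchrony anywhere the
window touches); the defaults reproduce the package's reference simulation
results.

## 3. CorrCA — Correlated Component Analysis

For subjects `i = 1…N` with mean-centred feature series `X_i ∈ R^{D×T}`:

```
R_ij = X_i X_jᵀ / (T − 1)
R_W  = Σ_i R_ii                      (pooled within-subject covariance)
R_B  = Σ_{i≠j} (R_ij + R_ji)/2       (pooled between-subject covariance)
R_W(γ) = (1 − γ) R_W + γ (tr R_W / D) I
```

Eigenvectors come from `scipy.linalg.eigh(R_B, R_W(γ))`, sorted by
descending eigenvalue, normalised to `wᵀR_W(γ)w = 1`, and sign-fixed so each
component's largest-magnitude forward-model loading is positive.

**Shrinkage regularises the eigenvectors only.** The reported eigenvalue of
component k is the *unshrunk* generalised Rayleigh quotient
`λ_k = (w_kᵀ R_B w_k)/(w_kᵀ R_W w_k)` evaluated at the fitted eigenvector,
and the component ISC is `ρ_k = λ_k/(N−1)`. By Cauchy–Schwarz this construction
guarantees `|ρ_k| ≤ 1` for every input and every γ, whereas the raw shrunk-
problem eigenvalue can exceed `N−1` on anisotropic data at large γ. The
shrunk-problem eigenvalues are kept separately (`gev_eigenvalues`) — they are
what a brute-force Rayleigh-quotient maximiser reproduces.

- **γ default 0.1**, swept over `{0.05, 0.1, 0.2, 0.5, 1.0}` by
  `gamma_sweep`; a helper checks whether groups' component-1 ISC rank order
  is γ-invariant.
- **Per-subject ISC** uses the pooled within covariance in the denominator,
  scaled so the subject mean equals `ρ_k` exactly:
  `ISC_{i,k} = N (w_kᵀ R_{B,i} w_k) / ((N−1) w_kᵀ R_W w_k)`; a per-subject-
  denominator variant (`variant="individual"`) is available.
- **Windowed ISC** re-estimates per-window-centred covariances inside a
  sliding window (default 3 s, step 1 s) and projects them through the
  *global* W — components are never refit per window, preserving component
  identity across time. The trace is scaled by `1/(N−1)` by default. For
  identical subjects the normalised trace is exactly 1 in every window.
- **Forward model** `A = R_W W (Wᵀ R_W W)⁻¹` (unshrunk `R_W`), satisfying
  `WᵀA = I`; with a 68-feature fit its columns are facial-topography loading
  maps. Reconstruction `X̂ = A Wᵀ X` equals centred X exactly (to 1e−6)
  when all D components are kept and γ = 0.

## 4. Simulation studies

### 4.1 Head-movement (SUSY) study

30 subjects, 120 s at 1 Hz. Each subject is unit-SD white Gaussian noise;
inside the closed window 70–80 s the signal is
`α · template + (1 − α) · noise` with α = 0.7 and a shared 0.5 Hz sine
template. At 1 Hz sampling a 0.5 Hz sine sits exactly at the Nyquist
frequency, so the sampled template is determined entirely by its phase:
phase 0 samples to all zeros (degenerate), so the default phase is π/2,
giving the alternating ±1 sequence. With these settings the pooled real
Fisher-Z over the two event segments averages ≈ 1.6 across seeds, the
surrogate mean is ≈ −0.01, and the intersect-mode paired test has df = 1304.

### 4.2 Landmark (CorrCA) study

30 subjects, 60 s at 5 Hz on a fixed canonical 68-landmark face template
(inter-ocular distance exactly 63 px). Per subject: Gaussian spatial offset
(σ = 5 px, constant over time) plus white temporal noise (σ = 0.5 px).
Two region-localised oscillatory events are injected on both coordinate
axes, evaluated in absolute recording time: mouth landmarks of subjects 1–15
during [20, 22) s, left-eye landmarks of subjects 16–25 during [30, 32) s;
each subject's copy is circularly phase-shifted by up to ±2 frames and
amplitude-scaled in [0.8, 1.2]. The temporal noise SD (0.5 px) is chosen so
the generator occupies the strongly synchronous regime the design describes:
at 1 px the weaker 10-subject eye event is not recoverable at all, which
would contradict the generator's stated purpose of validating recovery.

Recovery behaviour (verified over 20 seeds): the two events appear as the
two leading components, their top-5 forward-model loadings fall entirely in
the correct regions, and each component's windowed-ISC trace peaks at a
window whose 3-s span overlaps the injection window. Note the window (3 s)
is longer than the events (2 s), so the argmax window typically *straddles*
an event boundary — its centre can sit up to ~1 s outside the injection
interval. "Peak at the event" is therefore defined as span overlap, not
centre containment, which is structurally unattainable for boundary-
dominated signals.

### 4.3 Raw CSV fixture generator

`simulate_raw_trace_csv` writes a Trace-dialect CSV (template + per-subject
offset + slow sinusoidal drift, jittered timestamps, a stated fraction of
interior rows dropped, nested or flat landmark JSON, emotion columns)
together with a ground-truth manifest, for end-to-end pipeline tests.

## 5. Numerical conventions

- All stochastic code takes explicit seeds (`numpy.random.default_rng`);
  identical config + seed reproduces every artifact byte-for-byte.
- Fisher-Z inputs are clipped to `|r| ≤ 1 − 1e−7`, bounding `|z|` ≈ 8.4.
- Processed CSVs are written with `float_format="%.17g"` and read with
  `float_precision="round_trip"`, making the processed round trip bit-exact.
- Eigen-decompositions, the t-test and the ANOVA helper delegate to
  SciPy (`linalg.eigh`, `stats.ttest_rel`, `stats.f_oneway`); segment/lag
  correlations and circular surrogates are vectorised NumPy, as no standard
  library implements them.
- The ISC bound `|ρ_k| ≤ 1 + 1e−8` is asserted at fit time
  (`NumericIntegrityError` on violation).

## 6. Limitations

- Only linear interpolation onto the uniform grid is implemented.
- The real-video analyses that motivated the methods require external
  datasets; validation here rests on the two seeded simulation studies plus
  property-based tests (bound, oracle, calibration, structural identities).
- The face template is a synthetic canonical layout for simulation and
  plotting, not a statistical mean face.
- ANOVA is a thin reporting helper over `scipy.stats.f_oneway`, provided for
  condition-level comparison of component-1 ISC values only.
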