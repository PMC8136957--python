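# Methods

## The measurement model

Biodynamic imaging records, per well, a pixel × time array of
back-scattered intensity. Intracellular motion modulates the speckle
field, so the one-sided fluctuation power spectrum S(f) of each pixel
series over 0.01–12.5 Hz is the primary observable. A fluctuation
frequency f is interpreted as a Doppler shift in backscatter geometry,
v = f λ / (2 n); with λ = 836.2 nm we take n = 1.33 (aqueous tissue) as
the default refractive index, the value that reconciles the assay's
printed speed span (≈3 nm/s at 0.01 Hz, ≈4 μm/s at 12.5 Hz). n is a
parameter of `doppler_speed`.

The drug-response spectrogram is the log-ratio

D(f, t) = ln S(f, t) − ln S₀(f),

where S₀ is the time-averaged pre-drug spectrum of the same well. The
log-ratio (rather than (S−S₀)/S₀) is symmetric between motion increases
and decreases and additive under composition, which makes the cross-dose
contrasts below exact differences. Values are in RU — here, log-relative
spectral power; the sign convention is positive = more motion.

Frequency bands partition [0.01, 12.5] Hz as lo [0.01, 0.1), mid
[0.1, 0.5), hi [0.5, 12.5]; boundary frequencies belong to the upper band
(half-open convention). Biologically: lo ↔ whole-cell shape/integrity,
mid ↔ membrane undulation and nuclear motion, hi ↔ organelle and vesicle
transport. The apoptotic signature is lo↑, mid↓, hi↑.

## Spectral estimation

Within each analysis window, spectra are Welch estimates: per-pixel mean
subtraction, Hann taper, 50 % segment overlap, averaged over pixels.
Segment length defaults to half the analysis window; the resolvable floor
is therefore max(2/window, 0.01) Hz, and a full-window segment (plain
pixel-averaged periodogram) is available where 1/window resolution is
needed. Estimates are resampled onto a fixed log-frequency grid
(50 bins/decade over 0.01–12.5 Hz, log–log interpolation) so wells of any
duration align bin-by-bin. The estimator satisfies Parseval within 5 %
(density integral vs windowed variance) and tracks the synthetic
generator's analytic knee spectrum within ~3 % RMS log-power at 2048 s —
the suite asserts < 10 %.

Spectrogram windows default to 20 min with a 10 min step at
full-protocol durations (≈80 rows over 14 h); the desk-scale analyses in
this repository use 5 min windows/steps, stated per script.

## Biomarkers

- **Band biomarkers (local family):** mean of D over a band's frequencies
  and all post-drug times (t > 0).
- **NSD (global family):** per-pixel std/mean of raw image intensities in
  non-overlapping windows (default 10 min), averaged over pixels. ΔNSD is
  (mean post − mean pre)/mean pre, i.e. normalized by baseline so it is
  scale-free across wells. An alternative reading — NSD taken over
  spectrogram pixels rather than image pixels — exists in the field; the
  image-pixel definition is the implemented default, and the ambiguity is
  noted here rather than silently resolved.
- **Contrasts:** "A relative to B" is biomarker(A) − biomarker(B).
  Division is ill-defined for signed RU values; subtraction of log-relative
  quantities is the consistent reading, and makes contrast chains exact:
  (10/CTRL) = (10/1) + (1/CTRL).
- **Replicate averaging:** arithmetic mean over the four tissue
  replicates per condition, with per-replicate values retained for
  provenance.

Per-subject panels carry the per-condition values of all four bases
(Lo/Mid/Hi/DNSD) plus every higher-vs-lower dose contrast, 60 biomarkers
in total; the named quartet (*Hi Dox 1/CTRL*, *Hi Dox 10/1*,
*DNSD Dox 10/CTRL*, *DNSD Dox 10/1*) is a subset. Absolute per-subject RU
magnitudes are not published anywhere for the reference cohort, so only
signs, orderings and the derived statistics are reproducible — the tests
therefore validate the chain against synthetic injected truth.

## Selection

1. **Pooling.** Single-linkage grouping on |Pearson r| ≥ 0.9 across
   subjects, computed within each family; pooled value = per-subject mean
   of members. Restricting pools to one family is an interpretation: the
   later normalization needs every biomarker to have a "set of common
   origin", and a mixed local/global pool would not. Zero-variance
   biomarkers are excluded from pooling with a warning.
2. **Normalization.** Every biomarker is divided by the smallest
   across-subject SD within its family (local vs global, computed
   independently), so the least variable biomarker of each family attains
   SD 1. Sample (n−1) SDs throughout.
3. **z-factor.** Z = 1 − 3(σ₁+σ₂)/|μ₁−μ₂| between the two outcome
   groups — the standard screening-window statistic; no alternative
   formula is in common use, so this choice is adopted and documented.
   Z is flagged undefined when the group means coincide, and a singleton
   group contributes SD 0 (deterministic group) with a warning.
4. **One-hold-out ranking.** z-factors are recomputed with each subject
   held out; biomarkers are ranked by mean z across folds and scored by
   stability = fraction of folds inside that fold's top-k. The informal
   "iterate until consistently high" stopping rule is made concrete as:
   keep the biomarkers with stability 1.0 at the requested k (default 4).
   Folds that lose a label class are skipped and reported.

A caveat the null simulations expose: because folds share n−1 of n
subjects, per-fold rankings are strongly correlated, and ~8 % of
pure-noise 10-subject panels (40 biomarkers) still produce a stability-1
winner at k = 1. Stability 1.0 is a screening heuristic, not a
significance statement.

## Outcomes and endpoints

Counts are in 10³ cells/μL. Absolute change = post − pre; proportionate
change = (post − pre)/pre (reported to 3 decimals). Neutropenia is
post < 3.0; VCOG-CTCAE v1.1 grades use intervals closed at the lower
bound — grade 1 [1.5, 3.0), 2 [1.0, 1.5), 3 [0.5, 1.0), 4 < 0.5 — the
only convention consistent with every row of the bundled cohort. Endpoint
"deep drop" is a strictly-greater-than-50 % proportionate decrease (a
subject at exactly −0.500 is negative); endpoint "grade ≥ 2" follows the
grade directly.

## ROC statistics

AUC is the Mann–Whitney estimator (midranks; ties count ½), checked in
the suite against brute-force pair counting and scikit-learn. The
provisional cut-point maximizes the Youden index J = sensitivity − FP
rate over midpoints between adjacent distinct scores, ties broken toward
higher sensitivity and then the lower threshold; the score direction is
chosen so AUC ≥ 0.5 and cut-points are reported with their "≥"/"≤"
direction. Which cut-point criterion the instrument software used is not
stated anywhere; Youden is the conventional default and is flagged as a
choice. The 95 % CI attached to each biomarker is the exact binomial
(Clopper–Pearson) interval on classification accuracy at the cut-point
(e.g. 10/10 → 0.692–1.000, 9/10 → 0.555–0.997, 8/10 → 0.444–0.975, each
inverting the binomial tails to machine precision); no CI is put on the
AUC itself. The maximized J is positively biased in small samples (mean
max-J ≈ 0.5 under a permutation null at 7/3), which is why provisional
cut-points from 10 subjects must be read as exploratory.

## The synthetic-data generator

The generator exists so every stage is testable against known truth.

- **Baseline process:** white Gaussian noise per pixel, spectrally shaped
  in the Fourier domain to S(f) ∝ 1/(1 + (f/f_knee)^slope) (defaults
  f_knee = 0.5 Hz, slope = 2), globally rescaled to the configured
  fluctuation SD (10 on a mean intensity of 100, so intensities are
  positive in practice; a floor guards pathological settings). Spectral
  shaping by inverse FFT gives exact control of the fluctuation spectrum.
- **Drug response:** the fluctuation is decomposed into the three bands
  by FFT masks; each band's amplitude is multiplied by
  exp(gain · w(t)/2), where gain = band_gain × dose_scaling(dose) and
  w(t) ramps linearly from 0 to 1 over the onset period. The injected
  log-band-power change therefore equals `gain` exactly once the ramp
  completes. Onset defaults: 10 min at desk-scale durations, 30 min in
  the full-protocol preset — a 30 min ramp inside a 2 h post window would
  bias post-drug band means by ~12.5 %, confounding the recovery checks
  the desk scale exists for.
- **Dose scaling:** a saturating monotone ladder
  CTRL/0.1/1/10/100 μM → 0/0.25/0.5/0.75/1.0. Only monotonicity matters
  downstream; the ladder keeps each dose step visible in the contrasts.
- **Plates:** 5 conditions × 4 replicates, per-well seeds spawned
  deterministically from the master seed, injected truth recorded.
- **Cohorts:** latent sensitivity s ~ N(0,1) per subject drives both the
  biomarker (effect·s + noise) and the proportionate neutrophil drop
  (logistic in s), so the planted biomarker–outcome association has a
  computable ground-truth AUC. Counts stay positive by construction.
- **Desk-scale defaults:** 16×16 pixels at 25 Hz (the minimum sampling
  rate whose Nyquist covers 12.5 Hz), 1 h baseline + 2 h post-drug.
  Frame rate, pixel counts and window lengths of the physical instrument
  are not published; all are configurable.

What the generator does **not** emulate: speckle statistics of a real
interferometer (the field is Gaussian, not fully developed speckle),
spatial correlation between pixels, tissue heterogeneity and drift,
photobleaching, tomographic depth sectioning, and any pharmacokinetics.
Passing tests therefore demonstrate that the analysis recovers known
band-level spectral modulations from stationary noise — not that the
biology behaves this way.

## Numerical choices and degenerate inputs

- float32 storage for intensity arrays (a 16×16 × 3 h well at 25 Hz is
  ~105 MB); float64 for all spectral estimates.
- Undefined z-factors (equal means) propagate as NaN and rank below every
  finite value.
- NSD with a zero pixel mean, spectrograms over zero baseline power, and
  analysis windows outside the recording raise typed errors naming the
  offending pixel/window.
- All generators and the pipeline flow from a single integer seed;
  rerunning a pipeline config reproduces byte-identical CSVs.

## Problem sizes used in this repository

Analysis scripts and the test suite run at reduced sizes chosen so the
statistical assertions still have comfortable margins: 4×4-pixel wells
with 10 + 20 min recordings for the 10-subject study (the hi-band
recovery there has ~1 % estimation noise against a 15 % tolerance band),
16×16 wells with 30–68 min recordings for the estimator-accuracy and
null-spectrogram checks, and 2048–4096 s records for the spectral oracle.

## Known limitations

- The 13-biomarker → 4-biomarker screening funnel of the motivating study
  is reproduced structurally (planted-truth panels), not numerically: the
  identities of the 13 candidates and per-dog biomarker values were never
  published.
- Published optimal-cutoff values (≥ −0.366 etc.) are likewise not
  reproducible — they live on the unpublished per-dog RU scale.
- Pooling/normalization details ("closely associated", "smallest standard
  deviation of a set of common origin") and the z-factor formula are
  under-specified in the source description; each concrete choice above is
  an interpretation and is configurable.
- No multiple-testing correction is applied anywhere (none was applied in
  the original analysis); with 60 biomarkers and 10 subjects, the ROC
  summaries are exploratory by nature.
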