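# Methods

## Fluctuation measures

For a voxel time course of length `N` sampled every `TR` seconds, the
one-sided discrete Fourier magnitudes are `a_i = |rfft(x)_i|`,
`i = 0 … floor(N/2)`, with frequencies `f_i = i / (N·TR)` up to the
Nyquist frequency `1/(2·TR)`.  With the analysis band `[f_lo, f_hi]`
(default 0.01–0.1 Hz):

- `ALFF   = Σ a_i` over `f_lo ≤ f_i ≤ f_hi` (closed band edges),
- `fALFF  = ALFF / Σ a_i` over `0 < f_i ≤ f_Nyq`,
- `hfALFF = ALFF / Σ a_i` over `f_lo ≤ f_i ≤ f_Nyq`.

Conventions chosen here and their reasons:

- **DC is excluded everywhere.**  The zero-frequency coefficient encodes
  baseline intensity, not fluctuation; including it would make fALFF
  depend on the mean signal level and break its invariance under
  multiplicative gain fields.
- **Magnitudes are unnormalised one-sided `rfft` amplitudes without
  doubling.**  Any fixed convention cancels in the ratio measures and
  only rescales ALFF, which is standardised before use anyway.
- **Odd `N`:** the last one-sided bin is `floor(N/2)`; for even `N` the
  true Nyquist bin is included once.
- **No window, no padding** — plain FFT of the unmodified time course.
- A constant time course has an undefined ratio; fALFF/hfALFF return NaN
  (a flagged missing value) rather than a silent 0/0.

Maps are **standardised** (divided by the mean over in-brain voxels, so
the in-mask mean is exactly 1) and then smoothed with a separable
Gaussian (`σ = FWHM / (2√(2 ln 2))` per axis in voxel units, reflecting
boundaries, default FWHM 6 mm).  Standardisation precedes smoothing;
smoothing can move the in-mask mean slightly through edge effects, so
the `standardised` flag refers to the pre-smoothing operation.

Because fALFF and hfALFF are per-voxel ratios of magnitudes from the
same series, both are exactly invariant under any positive voxelwise
gain (receive-field/bias effects); ALFF scales linearly, and a bias
field can be divided out explicitly when one is available.

## Nuisance regression

Four regressor blocks are assembled per run:

- `detr` — constant, linear, quadratic trends on a time axis normalised
  to [-1, 1] (the normalisation keeps the basis well conditioned; only
  the span matters).
- `wm`, `csf` — the tissue mask is `probability ≥ 0.9` eroded by one
  voxel (6-connected); the block contains the spatial mean time course
  plus the first five temporal principal components of the voxel-demeaned
  data (covariance PCA, so strongly fluctuating voxels dominate — the
  components are meant to capture the dominant shared noise).  Six
  regressors per tissue.
- `rp` — the six realignment parameters, unmodified (no derivatives or
  expansions).

All non-trend blocks are orthogonalised against the polynomial trends
via a thin QR decomposition, whether or not the trend block itself
enters the design; a column lying entirely inside the trend span is
dropped with a warning.  Removal is ordinary least squares through a
QR-based solver (`lstsq`); the literal normal-equations form is kept as
a test oracle only.  Rank checks are performed on column-normalised
designs because the blocks mix units (baselines ~100 a.u., rotations
~1e-3 rad).  The residuals are identical whether the fit is done in the
time domain or, with the unitary DFT matrix, on the complex Fourier
coefficients — the cross-domain equivalence is verified to 1e-8 on
random instances, and it is the formal reason detrending touches every
frequency of the spectrum rather than just the slow bins.

The sixteen pipelines are the on/off combinations of the four blocks,
labelled `none`, `detr`, `wm`, `detr+wm`, …, `detr+wm+csf+rp` in a
stable order.

### Exploratory trends

Data-driven slow regressors are estimated from the non-grey time
courses: demean, reduce to `d = ceil(0.05·N)` temporal principal
components (N = time points; the 5 % rule is read as a fraction of time
points), then run a canonical correlation analysis between the reduced
series at times 1…N−1 and its lag-one shifted version.  The CCA is the
classical whitened-cross-covariance SVD with a 1e-10 ridge (scikit-learn's
iterative NIPALS variant is not the classical solution, so this is
implemented directly).  Canonical variates are reconstructed over the
full N samples by projecting the reduced data onto the first-set
weights, ranked by their empirical lag-one autocorrelation (descending;
canonical-correlation order breaks ties), and the top four form the
`expl` block.  Exploratory trends replace the polynomial block, are
used exactly as estimated, and nothing is orthogonalised against them.

### Phase-randomised surrogates

Surrogate regressor sets share, per repetition, one random phase vector
applied to every regressor's Fourier transform, with Hermitian symmetry
(DC and the even-N Nyquist bin stay real) so the surrogates are exactly
real-valued.  This preserves each amplitude spectrum bin-by-bin and —
because the phase rotation is common — every cross-spectrum, hence the
full inter-regressor correlation matrix, while destroying temporal
alignment with the data.  Default: 25 repetitions, results averaged.

## Group statistics

The primary statistic is the voxelwise one-sample t value
`mean / (sd/√n)` across subjects, computed on session-averaged
standardised maps (averaging uses all runs while keeping subjects the
unit of analysis); it reads as intersubject consistency of the
nonnegative fluctuation measure.  Pipelines are compared through percent
change relative to the no-regression pipeline and summarised as means
over grey-matter voxels (missing voxels skipped, contributing count
reported).  Marginal block effects average the percent change over the
eight pipeline pairs that differ only in the block of interest —
pairing, not pooling.  Test–retest variance is the unbiased
within-subject variance across sessions, averaged over subjects.
Zero-variance voxels yield missing values rather than infinities, and
all variances use the n−1 estimator.  A Bonferroni-over-voxels t
threshold is available as plumbing; it is deliberately conservative and
is not a random-field-theory family-wise correction.

## The synthetic data model

Each voxel time course is

```
bold = bias × [baseline_tissue
               + gm_signal                    (grey matter only)
               + physio                       (tissue-weighted)
               + tissue_noise                 (WM/CSF only)
               + gain_v · (drift + wander)
               + weight_v · motion
               + thermal noise]
```

on a small grid of three adjacent box compartments (default 18×16×10
voxels of 3 mm; ~55/25/20 % GM/WM/CSF shares, mirroring an in-brain
mask's tissue composition — the share matters because the
standardisation reference behaves differently when grey matter does not
dominate the brain mean).  Components, defaults, and what they emulate:

- **Grey-matter signal** — per-voxel independent processes with a
  `1/f^1.3` spectrum from the lowest resolvable bin up to 0.1 Hz,
  per-voxel amplitudes `1.0 × U(0.8, 1.2)` a.u. around a per-subject
  global factor `exp(N(0, 0.4))`.  Real low-frequency fluctuations are
  not brick-walled at 0.01 Hz; the sub-band tail is what the fALFF
  denominator absorbs, and the subject-level factor is the biological
  amplitude heterogeneity the standardisation step has to contend with.
- **Polynomial drift** — constant/linear/quadratic coefficients per
  subject `~ N(0, 0.5)` each, stable across a subject's sessions up to
  10 % session jitter, with a per-voxel spatial gain `U(0.5, 1.5)`
  (scanner drift is spatially heterogeneous).
- **Slow wander** — a non-polynomial process band-limited below
  0.95×0.01 Hz with subject-scaled amplitude (0.25 a.u. log-normal).
  Real drift is smooth but not an exact polynomial; the wander is the
  part polynomial detrending removes only approximately.
- **Physiological components** — sinusoids at nominal 0.05, 0.16 and
  0.2 Hz (a vasomotor wave and aliased respiratory/cardiac signatures)
  whose exact frequency is drawn per session within ±0.01 Hz (rates
  never sit exactly on a DFT bin), with session-varying amplitude and
  phase, coupled into GM/WM/CSF at weights 0.5/1.0/1.5.  CSF carries an
  additional per-subject pulsatility factor `exp(N(0, 0.5))`.
- **Shared tissue noise** — one broadband `1/f` process per non-grey
  tissue (0.4 a.u.), the shared aperiodic fluctuation that
  component-based (PCA) nuisance regression is designed to capture.
- **Motion** — realignment parameters are integrated Gaussian random
  walks (0.02 mm / 5e-4 rad steps, 2 % spike probability at 10× step);
  the motion-coupled signal is 0.7 × the mean of the z-scored
  parameters, entering each voxel with its own `U(0, 2)` weight
  (motion artefacts are edge-concentrated in real data).
- **Thermal noise** — white, 0.5 a.u. per voxel and time point.
- **Bias field** — smoothed white noise rescaled to [0.8, 1.25],
  constant across a subject's sessions.

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawn keys: subject-stable characteristics
(drift coefficients, amplitude map, coupling maps, bias field) come from
a per-subject stream, session-specific realisations from a per-session
stream, so any session can be regenerated independently and groups are
bit-reproducible.

Default study conditions: 20 subjects × 2 sessions × 128 time points at
TR 2 s.  At these sizes a full 16-pipeline comparison with surrogate
controls runs in a few minutes on one core.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis depends on —
band-limited signal against broadband artefact, shared low-rank tissue
noise, subject-stable versus session-varying components, multiplicative
gain — but not imaging physics: no k-space/EPI simulation, no slice
timing, no geometric distortion, no anatomical templates, and the
compartments are boxes, not anatomy.  Passing tests therefore show that
the *analysis* behaves as described on data with the assumed structure,
not that the assumed structure exhausts real scanner data.

Amplitude choices are calibrated for testability at desk scale (the
relative weight of artefact and signal determines whether 20 synthetic
subjects can expose the pipeline contrasts at all); they are loosely
realistic (drift and physio of order 1 % of baseline, GM fluctuations
~1 % with ~30–50 % biological amplitude spread) but not fitted to any
scanner.

## Direction-of-effect pattern

On the default group the package reproduces, and its acceptance tests
assert, the qualitative pattern that motivates the whole pipeline
comparison: full nuisance regression raises the grey-matter mean ALFF t
value and lowers test–retest variance; adding polynomial detrending on
top of WM+CSF+RP regression lowers the fALFF t value but raises the
hfALFF t value.  The mechanism is visible in the model: detrending
removes the sub-0.01 Hz content that the fALFF denominator uses to
absorb slow artefact and subject-amplitude differences, while hfALFF —
whose denominator never sees those frequencies — only benefits from the
removal of in-band drift leakage.

## Known limitations

- **Surrogate control at desk scale.**  With 128 time points at TR 2 s
  the sub-0.01 Hz subspace spans only two DFT bins (four real
  dimensions).  A 21-column surrogate design whose columns carry
  sub-band magnitude spans that subspace even after phase randomisation,
  so surrogate regression performs a real detrending-like cleaning; the
  phase diversity of the WM/CSF components likewise lets surrogates
  remove part of the genuinely shared physiological signal.  In a small,
  comparatively homogeneous synthetic group these effects are not
  negligible relative to real-regressor effects, so the surrogate
  control is substantially weaker here than on long, heterogeneous
  real-data cohorts; the corresponding acceptance test documents this
  honestly rather than relaxing the check.
- The detrending effects on fALFF/hfALFF are small by nature (they were
  single-digit percent on real cohorts of 23–82 subjects); with 20
  synthetic subjects their direction is stable at the default seed and
  across most, but not all, seeds.
- Bonferroni is the only multiple-comparison option; random-field-theory
  thresholds are out of scope.
- Bias-field *estimation* is out of scope; the pipeline only applies or
  removes a known field.
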