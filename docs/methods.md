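# Methods

This note documents the models, conventions and numerical choices behind
`psyfusion`: an analysis chain for paired drug/placebo EEG-fMRI
resting-state sessions, validated end-to-end on synthetic cohorts with
planted, recoverable effects.

## Study design emulated by the generator

Each synthetic subject contributes two 28-minute sessions (drug and
placebo) with the compound "injected" at the end of minute 8:

* parcel-level BOLD, 840 volumes at TR = 2 s over 112 regions
  (100 cortical regions assigned to the Yeo 7 networks - VIS, SM, DAN,
  SAL, LIM, FP, DMN - plus 12 subcortical regions, SC);
* 31-channel EEG at 250 Hz (10-20 montage including the midline chain
  Oz, POz, Pz, Cz, FCz), epoched in 2-s trials aligned to the TR grid;
* per-minute subjective-intensity ratings on a 0-10 scale;
* a per-region receptor-density map.

### BOLD factor model

Region *i* in network *k* mixes white, unit-variance latent factors:

    x_i(t) = a_i(t) f_k(t) + c_i P_pole(i)(t) + b_i(t) g(t) + sigma eps_i(t)

with `f_k` per-network factors, `g` a global factor and `P` one of two
*pole* factors: unimodal (shared by VIS/SM/DAN) and transmodal (shared by
SAL/FP/DMN). LIM and SC are bridge regions loading the average of the two
pole factors at 0.7 weight, which places them mid-way along the principal
gradient and keeps the similarity graph connected. Within each network
the loadings follow a deterministic core-periphery ramp (network loading
1.25 -> 0.75, pole loading 0.5 -> 1.5 across members), so connectivity
profiles grade smoothly across same-pole networks the way cortical
profiles do, rather than forming disjoint network blocks. Defaults:
within = 0.4, pole = 0.5, global = 0.25, noise sd = 1.

The mixed signal is convolved with a canonical double-gamma HRF
normalized to unit L2 energy before white measurement noise is added;
because all sources are white, this preserves the zero-lag correlation
implied by the mixing weights, so closed-form correlations
(`synthetic.expected_correlation`) are available for tests.

### The latent effect curve

Each drug session carries an effect level `e(t)`: the subject's
unquantized intensity curve (exponential rise with 0.7-min constant,
peak ~2 min post-injection, exponential decay with 8-min constant,
jittered per subject) multiplied by a smooth AR(1) modulation (30-s time
constant, 30% amplitude). Under placebo `e(t) = 0`. The same `e(t)`
drives every within-session effect:

* within-network coupling drops by up to 50% (`within_loss`);
* global coupling of transmodal regions rises by up to 90%
  (`global_gain`); in receptor-coupled cohorts the gain is proportional
  to receptor density instead;
* pole mixing rises to 0.4 (`pole_mix`), compressing the gradient;
* EEG alpha oscillator amplitude falls by up to 60%, delta and gamma
  rise by up to 80% (theta unchanged, beta -20%);
* reported intensity ratings are the quantized curve (integers 0-10,
  zero before injection; placebo is zeros with a rare isolated 1).

Because BOLD and EEG share `e(t)` within a session, multimodal coupling
analyses have a true within-subject association to find, not just a
shared group-mean time course. Effect sizes are synthetic: they were
chosen once so that every planted effect is comfortably recoverable at
n = 12, and they do not claim quantitative realism. What passing tests
show is that the chain recovers the *direction and coupling structure* of
such effects; they say nothing about effect magnitudes in real
pharmaco-imaging data, and the generator omits head motion, scanner
artifacts, physiological noise, non-stationary spectra and spatial
autocorrelation of real cortical maps.

All streams are keyed on `(seed, subject, condition, stream-name)`, so
any piece regenerates independently and bit-identically.

## Analysis conventions

* **Pairwise FC**: Pearson correlation over the analysis window
  (default: the 8 minutes after injection, 240 volumes), Fisher
  z-transformed with |r| clipped at 1 - 1e-7. Zero-variance regions
  propagate as missing. Censored volumes are excluded.
* **GFC**: per region, the mean off-diagonal z of its row; network GFC
  averages member regions; whole-brain averages all regions.
* **Dual regression / integrity**: stage 1 regresses spatial template
  maps (no intercept - the templates tile the parcellation) onto each
  volume; stage 2 regresses the resulting network series (plus
  intercept) onto each region. Integrity is the mean stage-2 PE over the
  network's members. Default templates are *graded* membership maps
  (linear 0.5-1.5 ramp over members, emulating unevenly loading
  canonical ICA maps). Purely binary maps are degenerate at parcel
  level: the member mean of stage-2 PEs then reproduces the stage-1
  regressor exactly and integrity is identically 1 whatever the data.
  Note also that noise-free dual regression is scale-self-normalizing:
  integrity responds to coupling-vs-noise and pattern mismatch, not to
  pure amplitude scaling.
* **Segregation**: ordered-pair GLM slopes between stage-1 network
  series, averaged over the two directions; simple pairwise regression
  by default (`partial=True` covaries the remaining networks).
* **Dynamic FC**: 22-volume (44-s) boxcar convolved with a Gaussian
  taper of sd 3 volumes (6 s) truncated at +-3 sd, renormalized to unit
  sum, stepped every volume; weighted Pearson correlation per window,
  Fisher z. Window centers are reported in seconds from scan start.
* **Covariates**: per-minute ratings are linearly interpolated to the
  window-center grid, then smoothed with the same 6-s Gaussian.
* **Mixed models**: random-intercept + random-slope Gaussian models per
  unit, fitted by profiled REML on per-group 2x2 sufficient statistics
  (Woodbury identity), optimized over the log-Cholesky of the scaled
  random-effect covariance with Nelder-Mead. Wald t on n_groups - 1 df.
  Fallback ladder on non-convergence: random-intercept-only, then OLS,
  each flagged. The backend is an internal contract pinned by tests:
  agreement with an independent REML implementation, unbiased slope
  recovery, and type-I error at most 7% at alpha = 0.05.
* **BH-FDR**: one shared step-up implementation; every corrected table
  records its family name and size. Degenerate zero-variance paired
  differences report p as the smallest positive float with a flag.
* **Cluster permutation**: two-sided cluster-forming threshold at
  pointwise p < 0.05 (t distribution); cluster mass = signed sum of
  member t values; inference compares |mass| to the permutation
  distribution of the maximum |mass|; the observed statistic counts
  toward the null, so p >= 1/(n_perm + 1). Channel clusters use a
  montage adjacency graph (neighbors within 2.1x the median
  nearest-neighbor distance, mean degree ~4-6, overridable by an edge
  table); temporal clusters are contiguous runs. Nulls: per-subject
  condition-label swaps (sign flips of differences), or per-subject
  independent circular rotations of the difference traces (rotating the
  difference is equivalent to rotating one condition), which preserve
  autocorrelation and spectrum.
* **Gradients**: row-wise top-10% thresholding of the z-matrix, cosine
  similarity between thresholded rows (negatives clipped to 0),
  anisotropic diffusion operator with alpha = 0.5, eigendecomposition
  via the symmetric conjugate. Scores are right eigenvectors referenced
  to the stationary vector and, at the default diffusion time 0, carry
  the multiscale scaling lambda/(1 - lambda) (the diffusion map summed
  over all walk lengths, as the standard toolbox computes at t = 0);
  t > 0 scales by lambda^t instead. Unscaled unit-norm eigenvectors
  would make the principal-gradient SD a constant 1/sqrt(n) for any
  input, leaving gradient compression unmeasurable. Disconnected
  affinity graphs warn and restrict to the largest component.
  Individual embeddings are aligned to the group template (embedding of
  the element-wise mean affinity) by orthogonal Procrustes without
  scaling; residual sign indeterminacy resolves toward positive
  correlation with the template. Compression is operationalized as the
  range and SD of principal-gradient scores per subject and condition.
* **IRASA**: resampling factors 1.1-1.9 in steps of 0.05 (rational
  approximations, `resample_poly`), Welch spectra with 4-s Hann windows
  and 50% overlap, geometric mean of each h / 1/h pair, median over
  factors = fractal; oscillatory = total - fractal evaluated over
  1-45 Hz, kept as a signed residual (clipping optional). 2-s epochs are
  concatenated into blocks (default the 8-min baseline and post windows)
  because single epochs cannot resolve delta.
* **LZ76**: exhaustive-history parsing where the copy window may extend
  into the current phrase; signals binarized per 2-s epoch at the epoch
  mean with ties mapping to 1. A brute-force oracle defines the
  convention; the production parser (bytes.find based) and a compiled
  batch parser are pinned to it exactly. Raw phrase counts and the
  normalized variant (count * log2 n / n) are both reported; LZs is the
  per-channel epoch mean, LZc the channel mean of LZs.
* **Traveling waves**: 1-s windows stepped by 500 ms; the five midline
  channels are stacked occipital -> frontal into a 2D map; after a 2D
  FFT, the maxima of the two off-axis quadrants (temporal frequencies
  1-45 Hz) quantify forward and backward power. With numpy FFT
  conventions and this stacking order, forward (occipital -> frontal)
  power lands in the negative-spatial/positive-temporal quadrant; this
  orientation is fixed by a planted-wave calibration test. Output is
  10 log10(observed / surrogate mean) per direction, with surrogates
  from 100 electrode-order shuffles. Waves faster than the spatial
  Nyquist of the 5-electrode chain (frequency x per-channel delay >=
  0.5 cycles/electrode) alias and cannot be decoded by construction.
* **EEG -> BOLD fusion**: per-measure electrode selection takes the
  top-|t| electrode of the strongest cluster plus its contralateral
  mirror (midline pairs with itself; |t| ties break to the
  lexicographically smallest label). Per-epoch traces are cleaned
  (> 5 SD outliers linearly interpolated; missing epochs masked, never
  interpolated), band-passed 0.01-0.08 Hz (zero-phase order-2
  Butterworth), convolved with the canonical double-gamma HRF (peak 6 s,
  undershoot 16 s, ratio 1:6, 32-s support, unit integral), smoothed
  with the 6-s Gaussian and resampled to the window-center grid; windows
  within one filter length (16 s) of an edge or nearest to a missing
  epoch are masked and never enter fits. The mixed model keeps the EEG
  trace as the response and the region's dynamic-GFC difference as the
  predictor (swappable by flag). The 5-SD outlier rule applies
  per-condition before differencing.

## Problem sizes used in validation

The planted-effect recovery study (`psyfusion.recovery`, also run by the
acceptance script and `analysis/08_recovery_study.py`) repeats the full
chain over 20 independently seeded default cohorts (n = 12 subjects,
full-length sessions). Within each repetition the package's analysis
scale is: dynamic FC stepped every 3 volumes; the EEG arm uses a
10-channel montage subset, 3 IRASA resampling factors (1.2, 1.5, 1.8)
and 4-min spectral blocks. These are analysis-resolution choices for the
repeated validation study - the generator and its effect structure are
the full defaults - and the single-run analysis drivers under
`analysis/` use the complete montage, the full factor set and 1-volume
steps. Type-I-error checks run 200 repetitions x 500 permutations;
mixed-model calibration runs 50 recovery and 500 null fits.

## Known limitations

* Latent factors are white; real BOLD and EEG have autocorrelated,
  non-stationary sources. The circular-rotation null is therefore easier
  here than on real data.
* The generator plants sinusoidal oscillators with deterministic band
  frequencies; real spectra have variable peak frequencies (the fixed
  8-13 Hz alpha window inherits that caveat).
* Receptor-map significance uses region-label permutation, which does
  not preserve spatial autocorrelation; autocorrelation-preserving
  nulls are a noted extension.
* Parcel-level gradients (112 units) stand in for vertex-level
  embeddings; the algebra is identical but the unit count is not.
* No artifact model: EEG cleaning, motion scrubbing and nuisance
  regression are assumed done upstream (inputs may carry censor masks
  and bad-epoch sets, which all stages respect).
* EEG-BOLD fusion sensitivity: at the default effect sizes and n = 12,
  per-region alpha-fusion slopes carry the planted (negative) sign in
  the large majority of regions and concentrate in transmodal networks,
  but individual regions rarely survive BH-FDR over 112 units - the
  windowed dynamic-GFC predictor is noisy and attenuates per-region t
  values. The within-subject mixed model still dominates the
  averaged-trace between-subject correlation by a wide margin (tested),
  which is the property the design is meant to demonstrate.
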