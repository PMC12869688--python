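# Methods

`ssmap` reconstructs, as a tested pipeline on synthetic data, an analysis
style used for intraoperative intracranial recordings in movement-disorder
surgery: build a *canonical* group-level spatio-spectral map of oscillatory
power and cortico-subcortical coherence, quantify how individual patients
deviate from it, and ask whether those deviations — rather than the shared
pattern — carry the clinical signal.

## Signal model and preprocessing

Recordings are multichannel local field potentials from an 8-contact
subdural ECoG strip spanning the central sulcus (CS) and a 4- or 8-contact
DBS lead (STN or GPi), sampled at 1,375 or 2,400 Hz for 3–5 minutes of rest
against a scalp reference.

Preprocessing follows the acquisition pipeline exactly:

1. **Band-pass 2–120 Hz** (read from the printed "lowpass and high pass
   filter at 2 and 120 Hz" as high-pass 2 / low-pass 120, the only
   physically sensible pairing), realized as a zero-phase 4th-order
   Butterworth, plus zero-phase second-order IIR notches at 60 Hz (and
   120 Hz below Nyquist). Q = 10 gives > 20 dB rejection within ±0.5 Hz of
   the line after the bidirectional pass while keeping the 4–96 Hz passband
   within 0.5 dB.
2. **Artifact handling**: full-wave rectification → first difference →
   5-point median filter; samples where this processed trace exceeds 5 SDs
   of its own recording-wide distribution are flagged (the source text
   leaves open whether the SD is of the raw or the processed trace; we
   threshold the processed trace and note the alternative). Flags closer
   than 10 ms merge into spans; each span is replaced by the straight line
   joining anchors `round(2 ms × rate)` samples outside it. Note the
   5-point median filter *deliberately* suppresses single-sample derivative
   blips; only transients whose large derivative persists for ≥ 3 samples
   are treated as artifacts.
3. **Bipolar montage**: adjacent-contact differences. A DBS lead with n
   contacts yields n−1 channels (contact i − contact i+1, ventral→rostral);
   the 8-contact ECoG strip yields 7 channels (anterior − posterior,
   posterior→anterior order), or the 3-channel anatomical montage S1 (two
   contacts posterior to the CS), M1 (the two straddling it), PM (the two
   anterior). Both ECoG montages are provided; the 7-channel adjacent
   montage is the default for maps, matching the 7 × 7 pairing geometry
   used downstream.

## Spectral estimation

PSDs use Thomson's multitaper estimator: 1-s consecutive non-overlapping
windows, half-bandwidth ±2 Hz, hence NW = 2 and 2NW−1 = 3 Slepian tapers,
evaluated on the 1-Hz grid 4–110 Hz (107 bins). Spectra are normalized to
total power excluding 58–62 Hz (the only line band inside the grid; the
first harmonic lies outside it). The aperiodic background is modeled in
semi-log space as

    log10 P(f) = b − log10(k + f^χ)

with offset `b`, knee `k ≥ 0` (Hz^χ units) and exponent `χ ∈ (0, 10]`,
fitted by bounded least squares from a grid of (k, χ) starting points, with
a second robust pass that masks bins whose positive residual exceeds 1 SD
(narrowband peaks) and refits. The printed knee form `k + f^χ` is
implemented verbatim; the more common `k^χ + f^χ` variant is available via
`knee_form`. The fitted curve is subtracted in log10 space
("aperiodic-adjusted" spectra, which may be negative); band powers (alpha
8–11, low beta 12–20, high beta 21–35 Hz, closed bins) are means over
aperiodic-adjusted bins by default, with the raw-PSD variant one flag away.

Magnitude-squared coherence uses the same window/taper settings:
msc = |Sxy|² / (Sxx·Syy) with cross- and auto-spectra averaged over all
windows × tapers. Coherence is computed on raw bipolar signals (aperiodic
removal has no analog for cross-spectra). **Maximum-coherence pairing**
reduces the 7 × 7 = 49 pair spectra to one per primary channel: the partner
with the highest mean msc over the closed 12–35 Hz band wins, ties breaking
to the lowest (most ventral / most posterior) partner index.

A practical caveat we document rather than hide: when the aperiodic model
is fitted to spectra that went through the 2–120 Hz acquisition filter, the
filter's rolloff near 110 Hz tilts the upper fit range and inflates the
recovered χ (visible in `analysis/02`). The exponent round-trip accuracy of
the estimator itself (±0.15) is therefore measured on unfiltered simulated
backgrounds, where the estimator and generator meet on equal terms.

## Statistics

**Spatial-permutation pixel test.** The null hypothesis is "no spatial
organization": each permutation independently shuffles the channel rows of
every subject's map (frequency axis intact) and recomputes the group mean;
1,000 permutations give per-pixel μ_null and σ_null, and
Z = (X_true − μ_null)/σ_null with p = 2[1 − Φ(|Z|)]. Pixels with
σ_null = 0 are undefined and leave the multiple-comparison family.

**Correction chain.** Benjamini–Hochberg at α = 0.05 (the printed step-up
condition omits α; we use the standard `p(k) ≤ kα/m`), then **blob
correction**: 4-connected components of the significance mask survive only
if they span ≥ 2 distinct electrodes *and* contain ≥ 3 consecutive 1-Hz
bins on at least one channel row. Permutation p-values use the plain r/N
convention as printed, with the (r+1)/(N+1) variant behind a flag.

**Specificity.** Pixelwise two-sided Wilcoxon rank-sum maps between
cohorts (asymptotic by default, exact available), corrected by the same
BH + blob chain; plus MVPA: maps flattened to feature vectors,
standardized with training-fold statistics only, linear SVM (C = 1,
precomputed-kernel formulation for speed — identical decision function),
stratified 10-fold CV, and a label-permutation test re-running the entire
CV per shuffle.

**Consistency.** Pixelwise one-sample signed-rank tests of subject values
against the grand average; per-subject deviation rates using 1-s segment
maps as within-subject replicates (the replicate unit is our design choice
— the source leaves it unstated); pointwise in-sample 95% percentile
intervals with a channel-shuffled control and a paired signed-rank
comparison; Pearson correlations of each subject with the grand average and
between all subject pairs. Two calibration facts the tests encode: (a) the
in-sample pixelwise signed-rank test is *strongly conservative* — centering
on the sample mean removes nearly all variance of the statistic, so "no
significant pixels" is the expected outcome for a consistent cohort; and
(b) the per-pixel percentage of subjects flagged at α = 0.05 is ~5%, but
the *maximum* of that percentage over 749 pixels of a 75-subject cohort has
expectation ≈ 14% (max of 749 Binomial(75, 0.05) proportions) — the ≤ 14%
"high consistency" summary is a statement about this maximum.

**Clinical linkage.** Pixelwise OLS of map values on 8 predictors (years
since diagnosis, UPDRS III total, six lateralized sub-scores) with overall
F-test p, BH across pixels (per-coefficient variant behind a flag);
variance-hotspot Z-tests against channel-shuffled null variance maps;
pixelwise Pearson correlation with the UPDRS total; selection of the
top/bottom 10% of pixels by cross-subject variance (⌈0.1·749⌉ = 75 pixels,
deterministic tie-break in channel-frequency order; at fraction 0.5 the
bottom set shrinks by one pixel so the halves partition the 749-pixel map);
and two-block PLS (NIPALS, via scikit-learn, X and Y columns z-scored) with
a 10,000-iteration permutation of the clinical rows, per-LV
p = Σ[r_perm ≥ r_obs]/N, the 95th-percentile rule, and BH across LVs as the
final gate. Score *correlations* are not monotone across deflation steps
(verified empirically), so "LV1 dominates" is asserted only under planted
dominant coupling.

**Subtyping.** PCA of flattened maps retaining components to 80% cumulative
variance; gap statistic over k = 1..10 with B = 50 uniform bounding-box
references (gap(k) = mean log W_ref − log W_obs, k* = argmax, with a
repeat-and-average mode that yields fractional average k); k-means with 10
k-means++ restarts; one-way MANOVA (Wilks' lambda) of the six sub-scores by
cluster and per-target ANOVAs (sub-scores, total, age, years since
diagnosis) with BH across targets; and the robustness simulation: 1,000
iterations of single-initialization k-means (k = 2..10) each followed by
MANOVA + ANOVAs, reporting the percentage of significant iterations per
(k, test).

## Synthetic cohorts

The generator is first-class code, not a fixture. Map-mode subjects are

    template + cluster signature + hotspot deviation + i.i.d. pixel noise,

where the cortical template has an anterior beta peak (Gaussian bump
centered 21.5 Hz, SD 1.8 Hz), a posterior alpha peak (9.5 Hz) and a small
posterior 16.5 Hz beta peak; GPi adds ventral low beta to uniform high
beta; STN weights high beta mid-to-ventral. Hotspot deviations are driven
by latent severity factors that also generate the clinical table
(scores = base + C·z + noise, clipped at 0 and rounded to UPDRS-style
integers), so brain–behavior coupling is linear and known. An "ET-like"
cohort attenuates beta-band peak amplitudes to 25%. Default pixel noise SD
is 0.15 log10-units against peak amplitudes ≤ 1 — chosen once as a
realistic single-subject spectral uncertainty at ~200 one-second windows.
Randomness is one RNG stream per subject keyed by (master seed, subject
index), so cohorts are reproducible independent of cohort size.

Time-series mode emits monopolar traces whose adjacent differences equal
target bipolar signals: spectrally shaped white noise matching
`10^b/(k + f^χ)` (clamped below 2 Hz — a knee-free power law diverges
toward DC, which is unphysical and would leak into the analysis band
through finite windows; the clamp sits a full half-bandwidth below the
lowest analysis bin), plus Gaussian-envelope narrowband oscillations, plus
shared beta-band sources injected into chosen cortico-subcortical pairs so
their coherence rises monotonically with the coupling weight. A common-mode
drift plus 60 Hz line is added to every contact (removed by differencing
and the notch, respectively). Artifact injection plants multi-sample
ramp transients of stated amplitude at known indices.

What the generator does *not* emulate: non-stationarity (bursting),
tremor-band activity, volume-conduction geometry, electrode localization
error, or non-Gaussian clinical score distributions. Passing tests
therefore certify the statistical machinery and its calibration, not
physiological validity on real recordings.

## Problem sizes

Calibration experiments run at the study's own scale where cheap (75
subjects, 7 × 107 maps, 1,000-permutation nulls) and at reduced permutation
counts where the production 10,000 iterations would add nothing but wall time (PLS
type-I checks at 300–500 permutations; MVPA calibration at 200 shuffles ×
200 datasets). The FDR calibration runs at the full 1,000 permutations:
at a 200-permutation reduction the Φ-based p-values inherit visible
estimation error in σ_null and the measured family-wise level creeps to
≈ 0.055, an artifact of the reduction rather than of the method.

## Known limitations

- The EDF interface is read/write via a float32 binary + JSON sidecar
  container only; no EDF writer is bundled.
- The in-sample signed-rank consistency test is conservative by
  construction (see above); a leave-one-out variant of the CI containment
  is available by flag but the in-sample variant is the default, matching
  the source wording.
- MANOVA falls back to p = 1 for degenerate groupings (k = 1, singleton
  clusters, rank-deficient responses) rather than failing.
- 3-D cortical surface projection is out of scope; visualization is 2-D
  heatmaps.
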