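# Methods

`cordfc` implements a cross-modal analysis of spinal-cord functional
architecture: seed-based resting-state BOLD connectivity between gray-matter
compartments, stimulus-evoked BOLD/LFP/spike responses, resting-state LFP
coherence connectivity, and the group statistics that compare the two
modalities.  Because the original animal recordings are not distributed with
the package, every pipeline is exercised end to end on a synthetic-data
module whose generative model is documented here, together with the design
choices that were genuinely open.

## The analysis model

### Resting-state BOLD connectivity

Connectivity between two ROIs is the mean of the Pearson correlations
between ROI A's mean time series and each voxel series of ROI B.  Before
correlation, each run passes through:

1. **2D rigid motion correction.**  Each slice of each volume is aligned to
   the reference volume by the in-plane rigid transform (dx, dy, θ)
   maximising the mutual information (MI) of a 32-bin joint intensity
   histogram.  Both images are Gaussian-presmoothed (σ = 1 voxel) for the
   cost evaluation and the moving image is binned with linear
   partial-volume weights; both measures keep the MI cost smooth at
   sub-voxel scale, which matters because realistic cord motion is a
   fraction of a voxel.  Optimisation starts from an FFT cross-correlation
   shift estimate and refines with Powell's method.  (A coarse grid search
   over ±3 px / ±5° was evaluated during development; it was ~3× slower at
   identical accuracy on injected-transform fixtures, so the
   cross-correlation initialisation is the default.)  Translation recovery
   on the synthetic runs is ~0.02 px r.m.s.; rotation, which the nearly
   circularly symmetric cord constrains only weakly, is ~0.1–0.2°.
2. **Nuisance PCA regression** (CompCor-style).  Principal components of
   the muscle + CSF voxel-by-time matrix; the component count is the
   smallest k whose cumulative variance reaches 70%, clamped into [3, 5]
   and to the matrix rank.  Components, slice-wise motion parameters and
   their squares (the squared terms absorb the nonlinear part of
   resampling artifacts) enter a voxel-wise OLS GLM; residuals keep the
   fitted intercept so percent signal change stays defined.
3. **Band-pass 0.01–0.1 Hz**, Chebyshev type II (order 5, 20 dB stop band,
   stop-band corners at 0.4× the lower and 1.3× the upper pass-band edge),
   applied forward–backward per voxel with the temporal mean restored.
4. **Quality gates.**  Runs whose mean gray-matter tSNR (temporal mean over
   linearly detrended s.d.) is below 50 are flagged; activation and
   correlation maps pass a cluster filter (4-connected, in-plane only,
   minimum size 2) against single-voxel effects.  The gate uses the mask
   mean and is evaluated on the motion-corrected, unfiltered series.

The evoked pipeline uses steps 1–2 only: the 0.01–0.1 Hz band-pass removes
the DC offset and the higher harmonics of the 1/60 Hz block response and
distorts the epoch-average course, so it is treated as a
resting-connectivity step.

### Depth profile and the functional intermediate-GM seed

On one side of the cord, 1-voxel-deep ROIs (2–5 voxels wide) run from the
dorsal to the ventral gray-matter edge.  The profile of seed correlations
by depth is classified after 3-point moving-average smoothing: **U-shaped**
if it falls from the superficial depths to an interior minimum by ≥ δ and
rebounds by ≥ δ (δ = 0.05 — a design choice; no canonical numeric
criterion exists); the functional intermediate-GM seed is the smoothed
argmin (ties toward the shallower depth).  Profiles that fall without the
rebound are *monotone* and take the anatomical fallback (the central-canal
depth); flat or irregular profiles are *other*.  Group profiles average
runs after shifting each run's IGM depth to zero, dropping relative depths
with fewer than 6 observations.

### Electrophysiology

LFP preprocessing: zero-phase notch filters (second-order IIR, Q = 30) at
60/120 Hz — plus the first five respiration harmonics for resting data —
followed by a zero-phase Butterworth band-pass (order 5, 1–150 Hz).
Evoked responses are quantified as the percent power change between the
20 s after and before each stimulus onset, summed over the Welch bins
(Hamming, 10-s windows, 50-ms overlap) nearest the first five harmonics of
8 Hz, normalised so the largest channel equals 1.  The unusually small 50-ms
overlap (0.5% of a window) follows the experimental convention and is
exposed as a parameter.
r.m.s. courses use 0.25-s bins against a 3-s pre-onset baseline; spike
summaries use 1-s rate bins, 0.005-s peri-event bins and the same baseline.
Spike detection band-passes 250–5000 Hz and takes negative-going crossings
of −4× the r.m.s. with a 1-ms dead time (a design choice).

Resting connectivity is the magnitude-squared coherence
C(f) = |Sxy|²/(Sxx·Syy) from Welch auto/cross spectra (2-s Hamming windows,
50% overlap — ~900 segments in 15 min, keeping the ~1/K estimator bias
below 0.002), averaged over a broadband range.  The averaging band is a required
configuration choice; the default is 1–100 Hz,
excluding bins within 1 Hz of any notched frequency.  The dorsal seed per
shank is the channel with the greatest evoked power change (ties toward
the shallowest contact); the intermediate-GM channel is the contact
nearest 1 mm from the seed on the same shank (ties toward the deeper
contact).  Pair classes: within-segment seed–seed (DD_within), seed–IGM
per shank (D_IGM), across-segment seed–seed (DD_across), and same-depth
contralateral pairs down to 1.5 mm.  Classes observed in a single subject
can be flagged and excluded from group statistics.

### Group statistics

Two-sided Mann–Whitney U tests (exact null up to a combined n of 12
without ties, tie-corrected normal approximation beyond), Bonferroni–Holm
correction for the primary comparisons and Benjamini–Hochberg for the
depth profile.  Dorsal-to-IGM observations from the left and right
hemi-cord are concatenated before testing.  Cross-modal agreement is the
Pearson correlation of the two modalities' pair-class means;
per-subject agreement is an OLS regression of per-subject BOLD correlation
on LFP coherence.  Significance tiers for report annotation:
p < 0.05 (*), < 0.0005 (**), < 0.00005 (***) after correction.

## The synthetic-data generator

### Geometry

A 32 × 32 × 5 label volume at 0.25 × 0.25 × 3 mm: a gray-matter butterfly
(dorsal horn 3 voxels wide × 4 deep, intermediate GM 4 × 3 with a
commissural bridge, ventral horn 5 × 5, mirrored left/right) inside a
white-matter ellipse, a CSF ring, and muscle filling the field of view.
Each slice stands for one spinal segment.  Five slices cover the imaged
middle segment and its neighbours.

### BOLD model

Gray-matter voxel signal (percent of baseline):

    s(t) = σ_lf · [ a·L_s(t) + b·M_{s,h}(t) + n_v(t) ] + σ_w·w(t) + physio + evoked

* `L_s` — one unit-variance latent per slice shared by both dorsal horns,
  correlated across slices as c^|Δs| via an AR(1) chain (within- and
  across-slice dorsal–dorsal connectivity).
* `M_{s,h}` — a per-slice, per-side latent shared by the dorsal horn and
  the ipsilateral intermediate GM (loading b on both).
* Ventral-horn voxels load `a_v` on `L_s`, producing the ventral rebound of
  the U profile (designed seed–VH correlation 0.50).
* `n_v` — unit-variance idiosyncratic voxel noise.  Latents and `n_v` are
  spectrally synthesised flat in 0.02–0.08 Hz, inside the analysis pass
  band, so the band-pass neither creates nor destroys designed
  correlations; `w` is white thermal noise.
  Defaults σ_lf = 0.25%, σ_w = 0.2% of baseline give a gray-matter
  fluctuation amplitude of ~0.6% and tSNR ≈ 170 (comfortably above the
  gate, as high-field surface-coil acquisitions are).
* Physiological components (default 0.3, 1.17, 2.4 Hz, aliased by the 3-s
  TR) load strongly (2%) on muscle/CSF with random per-voxel sign and
  weakly (0.1%) on gray matter — the structure the nuisance PCA is meant
  to find and the GLM to remove.  The respiration frequency is a config
  value rather than a fixed constant.
* Evoked runs add a gamma-variate HRF (shape 6, scale 0.9 s — a canonical
  form; no spinal HRF is established) convolved with the stimulus boxcar,
  normalised to unit plateau so `evoked_amplitude_pct` (default 0.76) *is*
  the plateau percent change, in the ipsilateral dorsal horn, with 40% of
  that amplitude contralaterally (contralateral responses are reliably
  weaker; the 40% fraction is a design choice).
* Tissue baselines GM 100 / WM 96 / CSF 125 / muscle 75 (low GM/WM
  contrast as in T2*-weighted images); static muscle texture (12% s.d.,
  1-voxel correlation length) supplies the angular structure real
  anatomy has, without which sub-voxel rotation cannot be registered.
* Rigid in-plane motion: white per-volume translations (σ = 0.1 px) and
  rotations (σ = 0.1°) applied to the whole cord.

**Calibration.**  For a seed of m voxels the model's seed-mean-to-voxel
correlations have closed forms, e.g.
r_DD = a²/√(v_m·v_d) with v_m = a²+b²+(1+ε)/m and v_d = a²+b²+1+ε, where
ε is the white-noise variance surviving the band-pass (computed from the
designed filter's |H|⁴ response).  The loadings solve these equations for
the targets divided by measured end-to-end pipeline gains
(0.950 / 1.031 / 1.006 for DD-within / D-IGM / DD-across, from a 15-run
ensemble): motion-correction resampling mixes seed-edge voxels with
zero-loading white matter and attenuates seed pairs by ~5%, while the
seed-mean variance shrink slightly inflates the D-IGM estimate.  The
across-slice decay is the ratio of the (gain-corrected) across and within
targets.

### LFP model

Channels (4 shanks × 16 contacts at 150 µm; shanks 0–1 in one segment,
2–3 in the next; dorsal seed designed at contact 2, giving contact 9 as
the 1-mm IGM contact) are built from processes spectrally flat across
0.75–101 Hz: a per-segment dorsal latent (across-segment correlation ρ),
a per-shank seed↔IGM latent, and *band-limited* channel noise sharing the
same spectral support — with matched supports the coherence equals the
squared spectral correlation, so loadings solve the same fixed-point
system as the fMRI generator with r = √C and no pipeline-gain correction
is needed (measured recovery is within 0.001 of the targets).  Non-seed
channels load the segment latent with an exponential depth falloff
(500 µm), giving the contralateral same-depth profile its decay.  On top:
60/120 Hz line noise, a 0.5-Hz respiration artifact with 5 harmonics
(both common across channels, hence removed from coherence by the notch
exclusion), and during stimulus-on blocks an 8-Hz oscillation with
harmonics (amplitude × 0.5^(k−1)), sharpest at the seed contact and 3.3×
weaker on non-stimulated shanks (digit selectivity).  Spike trains are
piecewise-homogeneous Poisson: 5 Hz baseline, 40 Hz during on blocks on
the stimulated channel.

### What the generator does *not* emulate

No MR physics (susceptibility, distortion, slice profiles), no spike
waveform biophysics, no cardiac ballistic motion, no across-run anatomy
changes, no partial-volume mixing beyond interpolation, and motion is
white rather than respiratory-locked.  Passing tests therefore show that
the *pipeline recovers the designed statistical structure under realistic
noise, physiology and motion*, not that it would survive every artifact of
real cord imaging; conversely, the per-subject regression and the
U-shape prevalence of real animals are properties of the animals' data and
are deliberately not reproduced.

## Numerical choices and degenerate inputs

* Registration of a zero-contrast slice returns identity with a warning;
  optimisation is bounded at ±3 px, ±5°.
* Rank-deficient GLM designs drop collinear columns (rank-revealing QR)
  with a warning; zero-variance voxels get a tSNR sentinel (10⁶) and are
  excluded from gate means.
* `classify_profile` tie-breaks argmin toward the shallower depth;
  `select_igm_channel` toward the deeper contact; `select_dorsal_seed`
  toward the shallower contact.
* Coherence requires ≥ 8 Welch segments (a single segment is identically
  1); band means exclude notched bins ± 1 Hz.
* All zero-phase filters are SOS cascades applied with `sosfiltfilt`.
* Exact vs approximate Mann–Whitney switches at combined n = 12.

## Problem sizes

The bundled studies run at full group scale:
15 resting runs × 300 volumes, 7 evoked runs × 7 epochs, 4
electrophysiology subjects × (10-epoch evoked run + 15-min resting
recording at 500 Hz).  A full resting run takes ~25 s on one core
(motion correction dominates); the complete acceptance computation is
~15 minutes.

## Known limitations

* Rotation estimates from MI on a near-circular cord are noisy (~0.2°);
  their artifacts are largely absorbed by the motion regressors but set
  the floor on connectivity recovery accuracy.
* The pipeline-gain constants are measured for the default geometry,
  motion level and ROI definitions; recalibration is needed if those
  change materially.
* The exact Mann–Whitney path requires tie-free data; tied small samples
  fall back to the tie-corrected normal approximation.
* `align_profiles` assumes a common depth spacing across runs (true for
  the generator's fixed geometry).
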