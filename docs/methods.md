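# Methods

This note documents the models, algorithms, default parameters and known
limitations of the package, in the order the pipeline applies them.

## Volume conductor and forward model

The head is a five-shell concentric-spheres conductor: white matter, grey
matter, CSF, skull, scalp. Defaults are infant-scaled — radii 58, 60, 62,
65, 70 mm and conductivities 0.33, 0.33, 1.79, 0.04, 0.33 S/m. A neonatal
scalp radius of ~70 mm and a relatively conductive infant skull motivate
these values; all are configurable, and none is clinically critical to the
package's conclusions (the acceptance surface is built on synthetic data
generated with the same model).

The dipole potential is the classical Legendre-series solution: per degree
`n` the radial profile in every shell combines `r^n` and `r^-(n+1)`,
matched by continuity of potential and radial current density across
boundaries, with zero radial current through the scalp. Numerics: the
per-degree transfer coefficients come from a 9x9 linear solve with
shell-normalized radial powers (no overflow up to the 200-term cap);
Legendre values use the stable three-term recurrences for `P_n` and
`P'_n`; the series stops adaptively when the last term contributes less
than 1e-8 relative at every electrode. In the equal-conductivity limit the
result matches the closed-form homogeneous-sphere solution to better than
1e-6 relative (tested).

Electrodes follow the idealized geometric 10–20 construction (10/20%
steps on the nasion–inion and ear-to-ear arcs, the 72°-inclination
circumferential ring, F3/F4/P3/P4 on great-circle midpoints). The
21-channel variant adds Fpz and Oz, which lie on the sphere; earlobe
electrodes do not and are not modeled.

The source space is a cubic lattice clipped to the brain interior with a
safety margin of half a spacing. The default spacing is 8 mm (~1300
points): at 10 mm the projected-power blob of the bilateral medial
precuneus pair is occasionally sampled at a midline lattice point ~18 mm
from either true source, while 8 mm sampling keeps the discrete maximum
within one spacing of a node.

## Synthetic burst-suppression generator

The generator is the package's ground truth; it emulates the structure of
clinical burst-suppression EEG in neonates:

- **Nodes.** Ten dipoles: brainstem (mid-brain tegmentum, (0,−25,−15) mm)
  and thalamus ((0,−15,10)); bilateral precuneus, somatosensory,
  prefrontal and occipital nodes placed at 50 mm radius along their
  anatomical directions (the brain sphere is 58 mm, so cortical sources
  sit near the surface). Precuneus orientations are mesial
  (±x-dominant), as appropriate for sources on the medial parietal wall;
  this also prevents the bilateral pair from masquerading as a single
  midline source, because their correlated component then produces a
  left–right antisymmetric scalp pattern that no midline dipole can
  explain.
- **Dynamics.** A stable VAR(3) at a 32 Hz model rate driven by
  innovations band-passed to 1–4 Hz (zero-phase 4th-order Butterworth),
  upsampled to the 512 Hz sensor rate. One model lag is 31 ms, so the
  lag-1/lag-2 couplings give physiological 31–62 ms conduction delays.
- **Burst network.** Directed: brainstem→thalamus (0.8),
  thalamus→precuneus (0.45 per side), a direct brainstem→precuneus
  arousal projection (0.30) — the ascending reticular system projects to
  cortex both through and past the thalamus, and without the direct branch
  the two-lag-removed brainstem–precuneus coherence would be ~0.02,
  undetectable by construction — precuneus→somatosensory (0.35),
  precuneus→prefrontal (0.30) and somatosensory→prefrontal (0.30),
  ipsilaterally, plus 0.3 self-damping. Occipital nodes are silent in
  bursts.
- **Suppression network.** Cortical nodes only (deep nodes silent), with
  weak symmetric couplings (0.18–0.32) between neighbouring regions and a
  homotopic precuneus–precuneus term; no directed edges exist by
  construction.
- **Moments.** Relative dipole moments: precuneus 2.6 (burst) / 2.2
  (suppression), somatosensory 0.75/0.70, prefrontal 0.60/0.55, occipital
  0/0.80, thalamus 2.4, brainstem 2.2. The precuneus dominance encodes
  the study condition that the strongest delta source is parieto-medial
  in every subject; deep moments are several-fold larger than cortical
  ones because a subcortical source must be strong to remain visible
  through 19 scalp electrodes — an assumption that any claim of
  EEG-detectable deep generators implies.
- **Background.** 80 random dipoles throughout the brain carry
  independent delta-band noise scaled to 10% of each phase's network
  band power. Spatially distributed brain noise is what bounds the
  adaptivity of covariance-based spatial filters on real EEG; without it
  a minimum-variance beamformer cancels correlated sources essentially
  completely and its coherence maps degenerate.
- **Calibration.** Each burst's noiseless scalp peak-to-peak is drawn
  from 210–290 μV (inside the clinical 150–350 μV band); the suppression
  source scale is set so the burst/suppression delta-band power ratio is
  37.5 dB, the midpoint of the clinically reported 35.85–39.09 dB range,
  with suppression peak-to-peak verified below 25 μV. White sensor noise
  (0.2 μV) is added last. Burst/suppression segment durations are drawn
  from 2–4 s; 26 cycles give ≥70 s of each phase so that 60 s survive
  relabeling.
- **Cohort.** Per-subject node jitter (≤5 mm, clipped to the brain) and
  ±10% amplitude jitter, with per-subject seeds spawned from one master
  seed.

What the generator does **not** emulate: biophysical burst-suppression
mechanisms, non-stationarity within phases, ECG/movement artifacts,
electrode-position errors, or skull inhomogeneity. Passing tests
therefore demonstrate correctness of the analysis chain under a
physically plausible linear forward model — not clinical performance.

## Phase segmentation

Samples are classified by sliding-window (0.25 s) peak-to-peak amplitude:
burst if any channel reaches 30 μV in the window, suppression if all
channels stay below 25 μV. The burst threshold sits far below the
clinical 150 μV floor because a quarter-second window sees only part of a
slow delta swing; it must only stay above the suppression ceiling. Each
labeled run is trimmed by half a window at both ends (the centered window
overreaches true boundaries by up to that much). Segments are
concatenated earliest-first to exactly 60 s per phase; fragments shorter
than one spectral epoch are skipped and the joins are recorded so that no
spectral epoch straddles a splice.

## Spectra

One-second epochs, demeaned, tapered with the first K=3 Slepian sequences
at time–bandwidth NW=2 (±2 Hz smoothing, appropriate for a 1–4 Hz band),
Fourier transformed and averaged over epochs and tapers into a one-sided
cross-spectral density with 1 Hz resolution (Parseval-checked
normalization; `S_xy = E[conj(X) Y]`, so a delayed second channel shows
negative phase). The band matrix for beamforming is the unweighted mean
of the CSD over the integer bins 1–4 Hz. Pooled spectra normalize each
channel by its total power before averaging. The relative SNR is the
channel-summed band-power ratio of burst over suppression, in dB.

## Source analysis

DICS spatial filters `A(r) = (L^H C_reg^{-1} L)^{-1} L^H C_reg^{-1}` are
built from the band CSD with Tikhonov loading `λ·trace(C)/N`, λ=0.05.
Source power is the dominant eigenvalue of `Re(A C A^H)`.

*Reference selection* uses the scalp-projected power `P(r)·||L(r)u||²`
(power times the squared oriented lead-field norm): raw minimum-variance
power peaks at the head centre through noise amplification, and the
noise-normalized index (power over filter noise gain) is biased against
strongly connected hubs because their filters carry large
interference-cancelling weights. The projected form is a purely
geometric depth correction and recovers the generating source in both
regimes (verified on single-dipole and full-network simulations).

*Coherence maps* reduce the source cross-spectrum `A(r₁) C A(r₂)^H` by
its dominant singular pair and divide by the auto-powers projected on the
same orientations; this is the orientation choice that the coherence
itself selects and avoids the systematic underestimation produced by
using the maximum-power orientations.

*Source iteration.* The reference signal is extracted once; candidate
sources are scanned with filters that carry zero-gain constraints at all
previously accepted sources' model topographies (leakage from, and
minimum-variance cancellation against, an accepted source cannot then
masquerade as a new one). Each step's map is compared with a Monte-Carlo
null in which the reference's one-second epochs are shuffled against the
sensor epochs (destroying exactly the alignment under test while
preserving all spectra and the fixed analysis operator); scanning stops
when no grid point outside 20 mm exclusion spheres exceeds its 0.99 null
quantile, or at 8 sources.

*Extraction* for the connectivity stage uses multi-constraint rows: unit
gain at the own source, zero gain at every other identified source, built
on the real part of the band CSD — the extracted signals then carry no
mutual zero-lag leakage. Sensor data are band-passed 1–4 Hz (zero-phase)
first. Filter signs are canonicalized (first significant weight
positive).

### A structural limitation, documented deliberately

With 19 electrodes, detecting *deep coherent* sources in the presence of
much stronger cortical sources is at the edge of what the measurement
supports, and the package does not pretend otherwise. Two effects verified
both analytically and numerically in this code base:

1. At the minimum-variance optimum, every scan filter subtracts the
   projection of its output onto the dominant source's signal (the cost
   is second order), so output coherence with the reference vanishes for
   any source whose topography is spatially separable — independent of
   that source's strength.
2. Heavy regularization disables this subtraction but makes the smoothed
   filters' leakage coherence at *silent* deep locations as large as true
   deep coherence during bursts, destroying burst/suppression
   specificity. No intermediate regularization resolves the conflict, and
   hard spatial nulls broad enough to remove the residues blind the scan
   within ±25 mm of each nulled source.

Consequently the pipeline recovers the reference region and its
suppression-phase specificity very reliably, recovers cortical coherent
sources partially, and does not reliably recover the thalamic and
brainstem sources; the corresponding acceptance checks are left failing
rather than weakened.

## Connectivity

Extracted source signals are anti-alias decimated to 32 Hz (two zero-phase
FIR stages), then fitted by least-squares MVAR with BIC order selection
(cap 20, shrunk when data are short; order forced ≥2 in the decision
pipeline so the renormalization covariance is full rank).

Renormalized partial directed coherence for the pair j→i stacks the real
and imaginary parts of `Ā_ij(f) = −Σ_k a_k,ij e^{-iωk}` into
`Z_ij(f)` and forms `λ_ij(f) = Z^T V^{-1} Z` with `V` the estimator
covariance of `Z` (per-equation residual variance times the inverse
regressor moment matrix, rotated by the lag cosines/sines; rank-aware
pseudo-inverse with matching χ² degrees of freedom). Under no influence λ
is asymptotically χ²(2); the pointwise 99% threshold's empirical type-I
error on independent noise is ~0.008 (tested at 200 replicates).

Three significance stages gate an edge, all at α=0.01:

1. band-mean λ above the χ² threshold;
2. band-mean λ above a data-driven bootstrap threshold (1 s blocks
   resampled *independently per channel*, destroying cross-channel lag
   structure; 100 resamples in the test presets, 1000 recommended for
   analyses);
3. the time-reversal test: the asymmetry contrast
   `θ = (λ_ij − λ_ji)_forward − (λ_ij − λ_ji)_reversed` must keep its
   α-quantile above zero under *joint* block resampling (all channels
   together, preserving the coupling), and the raw asymmetry sign must
   flip under time reversal. True lagged influences flip; zero-lag
   (volume-conducted) mixtures do not; symmetric bidirectional coupling
   fails the quantile bound. A decoupled null for θ is degenerate
   (under it both λ are small and θ≈0, so any real bidirectional
   coupling would pass), which is why the joint resampling is used.

An edge is accepted only if all three stages pass.

## Surrogate source statistics and contrasts

`surrogate_source_threshold` reorders one-second epochs independently per
channel, rebuilds the band CSD under the observed filters and reference,
and takes the 0.99 quantile (linear interpolation) of the null maxima of
off-reference coherence. For channel-independent recordings this shuffle
is distribution-preserving, so the null is exact; the observed maximum's
p-value uses the add-one permutation convention.

The Friedman two-way rank ANOVA (mid-ranks, standard tie correction,
χ²(k−1) reference; k=2 supported) compares per-subject mean source power
and mean pairwise extracted-signal coherence between phases; the package
reports the direction and p-values.

## Problem sizes in the test and acceptance presets

Simulated recordings are ~160 s at 512 Hz and 19 channels; analysis
segments 60 s per phase; the source grid ~1300 points; surrogate and
bootstrap counts 100 (50 where a rate is estimated over many runs);
recovery rates use 20 seeded runs in the test suite and a configurable
count (default 10) in the acceptance script; the cohort preset analyzes
13 subjects. These sizes were chosen so a full desk run completes in
minutes while keeping every Monte-Carlo tolerance meaningful.
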