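# Methods

`nanofoci` quantifies homologous-recombination repair at collapsed
replication forks from multi-channel single-molecule localization microscopy
(SMLM) data. This note records the models the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, the numerical choices, and known limitations.

## Pipeline model

A nucleus is analyzed as a 2D projection. Input is a localization table
(x, y in nm, frame, channel, intensity, precision) per color channel, plus a
manually drawn nucleus ROI polygon. Stages:

1. **Localization** (optional, when starting from raw frames). Candidate
   emitters are local maxima of a lightly smoothed, background-subtracted
   frame; each is refined by a least-squares elliptical 2D Gaussian fit.
   Background mean and s.d. are estimated per frame on a 2 × 2 µm window
   centered at the minimum-intensity pixel, which keeps emitters out of the
   noise estimate. Accepted fits satisfy FWHM ≤ 640 nm (geometric mean of
   the two axes) and SNR > 3 with SNR = fitted amplitude / background s.d.
   Candidates closer than one fitted FWHM are jointly rejected rather than
   fitted as multi-emitter models. The per-localization precision is the
   Thompson-style σ/√N with N = 2π·amp·σₓσᵧ used as a photon proxy; it is a
   relative quality score, not a calibrated uncertainty, because camera gain
   is not modeled.

2. **Chromatic registration.** Fiducial beads imaged in each channel are
   matched across channels by mutual nearest neighbors (500 nm gate), and a
   total-degree-3 bivariate polynomial (10 monomials per axis) is fitted by
   least squares mapping each channel onto the red/far-red reference. The
   design matrix is centered and scaled for conditioning; coefficients are
   reported in raw nm coordinates. Fits on noiseless synthetic warps of
   degree ≤ 3 recover the warp to machine precision; with 100 beads and 3 nm
   per-axis noise the median residual is ~3 nm (well under the 10 nm
   practical requirement). Localizations outside the convex hull of the
   training beads are corrected but flagged `extrapolated`.

3. **Rendering and segmentation.** Localizations are binned on a 20-nm-pixel
   grid (counts mode; a Gaussian precision-spread mode is also provided).
   Pixels are 0-based with half-open [k·20, (k+1)·20) nm bins. Per channel,
   an Otsu threshold is computed from the in-ROI pixel histogram — zeros
   included, since the empty interior is genuinely background in sparse
   SMLM renders and excluding it would inflate the threshold — and
   above-threshold pixels are labeled into 8-connected clusters (no minimum
   size; connectivity configurable). Cluster centers of mass are
   intensity-weighted, in nm; area = pixel count × 400 nm².

4. **Monte Carlo colocalization.** For a channel pair within one nucleus,
   overlap is measured either as the number of fixed-channel (naDNA)
   clusters intersecting ≥ 1 partner cluster, or as the total pixel area of
   the mask intersection. The protein channel's clusters are then each
   rigidly translated — no rotation — to a position drawn uniformly over all
   translations that keep the mask fully inside the ROI (rejection sampling
   over ROI pixels; relocated clusters may overlap each other). The
   coefficient is the real overlap divided by the mean over 20 such
   randomizations, computed with deterministic per-simulation sub-seeds.
   If the simulation mean is zero the result is flagged
   `insufficient-randomization-overlap` and excluded from population means
   rather than reported as infinite. Count mode is the default for MRE11,
   BRCA1, CtIP, and BLM; area mode for γH2AX, RPA, RAD51, RAD52, and BRCA2
   (accumulating factors).

5. **Population statistics.** Per (condition, timepoint) group: mean,
   s.e.m., and a Welch two-sample t test against the reference condition,
   with an ε-variance guard for degenerate zero-variance groups and the
   conventional significance tiers at 0.05/0.01/0.001/0.0001. Group means
   assemble into a protein × timepoint heatmap matrix.

6. **Focus classification and intrafoci distances.** Each naDNA cluster is a
   candidate focus; a protein is present if any of its clusters intersects
   the naDNA mask or lies within 250 nm (center of mass to center of mass).
   The 250 nm default matches the spatial scale of individual repair foci;
   it is configurable. Foci with no protein are counted but not recorded.
   For a protein pair, foci are classified A-only / B-only / both; the
   package also reports prevalence (fraction both), directional dependence
   (fraction of B-positive foci that are A-positive), and an exclusion flag
   when P(both) falls below the independence product P(A)·P(B). The
   exclusion/dependence/prevalence descriptors are this package's
   operationalization of those concepts; they are simple plug-in estimators
   without multiplicity control. At double-positive foci, the distance
   between the two proteins' centers of mass is measured, where each
   protein's center is the intensity-weighted center over *all* its
   associated clusters — robust to one physical structure segmenting into
   fragments, which would otherwise bias distances short if a single nearest
   fragment were used.

7. **Distance-distribution fits.** Distances are histogrammed at 10 nm and
   fitted by least squares on bin centers with Poisson weights taken from
   the model expectation (an unweighted pass seeds the expectation, one
   reweighted pass refines it; weighting by *observed* counts biases the
   fitted width low by ~3%). The single model is A·exp(−(x−c)²/2s²); the
   double model fixes component 1 at the 135 nm / 75 nm FWHM reference with
   free amplitude and leaves component 2 fully free. `model="auto"` adopts
   the double model only when it cuts the residual sum of squares by > 50%
   and an F test at α = 0.05 favors it. Classification: a single center in
   [97.5, 172.5] nm is proximal, > 180 nm distal, the gap (172.5, 180] and
   centers below 97.5 nm indeterminate, accepted double fits mixed. The 2D
   likelihood map expands each component into a circular ridge (radius =
   center, Gaussian cross-section of the component FWHM, height ∝
   amplitude, normalized to 1); it is a presentation aid, not an estimator.

Throughout the package FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ.

## Synthetic-data generator

No public localization data exist for these experiments, so validation runs
on seeded synthetic scenes with recorded ground truth.

- **Nucleus scenes.** An elliptical (default 10 µm circular) ROI contains
  `n_nadna_foci` naDNA clusters at uniform positions (centers inside the
  ROI; cluster tails may cross the boundary, as real foci touch the nuclear
  envelope). Per protein channel, a configurable fraction of clusters is
  attached to class-eligible foci — displaced by a distance drawn from the
  displacement model in a uniform random direction — and the rest are
  uniform. A cluster's member localizations are an isotropic Gaussian of
  s.d. = radius/2 around its center plus isotropic precision noise
  (channel defaults 9.5/9.3/17.7 nm for red/blue/green). Per-cluster
  localization counts are log-normal (shape σ = 0.4, floor 3) with mean 150:
  fluorophores re-blink across the 2000-frame acquisition, so one protein
  cluster accumulates on the order of 10² localizations; this density is
  what makes Otsu segmentation operate in its intended regime (threshold
  above single stray localizations). Background localizations are uniform
  in the ROI at 1 µm⁻² per channel (Poisson count). Cluster radii are
  uniform in 40–100 nm. The count and size distributions are assumptions —
  stated in the config, not taken from measured data.

- **Focus populations.** For classification studies, foci are laid out on a
  jittered grid (1.5 µm pitch) in a rectangular ROI so each focus is
  identifiable in isolation. Each focus samples a class from a named mixture
  (e.g. `{"RPA-only": 0.714, "both": 0.221, "RAD51-only": 0.065}`). A lone
  protein is displaced from the focus center by the displacement model; a
  colocalized pair is placed symmetrically about the center, separated by a
  model draw, so the pair's center-of-mass separation follows the model
  exactly while both partners stay within the association radius.

- **Bead fields.** Reference-channel beads are uniform with ≥ 2 µm spacing
  (unambiguous matching); the second channel is a degree ≤ 3 polynomial warp
  of the reference plus isotropic Gaussian noise.

- **Raw frames.** Each molecule renders as a 2D Gaussian PSF of configurable
  FWHM carrying a Poisson photon budget over constant background. No
  blinking kinetics, duty cycles, EM-gain statistics, or 3D/astigmatic PSFs.

What passing tests on these scenes shows: the pipeline recovers known
mixtures, displacement distributions, warps, and enrichment levels under
idealized, well-separated, in-focus conditions. What they do not show:
robustness to labeling stochasticity, blinking-induced over-counting,
overlapping foci, chromatic residuals varying across the field, or
out-of-focus light — all present in real data.

## Null calibration of the coefficient (small-sample behavior)

`coloc.csr_null_experiment` places both channels' clusters uniformly at
random inside the ROI (the randomizer's own null) and computes the
coefficient per nucleus. With the default geometry (10 µm ROI, 50 clusters
of 40–100 nm radius per channel) the expected overlap is only ~21 px,
arriving in ~2 discrete cluster-intersection events per nucleus, and ~14–16%
of nuclei have zero real overlap. In this sparse regime the per-nucleus
coefficient X/Ȳ is heavily skewed: the per-nucleus s.d. is ≈ 1.1, so the
mean over 100 nuclei has a sampling s.d. of ≈ 0.11, and the skew of the
20-simulation denominator inflates its expectation by several percent
(package measurement over 1100 nuclei: ≈ 1.07–1.09; an exact continuum
computation of the same experiment gives 1.016 ± 0.020, the remainder coming
from 20-nm pixel quantization). The ratio of *means* across nuclei —
total real overlap over total simulated mean — is unbiased (measured 0.975).
Practical consequence: a single 100-nucleus CSR calibration scatters within
roughly ±0.2 of 1; interpreting per-nucleus coefficients near 1 requires
either denser scenes (as real nuclei are, with hundreds to thousands of
clusters) or many more nuclei. The acceptance script reports this
calibration at the 100-nucleus scale.

## Problem sizes and determinism

Test and acceptance runs use: 100 nuclei for the CSR calibration; 100 beads
for mapping; 500 distance draws for fit recovery; 2000 foci per mixture for
classification recovery; scenes of 10–50 foci elsewhere. All randomness
derives from explicit integer seeds via `numpy` SeedSequence spawning
(per-nucleus and per-simulation sub-seeds), so identical configurations
reproduce outputs bit-for-bit; every pipeline output records the seed and a
configuration hash.

## Known limitations

- 2D only; no drift correction; single-emitter fitting only.
- Otsu on a counts render is sensitive to overall localization density;
  extremely sparse channels can segment stray background localizations as
  clusters (flagged by unrealistically low thresholds).
- The overlap "number" statistic counts fixed-channel clusters with ≥ 1
  intersecting partner (not pairs or intersection components).
- Randomization is translation-only and requires full containment in the
  ROI; clusters larger than the ROI erode the feasible region noticeably.
- Dependence/exclusion/prevalence descriptors are plug-in estimates with no
  uncertainty quantification.
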