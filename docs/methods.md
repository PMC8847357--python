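# Methods

`rncfret` implements the analysis side of a solid-support FRET screen for
conformational changes in ribosome-bound nascent chains (RNCs), together
with a forward simulator that generates plates with known ground truth.
This note records the models, the defaults and why they were chosen, and
what the synthetic data do and do not establish about real instrument data.

## The measurement model

One FRET value comes from a matched pair of wells carrying beads coated
with donor-only (D) or donor+acceptor (D+A) RNCs. Energy transfer quenches
the donor, so efficiency is the fractional loss of donor signal,

E_FRET (%) = (1 − F_DA/F_D) × 100,

with F_D and F_DA the mean background-subtracted per-area bead intensities
(AU/µm²) of the two wells, averaged over beads that pass the selection
gates. Acceptor emission is not used. E is reported signed and unclamped:
compounds that brighten the D+A channel produce negative values, and the
screen's hit classes include FRET decreases. Compounds are run in
duplicate (two pairs, four wells); the duplicate average halves the
variance of a single pair.

In solution, F_D and F_DA are the mean of the five highest emission
intensities (the CFP peak near 475 nm) after subtracting a matched
non-fluorescent blank, each divided by that sample's RNC concentration
from ¹⁴C scintillation counting. Dividing by concentration is the only
normalization that makes D and D+A comparable when stop-codon readthrough
yields differ between the two translations; it also makes the result
invariant to any constant offset shared by a sample and its blank.

## Image analysis

Stages, in order:

1. **Flat-field correction.** A single smooth illumination surface per
   plate — a least-squares fit of the nine `{1,x,x²}×{1,y,y²}` terms to
   non-bead pixels pooled over a sample of wells (default 8), subsampled
   on a 7-px grid. The surface is normalized to mean 1 before division, so
   correction preserves the global intensity scale and the FRET ratio is
   invariant to any overall rescaling of both channels (this mirrors the
   observation that two vendor software versions scale intensities
   differently without changing FRET).
2. **Background and noise.** Median and 1.4826×MAD of non-bead pixels,
   computed on a 2-px-subsampled grid after one round of outlier
   rejection. The median's standard error at these pixel counts is far
   below 0.1 AU.
3. **Segmentation.** Threshold the 1-px-Gaussian-smoothed image at
   background + k·σ (k = 3 by default; for noiseless synthetic images the
   threshold floor is 0.1% of the dynamic range, keeping the operation
   scale-invariant), fill holes, label 8-connected components, and
   attempt a distance-transform watershed split on any component larger
   than the largest admissible single bead. Unsplit merges are still
   removed by the circularity gate (a figure-eight of touching disks has
   4πA/P² ≈ 0.5).
4. **Gates.** An object passes if it does not touch the image edge, its
   equivalent-circle diameter 2√(A/π) lies in 16–23 µm, its circularity
   4πA/P² (Crofton perimeter) exceeds 0.93, and its mean per-area
   intensity exceeds a floor (default 2× the background noise SD per µm²).
   Gates are checked in the order edge → diameter → circularity →
   intensity and every rejected object is reported with the first gate it
   failed, which makes the ~10% unusable-data figure auditable from the
   per-bead table. Equivalent-circle diameter (rather than a caliper
   width) is robust to boundary noise; the Crofton perimeter keeps
   rasterized disks above the 0.93 gate at 0.325 µm/px where a
   marching-squares perimeter would push them below it. Its corner
   smoothing reports ~0.91 rather than the ideal π/4 ≈ 0.785 for a square
   — still comfortably rejected.
5. **Quantification.** Per-bead intensity is the background-subtracted
   pixel sum over the object's *measurement mask* divided by that mask's
   area in µm². The measurement mask is the 4-px-eroded interior of the
   threshold mask: the soft anti-aliased rim plus the worst-case
   smoothing-driven mask inflation (~2σ of the smoothing kernel) never
   enter the mean, so the per-area intensity — and therefore the D/D+A
   ratio — does not depend on where the threshold happens to cut each
   channel's edge profile. Shape features still use the full mask.
   Defocused beads spread their flux and are caught by the diameter gate
   in bright wells and by the intensity floor when dim.

## Plate statistics and decisions

* **DMSO baseline.** Per plate, the mean and sample SD (n−1 throughout)
  of the vehicle-control pair E values (n = 32 by default), plus the mean
  donor intensity and background of the control wells. All hit thresholds
  are per-plate: plates are imaged hours apart and their baselines drift.
* **QC gates.** A compound is usable only if *every* donor well's mean
  bead intensity lies strictly within 0.9–1.1× the baseline donor mean
  and *every* well's background is below 1.2× the baseline background.
  Gating each well individually (not the duplicate mean) is the stricter
  reading and the one implemented.
* **Hit rule.** |duplicate average − baseline mean| > 3 SD *and* both
  single values beyond 1.75 SD on the same side as the average, QC
  passing. The same-side requirement is imposed because an average pushed
  past 3 SD by one wild single is exactly the artifact pattern the
  singles condition exists to remove. The joint rule's null rate is far
  below the naive 2Φ(−3) ≈ 0.27%; the test suite checks it against a
  brute-force Monte-Carlo oracle at ~10⁵ compounds.
* **Assay window.** Z′ = 1 − 3(SD_P + SD_N)/|Mean_P − Mean_N|. With
  control SDs of 0.7% and 0.6% E_FRET, separations above 7.8% (→ 8% in
  practice) give Z′ > 0.5.
* **Per-plate descriptors.** CV = 100×SD/mean of the control E values;
  signal-to-background compares the *raw* (background-inclusive) mean
  donor bead intensity with the background, both in per-area units — the
  convention under which the screen's ≈2.6 ratio is reproduced.
* **Dose–response.** 4-parameter logistic
  r(x) = bottom + (top−bottom)/(1+(EC50/x)^hill) by least squares;
  starting values from the data (plateaus from the extreme doses, EC50
  from mid-response interpolation, hill = 1), EC50 bounded to
  [min dose/10, max dose×10], hill to [0.1, 10]. The fit is declared
  unconverged for flat data, optimizer failure, a fitted span below twice
  the residual RMS, or an EC50 beyond the top dose (plateau unsampled).

## The synthetic screen

The generator's defaults are the screen's operating conditions: 1,536-well
format; 600 beads/well of which a single image covers 19% (a 2048² field
at 0.325 µm/px, ≈0.44 mm² ≈ 19% of a 1.53-mm-square well, expecting ≈114
beads); bead diameters 17 ± 1 µm truncated to 16.5–22.5 µm (gravity
segregation into the 16–23 µm window); per-bead brightness CV 10% (a free
choice — the source data only establish that 17-µm beads vary less than
larger ones; 10% reproduces the observed plate-level E_FRET CV of ~3–4%);
3% defocused beads blurred with σ = 4 µm; elongated artifact objects
(axis ratio 3, minor axis 6–10 µm) at 5% of the bead count; a parabolic
illumination field of 15% amplitude; background 200 AU/px; Gaussian read
noise of 10 AU (Poisson shot noise optional — read noise dominates at
these exposures); donor bead amplitude 324 AU above background, which
fixes signal-to-background at ≈2.62; baseline true E_FRET 29% (the
destabilized-mutant construct the screen was built around); and 10% of
compounds carrying an optical artifact, half perturbing donor intensity
(×0.70–0.85 or ×1.15–1.30), half raising background (×1.3–1.8), so the
QC gates remove ≈10% of the library. With these defaults the per-pair E
SD is ≈0.9–1% absolute — the plate behaviour the hit rule assumes.

Beads render as uniform disks with a soft 1-px edge. The analysis uses
mean per-area intensity, which is independent of the radial profile, so a
projected-sphere profile would add realism without changing any tested
quantity. Bead centres keep a pairwise distance of 1.05× the mean of the
two diameters — a settled, non-touching monolayer. (A fixed one-mean-
diameter separation would let two larger-than-average beads overlap and
merge at segmentation; the pairwise rule states the same monolayer
assumption without that artefact.) Defocused beads and artifacts share
the placement process.

Seeding is counter-based: every well draws from
`SeedSequence([seed, stream, well_index])` substreams (stream 0 =
plate-level effects, 1 = bead placement, 2 = rendering noise, 3 = the
statistical fast path), so any single well is reproducible in isolation
and plates are byte-identical across reruns.

**Statistical fast path.** Under the generator's own model the per-bead
measured intensity is Gaussian, so a well's mean over n beads is *exactly*
Gaussian with SD amp·CV/√n (plus a small pixel-noise term). The functions
`sample_measurements` and `simulate_screen_statistical` draw well-level
measurements directly from that law, skipping rendering. They assume every
imaged bead passes the gates (true up to edge effects at the default
geometry) and are used for plate-scale statistical studies — null
hit-rate calibration at 10⁵ compounds, power curves — where rendering
would be pointless. Anything that exercises segmentation itself (closure,
precision/recall, spiked-hit recovery, scale invariance) runs through
rendered images.

## What the synthetic data do not show

The generator emulates the statistical structure the analysis relies on,
not the instrument: no optical PSF or spectral bleed-through, no
bead-binding kinetics or storage effects, no spatial plate gradients in
compound effects, no liquid-handling failures, and compound artifacts act
as clean multiplicative factors. Passing closure tests therefore
demonstrates that the pipeline is internally consistent and correctly
calibrated under its stated assumptions — not that those assumptions
exhaust real microscope data.

## Problem sizes in the test suite

Test and acceptance runs choose sizes that keep the full suite in the
minutes range on one CPU while preserving the stated statistical power:
closure uses 5 well pairs per condition (≈480 beads per channel, above
the ≥400-bead requirement); segmentation fidelity uses 4 rendered wells
with the artifact rate at 10%; the null-rate calibration uses 313 × 320 ≈
10⁵ compounds through the statistical fast path; end-to-end spiked-hit
recovery renders a partially filled plate (20 compounds + 32 DMSO pairs =
144 wells) at full default resolution; dose–response recovery runs 200
noisy 6-point × 3-replicate simulations. Unit tests of mechanics
(determinism, I/O, gate logic) use a reduced 512² field with ~19 beads.

## Known limitations

* The effective bound-molecule concentration model (all bound molecules
  dissolved in the bead's own spherical volume, 3·density/(R·N_A)) gives
  0.29 µM at 500 molecules/µm² on 17-µm beads — a ~150-fold concentration
  over the 2 nM solution phase. Other reasonable volume conventions (e.g.
  a thin surface shell, or a smaller effective radius for a porous bead)
  shift this by tens of percent; the operation documents its convention
  rather than claiming precision beyond the model.
* Bead surface area is the nominal sphere (πd²); agarose beads are porous
  and their true capture area is larger, which is precisely why the
  geometric-saturation fraction is a conservative framing.
* Z′ is only as meaningful as the spread estimates fed into it: control
  sets summarized as 51.7 ± 0.7 vs 61.6 ± 0.6 give Z′ = 0.61 when the ±
  are SDs, but a visibly better value if they are SEMs of replicate
  means. `z_prime` takes explicit `ControlStats`, leaving that choice —
  and its documentation — to the caller.
* The 4PL fit reports an EC50 only when the dose range samples the
  plateau; screens whose top dose sits below the EC50 get
  `converged=False` rather than an extrapolated number.
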