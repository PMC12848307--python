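# Methods

This note documents the models, estimators and numerical choices behind
`vesselmech`, and what the synthetic-data tests do and do not establish
about real microscopy data.

## Strain decomposition

For any positive geometric quantity X measured at two developmental
stages, the strain is eps_X = (X2 - X1)/X1.  Vessel remodelling is
decomposed per axis into a cell-deformation part and a cell-number
(rearrangement/addition) part through the effective cell numbers

    N_eff_radial = pi * D / w      N_eff_axial = L / l,

where D and L are vessel diameter and length, and w = sqrt(a/r),
l = sqrt(r*a) are the radial width and axial length of a cell with area
a and aspect ratio r (aspect ratio is taken as axial/radial, so l is
the axial dimension).  Because N_eff is defined as a quotient, the
decomposition is an exact multiplicative identity:

    (1 + eps_D) = (1 + eps_w) (1 + eps_N,radial)
    (1 + eps_L) = (1 + eps_l) (1 + eps_N,axial)

The package computes strains from per-stage *group means* (cells are
not tracked across days; population averages per stage are compared),
and recomputes N_eff at each stage from that stage's mean D, L, w, l.
With this convention the identities hold to machine precision and are
enforced by tests at 1e-12 for biologically scaled inputs.  For extreme
ratios (X2/X1 of order 10^3 or more, far outside any vessel data) float
cancellation in 1 + eps grows the residual proportionally; property
tests scale their tolerance accordingly.

`label_mechanism` tags each component as contributing / opposing /
neutral relative to the vessel-strain sign with a dead-band tolerance
(default 0.02, a descriptive choice; the labels are narrative output,
not statistics).

## Vessel diameter from intensity profiles

A profile drawn perpendicularly across a fluorescently labelled vessel
shows two wall peaks.  The estimator:

1. Baseline = median of the outer 10% of samples on each side
   (robust; the endpoints are assumed baseline-dominated).
2. Wall peaks = the two most prominent local maxima with prominence at
   least `min_prominence` (default 0.2) of (max - baseline).
3. For each wall, the half-maximum level is baseline + 0.5*(peak -
   baseline); the two crossings are located by linear interpolation
   scanning outward from the peak, and the wall centre is their
   midpoint.
4. Diameter = distance between the two wall centres.

The centre-to-centre convention is unbiased by the thickness of the
membrane label and symmetric under mirroring; the estimator is exactly
invariant under affine intensity rescaling.  On noiseless synthetic
profiles it recovers the generator's wall-centre separation to better
than half a pixel; at additive noise of 5% of wall height it stays
within 2%.  At least three repeated measurements per vessel are
averaged (`mean_diameter` warns below three).

## Ablation recoil velocimetry

The ablation gap is tracked on a space-by-time kymograph.  Per time
column the gap edges are the inner crossings, nearest the intensity
minimum, of a threshold placed `threshold_fraction` (default 0.5) of
the way from the local minimum to each flanking maximum, interpolated
to sub-pixel precision; columns before the ablation frame, or without
at least 20% gap/flank contrast, are reported missing rather than zero.
The recoil velocity is the gap displacement over the first 10 s after
ablation divided by the elapsed time, which equals the mean per-frame
velocity for uniform sampling; a least-squares slope over the same
window is reported alongside as a cross-check, and the two agree to
0.02 um/s on the synthetic data.  Three line-ROI estimates per vessel
are averaged into the final value.

## Trace normalisation and junction/cortex ratios

Actin/myosin intensity traces are background-subtracted (mean of a
rectangular region), log10-transformed and max-min scaled to [0, 1].
Values at or below `floor_fraction` (default 1e-4) of the maximum are
clipped to the floor before the log, with a warning — background
subtraction can leave non-positive samples and the floor preserves
monotonicity.  The junction/cortex measure is
log10(mean(junction) - bg) - log10(mean(cortex) - bg) with bg the mean
of the background ROIs (defaults 6 junctional, 10 cortical, 2
background regions, all configurable); it is exactly invariant under a
common multiplicative gain.

## Cross-correlation lag

Pearson correlation on the overlapping samples at each integer-frame
shift, followed by parabolic refinement of the extremum (skipped when
the discrete peak is already a perfect correlation).  Positive lag
means the first series leads.  The estimator recovers integer-frame
lags exactly and generator lags within one frame at 10% noise.

## Actin-organisation classifier

The structure tensor (Gaussian gradient, sigma 2 px) is averaged over
the image; its anisotropy (l1 - l2)/(l1 + l2) is the orientation
coherence and its minor eigenvector the dominant stripe direction.
Coherence below `coherence_threshold` (default 0.2) is mesh (M);
otherwise a stripe direction within `angle_band` (default 30 deg) of
perpendicular to the vessel axis is circumferential (C), within the
band of the axis is longitudinal (L), and anything between is M.  On
generated striped/cross-hatch panels with orientation jitter the
classifier exceeds 90% accuracy; it is an explicitly approximate
automated stand-in for expert annotation and has not been validated on
real cortical actin images, where mixed and curved textures dominate.
Front/back views of one vessel combine to the ordered category
(C-M, M-L, C-L) when they disagree.

## The 2D actomyosin cortex model

A flat endothelial cell is modelled as a 2D rectangle, 8 um along the
circumferential axis (x, bounded) by 30 um along the longitudinal axis
(y, periodic).  Units are um, s, pN throughout; 2D stress in pN/um.

Components:

- **Filaments** - bead-spring chains (segment rest length 0.5 um, 2-6
  segments, mean 2 um) with polarity (bead order runs minus to plus
  end), harmonic stretching (20 pN/um) and an angular potential at
  interior beads giving a 10 um persistence length (kappa = kT * Lp).
  Excluded volume is neglected; filaments may cross.
- **Motors** - two heads that bind filament segments within a capture
  radius (0.1 um) at 5 /s, unbind at 0.5 /s, and walk toward the plus
  end at v = v0 * max(0, 1 - f_par/f_stall) with v0 = 0.2 um/s and
  stall force 4 pN, detaching when they pass the plus end (an option
  to dwell there instead is off by default).  Bound head pairs are
  coupled by a spring (20 pN/um, rest 0.1 um).
- **Crosslinkers** - as motors but immotile, with slower unbinding
  (0.1 /s).  A bound crosslinker additionally exerts a weak nematic
  torque aligning the two segments it bridges
  (E = -k_align (u1.u2)^2, k_align = 0.05 pN um), the coarse-grained
  signature of a bundling crosslinker.
- **Turnover** - free filaments are deleted and re-inserted uniformly
  at random at 1/30 s^-1 (an atomic operation, conserving the filament
  count), and polymerise/depolymerise at the plus/minus end at
  0.1 segments/s within the length bounds.  An option to protect
  heavily crosslinked filaments from turnover exists and is off by
  default.
- **Anchored filaments** - at most 1% of all filaments, 2 um long
  (about one fourth of the vessel width).  In circumferential mode
  they are pinned to the membranes in facing left/right pairs at
  matched y inside a central band (default 3 um tall), oriented inward
  along x; in midline mode they are pinned to fixed midline points and
  oriented along y.  The pin clamps the end segment (the two minus-end
  beads), fixing the filament's direction at the anchor; the distal
  part flexes.  Anchored filaments are exempt from turnover.
- **Membranes** (deformable mode) - bead chains along each vertical
  boundary (spacing 0.5 um, stretching 20 pN/um, bending 1 pN um^2),
  with a lateral elastic foundation (0.05 pN/um per bead) holding each
  bead near its rest x, endpoint beads pinned, and a large per-bead
  drag (10 pN s/um).  Free beads are confined by a one-way harmonic
  wall force from the instantaneous membrane line; anchored filaments
  transmit their net force to the membrane bead they are pinned to,
  which is how bundle tension constricts the membrane.  The
  drag/foundation quotient sets a membrane response time of ~200 s, so
  the membrane acts as a minutes-scale low-pass filter of bundle
  tension — the origin of the alignment-to-width lag.

### Integration and kinetics

Overdamped explicit Euler with dt = 5 ms, per-bead drag 0.5 pN s/um,
and thermal kicks of variance 2 kT dt / gamma (kT = 0.0042 pN um).
The kicks are variance-matched uniform deviates rather than Gaussians;
over the millions of steps of a run the summed displacements are
Gaussian to high accuracy, at half the per-step cost.  dt is validated
against the stiff-spring stability bound gamma/(4 k_max) = 6.25 ms.
Binding, unbinding, stepping, polymerisation, depolymerisation and
turnover fire with per-step probabilities 1 - exp(-rate dt) in a fixed
order from a single seeded stream, so runs are bit-reproducible per
(params, seed).  Unbinding is load-dependent (Bell slip bond,
rate * exp(f/f_d) with f_d = 4 pN) and link forces are clamped at
3 f_d; together with a per-step displacement cap of 0.1 um these keep
rare stacked-spring configurations bounded without affecting typical
dynamics.

### Readouts

- **Virial stress** sigma_ab = (1/A) sum over pairs of f_ij,a r_ij,b,
  restricted to pairs whose midpoint lies in a region, tensile
  positive.  The pair ledger contains the central-force interactions:
  filament stretch springs and motor/crosslinker link springs.
  Bending, the crosslinker alignment torque, anchor pins and wall
  confinement are not pairwise central forces and are excluded — the
  stress reported is the tension-bearing network component.  The
  time average is a 30 s sliding window.
- **Circumferential alignment** N_x^2 = sum of squared x-components of
  unit segment orientations over a region, with the segment count S;
  N_x^2 + N_y^2 = S identically and N_x^2/S = 0.5 for isotropy.
- **Vessel width** - mean left-right membrane gap over the central
  band (trapezoidal mean of the linearly interpolated chains).
- The **central region** is the full-width anchored band (bundles grow
  inward from the anchors, so the readout spans wall to wall);
  **bundle episodes** are maximal intervals with N_x^2/S above 0.65
  for at least 60 s (gaps under 10 s merged).  Width and alignment are
  linearly detrended before their cross-correlation, since slow drift
  from turnover would bias the lag.  For the headline lag estimate the
  per-replicate correlation curves are averaged before locating the
  most negative correlation (`width_alignment_corr_curve`): at the
  weak correlations of the reduced system a single run's arg-min
  scatters over the lag window, while the pooled curve estimates the
  common lag consistently.

### Parameter provenance and calibration

The geometry (8 x 30 um, 2 um anchored filaments at <= 1% of the
population, circumferential vs midline anchoring) follows the study
design this package implements.  All remaining constants are this
package's own calibration, chosen in the range of published
coarse-grained actomyosin models and then fixed: the kinetic rates
were set so that spontaneous bundling of the bulk mesh stays
subcritical (fast turnover, 1/30 s^-1) while the permanently anchored,
orientation-clamped filaments act as the only persistent nucleation
sites.  In this regime the anchoring direction controls the local
orientation response robustly (circumferential anchoring raises
N_x^2/S in the band; midline anchoring lowers it), while the stress
anisotropy sigma_xx - sigma_yy responds in the expected direction but
with seed-to-seed variability of the same order as the effect at the
reduced system size — see Limitations.

Presets: `paper_like` (400 filaments, 800 motors, 800 crosslinkers, 4
anchored) and `reduced_test` (200/400/400, 2 anchored — one per side,
preserving the facing-pair bridging geometry), identical physics
constants.

## Synthetic data generators

Every generator takes an explicit seed, is bit-deterministic given its
spec, and returns machine-readable ground truth with the data.  They
target the statistical structure each estimator assumes, not image
realism: wall profiles are triangle/Gaussian peaks plus white noise;
cell tables draw multiplicative noise truth*(1 + cv*z) so the standard
error of a mean is truth*cv/sqrt(n); kymographs are ideal dark gaps
with erf-smoothed edges widening at constant velocity; lagged series
are band-limited sums of sinusoids (so non-integer shifts are exact);
textures are sinusoidal stripes/cross-hatch with orientation jitter.
The default cell-shape trajectory emulates arterial-vessel remodelling
from 2 to 4 dpf: area shrinkage with moderate elongation, so that
radial constriction is driven by cell narrowing with a rearrangement
contribution, and axial elongation mainly by cell addition.
Passing parameter-recovery tests on these inputs demonstrates
estimator correctness under the stated noise models; it does not
validate performance against deconvolution artifacts, uneven
background, motion, or annotator variability in real microscopy.

## Known limitations

- The cortex model is 2D, without excluded volume, hydrodynamics, or
  signalling; membrane coupling of free beads is one-way (steric
  confinement exerts no reaction on the membrane; mechanical coupling
  is through the anchors only).
- At the reduced system size the virial stress in the central band is
  dominated by fluctuations of the surrounding mesh: the sign of the
  episode-averaged anisotropy follows the anchoring direction only in
  a majority of seeds, not uniformly, and the deformable-membrane
  constriction is correspondingly shallow (tenths of a micrometre).
- In the deformable runs the width-alignment anticorrelation is real
  but its dominant lag is width-leading: an inward membrane excursion
  brings the anchored tips closer and promotes bridging faster than
  bundle tension moves the slow membrane, so at this scale the
  feedback loop runs mostly in the reverse direction from the
  full-scale mechanism (alignment-led constriction), whose signature
  appears only as the weaker positive-lag shoulder of the pooled
  correlation curve.
- The bundle episodes of this model are briefer and weaker than the
  minutes-long, visually obvious episodes the full-scale system
  displays; the episode detector therefore often finds none at the
  default threshold, in which case downstream summaries fall back to
  whole-run averages.
- The orientation classifier is a global-texture method; it cannot
  represent vessels whose front and back differ within one view, and
  is not a substitute for expert annotation.
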