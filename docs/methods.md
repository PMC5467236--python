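# Methods

## The system being modelled

CaMKIIα assembles into holoenzymes of 12 (rarely 14) subunits.  A rigid
central hub complex (radius ≈ 55 Å) organises the particle; each subunit's
kinase domain (diameter ≈ 45 Å) is tethered to the hub by an intrinsically
disordered linker and therefore explores a continuum of positions.  In
negative-stain projection images the particles lie flat, so the geometry
is effectively two-dimensional: per subunit one measures a *kinase radius
of extension* (hub centre to kinase outer edge; centre-to-centre distance
plus a fixed 22.5 Å kinase-radius append) and a *clockwise neighbour
separation* (centre-to-centre).  Two minority states matter: transient
kinase–kinase dimers (neighbours within the 45 Å steric-contact
threshold) and a compact state with the kinase docked against the hub
(radius < 100 Å).

holoflex re-implements the quantitative analysis of such data — geometry
measurement, distribution statistics, pair classification, closed-form
physical models, sensitized-emission FRET correction and Hill
dose-response fitting — driven entirely by a calibrated synthetic
ensemble generator so that every stage is verifiable without
experimental data.

## The synthetic ensemble generator

### Calibration targets

The generator's defaults are chosen so the synthetic population
reproduces, at the population level, the published geometry statistics of
basal-state CaMKIIα holoenzymes:

| statistic | target | generator default |
|---|---|---|
| kinase radius mean ± s.d. | ≈127 ± 16 Å | mixture below |
| radius range | 77–175 Å | truncation supports |
| compact fraction (radius < 100 Å) | < 3 % | `p_compact = 0.025` |
| separation mean ± s.d. | ≈58 ± 15 Å | mixture below |
| separations < 45 Å | ≈20 % | pair categorical |
| particles with 0 pairs | ≈10 % | `P(0) = 0.10` |
| particles with 1–3 pairs | ≈60 % | `P(1)+P(2)+P(3) = 0.60` |
| particles with 6 pairs | ≈2.5 % | `P(6) = 0.025` |
| 14-mer fraction | < 4 % | `p_tetradecamer = 0.035` |

Radii come from a two-component truncated-Gaussian mixture: extended
N(127, 15²) on [100, 175] Å and compact N(88, 5²) on [77, 100) Å with
per-subunit compact probability 0.025.  A *single* Gaussian N(127, 16²)
would place ≈4.6 % of its mass below 100 Å, contradicting the < 3 %
compact fraction, which is why the compact class is a separate component.
The truncated extended component has analytic mean ≈128.2 Å and
s.d. ≈13.7 Å; mixed with the compact class this gives a population mean
≈127.2 Å and s.d. ≈15.0 Å, inside the validation bands (±1 Å on the
mean, ±1.5 Å on the s.d.).

Separations come from a second mixture with a hard support split at the
45 Å pairing threshold: paired N(36, 5²) on [20, 45) Å, unpaired
N(62.5, 11²) on [45, 110] Å.  The split makes threshold classification
recover the generated pair labels exactly in separation-explicit mode,
so pair-count recovery tests are pure multinomial-sampling tests.  Real
separations overlap the threshold; this idealisation is deliberate and
means the tests validate the classification pipeline, not threshold
robustness on real data.

Pair counts per 12-mer follow the categorical
(0.10, 0.25, 0.20, 0.15, 0.165, 0.11, 0.025) over 0–6 pairs.  The 0-,
1–3- and 6-pair masses are fixed by the published fractions; the 4- and
5-pair masses are free calibration parameters chosen so the implied
short-separation fraction, E[pairs]/12 = 2.46/12 ≈ 20.5 %, matches the
≈20 % figure.  Given a drawn count k, a matching of size k is placed
uniformly at random on the subunit cycle, by explicit enumeration of all
k-matchings of C₁₂/C₁₄ (cheap for n ≤ 14; no rejection sampling).
14-mers reuse the 12-mer distributions and categorical (P(7) = 0) and
keep the 55 Å hub radius.

### Modes

*Separation-explicit* mode samples radii and separations directly as
independent marginals — this is the mode the statistical validation runs
in, and by construction radius and separation are uncorrelated.
*Angular* mode realizes full 2D coordinates: paired angular gaps drawn
from N(19.5°, 2.5°); unpaired gaps drawn around the equal-share residual
angle with an s.d. of 25 % of that share, then rescaled so the gaps sum
to exactly 360° (bounded resampling if any gap is non-positive).  Kinase
centres sit at polar radius (radius − 22.5 Å); separations are then
*computed* by the law of cosines.  Sharing each radius between two
adjacent chords couples radius and separation mechanically, giving a
positive Pearson correlation that stays ≤ 0.35 at these defaults —
consistent with a reported weak correlation (≈0.2) being read as "no
significant correlation".  The 25 % gap jitter is a package choice: it
is the value at which the angular-noise contribution to separation
variance dominates enough to keep the correlation in that band while
keeping all gaps positive in practice.

All lengths are in Å, angles in degrees in configurations and radians
internally.  Everything is driven by one `numpy` Generator seeded from
the config, so identical config + seed reproduces ensembles exactly.

## Measurement rules

"Clockwise" is fixed in image convention (y down): neighbour order is
taken by decreasing mathematical polar angle about the centroid, ties
broken by smaller radius.  The statistics are direction-symmetric; the
convention only pins down per-edge labels.  The pass-through path (for
separation-explicit tables) is the identity.  Per-particle pair counts
are the number of separations strictly below 45 Å; chains of short
separations (impossible on generated matchings, possible on thresholded
real-style data) are capped at ⌊n/2⌋ with a logged warning.  Both
thresholds use strict `<`.  The histogram convention is 5 Å bins
anchored at 0 Å, half-open on the right; the "Gaussian fit" is
moment-based (sample mean and n−1 s.d.), with no optimisation, by
definition of the procedure it reproduces.

## Physical models

*Random-coil tether*: RMS end-to-end distance b·√N with b = 3.5 Å;
N defaults to 45 residues (residues 301–344 inclusive count 44; the
conventional arithmetic uses 45 and the count is configurable), giving
23.5 Å.  *Linker decomposition*: mean radius − 55 Å hub − 45 Å kinase
diameter ≈ 27 Å on the calibrated ensemble, in agreement with the coil
prediction.  *Torus local concentration*: V = (πr²)(2πR) with R = 126 Å
and r = 49 Å (derivable from the radius bounds as (77+175)/2 and
(175−77)/2, provided as an alternate constructor); 12 kinases in V give
3.3 mM (2 s.f.), using 10⁻²⁷ L/Å³.  At millimolar local concentration
even a weak (hundreds of μM) dimerization affinity populates paired
states appreciably, rationalising the ≈20 % paired fraction; no mass-
action equilibrium model is implemented because naive mass action
over-predicts pairing and no quantitative coupling is established.

## Rendering and detection

Particles are rendered at 4.37 Å/px in a 128×128 box: hub annulus
(outer 55 Å, pore 12.5 Å), isotropic Gaussian kinase blobs (σ = 10 Å),
intensities clipped to [0, 1], additive Gaussian noise (σ = 0.05).
Detection: Gaussian smoothing (1 px); hub centre by intensity centroid
of the central disc; a hub-annulus template aligned to that centre is
subtracted before peak search so the annulus plateau cannot produce
false kinase peaks; local maxima above 0.25 outside a 50 Å inner
exclusion radius are refined to sub-pixel positions by 5×5 centroids;
detections closer than 20 Å are fused and flagged as merged, emulating
the "clearly resolved densities only" rule.  Fewer peaks than expected
yields a flagged partial result, not an exception.

Because the generator has no excluded volume it can place two kinase
centres arbitrarily close; a kinase is considered *clearly resolved* —
and only then held to the ≤1 px round-trip localisation bound — when no
other kinase centre lies within 30 Å and its own centre is ≥ 65 Å from
the hub centre (off the annulus).  At the defaults ≈95 % of subunits are
clearly resolved, the noise-free round trip localises them within
0.5 px, and the end-to-end pipeline (generate → render → detect →
measure → stats) reproduces coordinate-path mean radius and separation
within 2 Å at default noise over 200 particles.

## FRET correction

The three-filter correction subtracts fixed bleed-through fractions from
the raw FRET channel: FRETc = raw − 0.02093·donor − 0.09484·acceptor,
on background-subtracted images (background = median of a user-supplied
blank region per channel), with negative pixels retained.  The
coefficients are rounded up from measured cross-bleed, so on scenes
generated with smaller true cross-bleed FRETc can only under-report —
never inflate — true FRET.  Per-cell FRETc is normalized by mean donor
intensity, valid only with acceptor excess, enforced by a closed [4, 11]
window on the acceptor/donor abundance ratio; detected GFP intensity is
divided by the 4.8 channel detection-efficiency factor before the ratio
is formed.  Fluorophore roles are configurable; the default maps GFP to
the acceptor and mCherry to the donor.  Synthetic scenes implement
exactly the linear mixing the correction assumes (uniform disc cells,
donor quenching by (1−E), GFP-role channel carrying the 4.8× gain, flat
background, Gaussian read noise); they do not emulate spatial
illumination gradients, photobleaching, or spectral unmixing residuals,
so passing tests demonstrate correctness of the arithmetic and gating,
not robustness to those effects.

## Dose-response fitting

The variable-slope (4-parameter logistic) model is fit by nonlinear
least squares in log10-dose.  The 4PL is invariant under
(bottom, top, n) → (top, bottom, −n); fits are normalised to
top > bottom so the slope sign encodes direction (positive for
activation).  EC50 standard error is propagated from log10(EC50) by the
delta method; EC50 fold changes and Hill differences between two fits
carry delta-method errors.  Noiseless synthetic data are recovered to
solver tolerance; at 2 % multiplicative noise and 10 log-spaced doses
the EC50 and Hill estimators are biased by < 2 % over 500 replicates.
Only recovery of known synthetic parameters is claimed; experimental
EC50/Hill values are out of scope.

## Problem sizes and numerical choices

Validation runs use 1,000 particles (≈12,000 subunits) for distribution
recovery, 4,000 12-mers for pair-count categorical recovery, 600
angular-mode particles for the correlation band, 200 rendered particles
for the end-to-end image check, 10⁶ rejection samples for the
Monte-Carlo torus-volume oracle, and 200–500 replicate Hill fits — sizes
at which Monte-Carlo error is comfortably inside the stated tolerances
while the whole suite runs in well under a minute.  Truncated Gaussians
are sampled by inverse-CDF transform (`ndtr`/`ndtri`); degenerate
s.d. = 0 specs return the mean exactly.  Angular-gap realization retries
up to 64 times before raising.  Categorical validity requires mass ≥ 0
and sum within 10⁻⁹ of 1.

## Known limitations

- 2D only; no 3D conformations, atomic models, or activated-state
  (Ca²⁺/CaM-bound) ensembles.
- No excluded-volume interactions between kinase domains; overlapping
  placements occur and are handled at the detection/resolvability layer.
- The hard 45 Å support split idealises a threshold that real data
  straddle; classification error on real measurements is therefore not
  probed by these tests.
- The pair-count categorical's 4- and 5-pair masses are calibration
  choices, not published values.
- The rendering model has no CTF, stain granularity, or orientation
  disorder; detection performance on real micrographs is out of scope.
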