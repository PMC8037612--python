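# Methods

## The measurement being modeled

A single intraperitoneal EdU pulse, with euthanasia one hour later, labels
the S-phase cohort of every proliferating cell population in the brain.
Brains are cut transversely at a nominal 50 µm through their whole extent,
every section is imaged at 1.29 µm/pixel on 16-bit scans, and each labeled
nucleus is detected as one intensity peak. Because the 5× objective's focal
depth exceeds the mounted section thickness, detection is strictly
per-section 2D and no deduplication across sections is needed. The package
takes over from the images (or from pre-detected per-section coordinate
tables): detection, 3D reconstruction, density, compartment counting, and
production estimation. Sectioning, staining and registration are upstream;
inputs are assumed pre-aligned.

Coordinate convention (fixed here, since none is standard for this kind of
data): all physical coordinates in µm; x is left-right with the sagittal
midplane near x = 0, y dorso-ventral, z the rostro-caudal section axis. A
nucleus detected at pixel (x_px, y_px) on section k maps to
(1.29·x_px, 1.29·y_px, (k + ½)·50) µm. Placing z at the section center is
unbiased when nuclei are uniform through the section; the nominal 50 µm
thickness is used rather than the post-drying ~25–27 µm because the
in-vivo geometry, not the mounted geometry, carries the 200 µm density
radius.

## Spot detection

`find_maxima` retains exactly the regional maxima with prominence ≥
`tolerance` under 8-connectivity: a maximum at level v is rejected iff some
strictly higher pixel can be reached along a path whose minimum exceeds
v − tolerance. Within one tolerance basin only the highest maximum
survives; equal-valued maxima sharing a basin collapse deterministically to
the plateau containing the smallest (row, col) pixel; plateaus report their
rounded centroid (policy `first` reports the smallest pixel instead). The
widely used interactive implementation of this operator does not document
its connectivity or tie rules, so these semantics are pinned explicitly;
parity is expected (and tested) on well-separated spots, not promised
pixel-for-pixel on arbitrary images. Properties guaranteed by construction
and enforced by tests: invariance to additive offsets, covariance under
intensity scaling with a scaled tolerance, and monotonicity (raising the
tolerance never adds maxima). The implementation is exhaustively checked
against an independent brute-force flood-fill oracle on small random
images.

`false_positive_review` drops peaks dimmer than a brightness floor — the
automatable stand-in for the manual curation pass used on real scans, where
a low tolerance admits a few dim false positives.

## Density

The volume number density of a nucleus is the number of *other* nuclei at
Euclidean distance strictly below 200 µm, computed in 3D across sections
(the radius spans 8 nominal sections). Strict inequality follows the
statistic's wording; for continuous positions the choice is measure-zero.
No edge correction is applied at the brain surface — boundary nuclei see
truncated spheres — because the reference quantification applies none and
the tabulated AVND values depend on that choice. The default reference set
is the whole-brain cloud; a within-compartment mode exists for sensitivity
analysis only. The KD-tree implementation is contractually identical to the
O(n²) definition (tested exactly), and on homogeneous Poisson clouds the
interior mean matches λ·(4/3)π·200³ (tested to 3 SE).

## Compartments and the high-density selection

Compartment membership is a nearest-voxel lookup in a label volume; NPC
(number of proliferating cells) aggregates exactly up the hierarchy, and
AVND is the mean density of a node's points (NaN, never 0, when empty).
`select_high_density` takes the ⌈fraction·n⌉ densest points with a
deterministic tie order (density desc, section asc, x asc, y asc) — the
reference analysis does not define ties. The bilateral criterion "areas
dense on both sides of the brain" is operationalized as mirror-pairing: a
selected point survives iff some selected point lies within 200 µm (the
density scale; configurable) of its reflection about the midline. This is a
documented design choice — the simplest deterministic rule consistent with
the described figure — not a claim about the original manual procedure.
The midline itself is estimated as the median x of the whole-brain cloud.

## Production

With a 12-h S phase, a detected cohort of N cells turns over twice a day,
so the instantaneous production rate is 2N/day. Assuming the count varies
linearly between two sampled ages with counts A and B separated by C days,
the integral is (A+B)/2 · 2 · C = **(A + B) × C**. Months are converted at
30 days/month by default (configurable to 30.44); the reference totals
cannot be matched to the last digit under any single day convention, and
with 30-day months the package reproduces them to ~1 %. The schedule's
`s_phase_hours` scales the estimate by 12/s (so the default reproduces the
published formula exactly); heterogeneity of S-phase length across
populations is a known, unmodeled bias of this estimator. Intervals follow
the sampled ages (2→4, 4→8, 8→12, 12→30 months); no extrapolation outside
them. The cross-mouse spread uses the n−1 standard deviation, matching the
published two-animal table. Additivity down the compartment hierarchy
follows from the linearity of the formula and is asserted in tests.

`replacement_summary` divides production by a target neuron pool (e.g.
600,000 olfactory-bulb interneurons) for fold coverage, and the pool by the
daily rate for a replacement time. The replacement-time figures quoted for
young mice are reproduced with the whole-MPZ count; the subpallial-only
variant is a caller's choice of inputs.

## Age statistics

`one_way_anova` is the classical fixed-effects decomposition computed from
the definitional sums of squares with the p-value from the F upper tail;
it is cross-checked against `scipy.stats.f_oneway` on random instances.
The degenerate all-identical case returns F = 0, p = 1 rather than NaN
because "no effect" is the scientifically correct report there. With two
animals per age group the design is F(4, 5); the tabulated statistics are
reproduced within ~1 %. `decline_rate` defaults to the linear convention
(total percentage drop over the interval divided by months) because that is
the convention under which the published "12 % per month" figure emerges
from the counts; a compounding geometric variant is available by flag.

## The phantom: what it emulates and what it does not

The phantom exists so that every stage can be tested blind against known
ground truth. It is an ellipsoidal "brain" (full extents 6 × 4 × 8 mm, so
50 µm sectioning gives 160 sections) with geometric compartments: paired
CMS shells on a caudoputamen ellipsoid (split medially into an SEZ band),
paired RMS tubes running rostrally, paired thin midlayer sheets and SGZ
blades, a transverse corpus-callosum slab plus paired oblique
internal-capsule fans for white matter, and parenchyma elsewhere. Overlaps
resolve by fixed precedence (CMS > RMS > midlayer > SGZ > WM > parenchyma),
mirroring the fact that the reference compartments partition the brain
exactly. All shapes are functions of |x| on a grid symmetric about x = 0,
so phantom volumes are voxel-exactly mirror-symmetric. Slab faces are
aligned to 50 µm voxel boundaries so that voxelized volumes are unbiased at
the default pitch and converge under refinement.

Nuclei are drawn per compartment as Poisson(λ·V) with uniform positions
(uniform voxel choice + in-voxel jitter), keeping the label volume the
single source of truth for membership. Intensities are calibrated from the
packaged count table: λ = published count / phantom compartment volume, per
age (interpolated between sampled ages). The published table gives no
compartment volumes, so absolute per-mm³ intensities are not anatomical
claims; the phantom matches *counts* and the *ordering* of compartment
densities (CMS ≫ RMS > midlayer > SGZ ≫ parenchyma), not absolute anatomy.
The white-matter share of the tabulated "other" count is a free choice
(white matter set 8× denser than parenchyma, consistent with bundles being
"modestly denser" than surroundings). The default 2-month phantom carries
an expected 68,010 nuclei. Rendered images are Gaussian spots (default
σ = 2.58 µm ≈ 2 px) with optional Poisson-Gaussian noise. Not emulated:
real histology artifacts (tears, folds, staining gradients), anatomical
atlas fidelity, DAPI counterstain, and nucleus shape — so passing tests
demonstrate correctness of the *computational* chain, not robustness to
real-world image degradation.

## Numerical and testing choices

- One integer seed governs every stochastic draw of a generator run; all
  artifacts record it.
- Poisson-law conformance is tested as an index of dispersion in
  [0.7, 1.3] over 100 seeds; statistical recovery tests use 3-standard-error
  bands at fixed seeds.
- Problem sizes in tests and in `scripts/acceptance.py` (full 2-month
  phantom ≈ 68k points; 100-seed density calibration at 400 nuclei/mm³ in a
  2 mm box; 200 random 12×12 images against the detection oracle) were
  chosen to exercise every stage at realistic scale while keeping the whole
  suite interactive (~15 s).
- Degenerate inputs resolve to defined values, not errors, wherever a value
  is scientifically meaningful: empty compartments give NaN AVND, constant
  images give no maxima, identical ANOVA groups give F = 0.

## Known limitations

- The bilateral filter is one deterministic operationalization of a
  verbally described figure criterion; other rules (grid-based, area-based)
  would select slightly different point sets.
- Production estimates inherit the 12-h uniform S-phase assumption and the
  linear interpolation between widely spaced ages; both bias compartments
  with fast early decline.
- Exact pixel-level parity with the interactive Find-Maxima tool is not
  guaranteed on images with extensive plateaus or near-tolerance saddles;
  parity holds for well-separated spots, the regime the workflow operates
  in.
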