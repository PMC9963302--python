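# Methods

This note documents the models, conventions, and numerical choices behind
`synquant`, in the spirit of the methods documentation of mature scientific
packages: what each procedure assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where design decisions
were genuinely open.

## The measurement problem

A T cell contacting a ligand-presenting surface organises its receptors into
a bull's-eye: a central supramolecular activation cluster (cSMAC) fed by
centripetally moving receptor microclusters, surrounded by an adhesion ring
(pSMAC). Quantifying this architecture and its endocytic machinery requires
several distinct measurements: per-cell mean intensities and channel
correlations at the contact interface (TIRF geometry), rotationally averaged
positional maps, time-resolved microcluster tracks, 3D counts of vesicles on
either side of the cell membrane, and a population-level transfer statistic
from bead assays. Each stage is implemented as an independent module with a
documented contract; the pipeline drivers compose them.

## Synthetic ground truth

The generator is the package's validation instrument: every rendered object
carries an exact ground-truth record.

**2D synapse** (`SynapseSpec`). A 12.8 µm field at 0.1 µm/px holds one
synapse: a bright-field-like footprint disk (radius = ring radius + ring
width), a Gaussian-profile adhesion annulus (default radius 3.5 µm, FWHM
0.8 µm), a receptor channel composed of a soft-edged cSMAC disk (radius
1.2 µm) plus analytically evaluated Gaussian microclusters (default 30, σ
0.2 µm), and an adaptor channel mixing a rescaled copy of the receptor
signal with an independent punctate pattern in proportion `m : (1 − m)`
(`coloc_mixing`). Channel amplitudes default to 200/20/30 a.u. for
adhesion/receptor/adaptor — the relative ligand densities per µm² used on
supported lipid bilayers in this assay family — purely as recognisable
relative scales; absolute intensities are arbitrary units throughout.
Soft edges (≈1 px) keep the images band-limited so that interpolation-based
operations (rotation) stay within their stated tolerances; hard-edged
figures would alias.

**Movies.** Microclusters start in the pSMAC annulus and move radially
inward by a fixed drift per frame, clamping at the cSMAC radius; identities
are recorded per frame. Initial radii and angles can be given explicitly,
which test fixtures use to guarantee stated separation preconditions by
construction. An optional per-frame adaptor scale emulates recruitment
ramps. The central disk's amplitude is separately scalable
(`csmac_amplitude_scale`) because its edge is a genuine LoG responder;
detector tests that need isolated point sources set it to zero.

**3D stacks** (`StackSpec`). A (24–32) × 64–96 × 64–96 voxel volume at
0.15 µm laterally and 0.25 µm axially (the standard confocal z step for
whole-cell imaging) holds one ellipsoidal cell. The membrane channel is a
soft-edged filled ellipsoid with a narrow shell accent centred exactly on
the boundary, so a half-maximum threshold recovers the true surface; this is
what keeps the recovered mask volume within ~5 % of (4/3)πabc. Vesicles are
uniform-intensity balls evaluated at voxel centres; internal vesicles are
placed entirely inside the ellipsoid, released ones entirely outside, and
centres keep a surface gap of at least two voxel layers so that discretised
balls can never merge under 26-connectivity — a ground truth of n objects
must render as n resolvable components. Placement is rejection sampling
with a bounded retry budget; exhaustion raises an error naming the violated
constraint. Default noise for stacks is Poisson shot noise plus Gaussian
read noise (sd 2 on a vesicle amplitude of 150); this is the standard
condition for count-recovery experiments. The 2D synapse defaults are
noise-free; tests switch noise on explicitly where robustness is the point.

**RNG discipline.** Each object class (microclusters, puncta, vesicles, 2D
noise, 3D noise, movie placement, transfer events) draws from its own
`numpy` Generator derived from the top-level seed with a fixed stream id, so
adding one class of objects never perturbs another. Same seed + same spec
gives bit-identical output.

**What the generator does not emulate:** optics (PSF, TIRF evanescent
decay, SIM patterning), photobleaching, stage drift, cell-to-cell shape
variability, touching cells, and autofluorescence. Passing tests therefore
demonstrate the correctness of the measurement chain on resolvable,
well-separated structures — not robustness to every pathology of real data.

## Segmentation and background

Rolling-ball background subtraction is the classic morphological definition:
the background is the upper envelope of a ball (default radius 50 px) rolled
under the intensity surface (`skimage.restoration.rolling_ball`), and the
result is `max(image − background, 0)`. On a tilted plane the ball leaves a
small constant residual ≈ R·s²/2 (R radius, s slope); features sharper than
the ball are untouched.

Cell segmentation thresholds the reference channel with Otsu's method (the
specific auto-threshold used interactively in imaging software is rarely
recorded; Otsu is the parameter-free standard and is configurable), fills
holes, removes objects below a minimum area (given in µm², default 20),
excludes border-touching objects by default (whole synapses only), and
labels 8-connected components, returned sorted by descending area. A
constant image yields an empty list, not an error. Pixel coordinates are
0-based; bounding boxes half-open.

## Radial averaging

The reference procedure literally rotates the image N = 360 times by 1°
about the synapse centre (bilinear interpolation) and averages the copies.
Pixels rotated in from outside the frame are excluded from the mean via a
rotated weight image rather than zero-filled — zero-filling darkens corners
and distorts profiles (the zero-filling variant is available as a flag; which
behaviour the original interactive macro used is not recoverable, so the
less biased one is the default). The default implementation computes the
same angular mean by polar resampling (angular sampling ≥ 2 points per
half-pixel of arc) and maps the radial function back to the grid; it agrees
with the literal rotation loop within interpolation tolerance (< 0.5 % of
signal amplitude on test fixtures) and is ~20× faster. The rotation centre
defaults to the cell-mask centroid. Radial profiles bin pixels into annuli
of fixed width (default 0.25 µm, bin i = [iw, (i+1)w)); empty bins are
omitted. Cohort averages report per-bin mean ± SEM across cells; with
`normalize_radius` each cell's radius axis is first rescaled by its
equivalent radius √(area/π) and interpolated onto a common normalised grid.
SEM for n = 1 is reported as 0 by convention.

## MFI and colocalization

MFI is the arithmetic mean of (by default background-subtracted) pixel
intensities over the cell mask; the mask — the TIRF footprint — is the
operational definition of "across the synaptic interface". PCC is the plain
Pearson correlation over mask pixels (no Costes thresholding or Manders
variants); a channel that is constant over the mask makes the correlation
undefined and returns NaN, deliberately not 0. Values within 1e-12 of ±1
are snapped to exactly ±1: at mask sizes of 10⁴ pixels the accumulated
rounding of the dot products exceeds the resolvable correlation difference
in that band, and the perfect-colocalization limit should read exactly 1.
Aggregation reports median and 25th/75th percentiles (linear-interpolation
percentile convention — conventions differ between software packages, so it
is fixed and stated) plus per-experiment means for superplot-style display.
Whether MFI should be computed before or after per-channel background
subtraction is not standardised; subtraction is on by default and
configurable.

## Tracking

Detection: scale-normalised LoG response `σ²·(−∇²(G_σ ∗ I))`, whose peak at
a matched Gaussian spot of amplitude A is A/2 — thresholds are therefore in
amplitude units. Local maxima above threshold are suppressed within 2σ of a
stronger maximum and refined by a per-axis quadratic fit (offset clamped to
±0.5 px). Linking minimises total squared displacement per frame pair via
the Hungarian algorithm on a padded cost matrix in which a link beyond the
displacement gate (default 0.5 µm per elapsed frame) is inadmissible and
leaving a point unmatched costs gate². Tracks absent for up to
`max_gap_frames` (default 1) can resume, with the gate scaled by the elapsed
frames; longer absences start a new track. No split/merge events and no
motion-model prediction — appropriate for microclusters at these densities,
and the defaults (σ 0.2 µm, gate 0.5 µm/frame) suit TCR microclusters at
~0.1 µm/px sampling. Intensity traces average a secondary channel in a disk
(default radius 0.4 µm) around each tracked position; cohort traces align by
frame and report mean ± SEM across tracks.

## 3D vesicle quantification

The cell mask comes from the membrane channel: Gaussian smoothing at a
physical scale (converted per axis to voxels; default 0.3 µm), Otsu
threshold, per-slice hole filling (the stain is a shell; filling each z
slice recovers the solid body), then the largest 26-connected component.
Vesicle segmentation thresholds the cargo channel restricted to the region
inside (internal mode) or outside (released mode) the mask. The automatic
threshold is Otsu floored at median + 5 robust SD (1.4826·MAD) of the
region: Otsu alone misbehaves when the foreground class is tiny or absent —
it then simply splits the noise — and the floor guarantees that a
signal-free region yields zero objects. 26-connected components smaller
than `min_voxels` (default 4) are discarded; per-object voxel count, volume
(count × voxel volume, in µm³ from the anisotropic voxel size), centroid,
and summed raw intensity are reported. This documented
threshold/connected-component procedure deliberately replaces proprietary
surface-rendering pipelines whose parameters are not published. Summed
intensity uses raw voxel values (background-subtracted variants can be fed
in upstream). Zero objects is a valid result, not an error.

## Transfer statistic and F test

The transfer fraction is `MFI_bead / (MFI_bead + MFI_cell)` with MFI the
arithmetic mean of event fluorescence per population (median selectable),
computed per experiment and averaged with SEM. It is invariant to global
rescaling and maps to `1 − f` under swapping the population labels. Dose
curves over ligand density are compared with the extra-sum-of-squares F
test: one curve fitted to the pooled conditions versus one per condition,
`F = [(SS_sh − SS_sep)/k] / [SS_sep/(n − 2k)]` with k parameters per curve.
The default curve family is a straight line in log₁₀ density — the minimal
assumption when the true functional form is unknown — with a saturating
hyperbola (`top·x/(K+x)`) selectable. Noise-free degenerate cases are
handled explicitly: identical conditions give F = 0, p = 1; perfectly
separated conditions give p = 0.

## Mann–Whitney U

For samples with both n ≤ 8 (configurable) the exact permutation null of
the rank sum is computed by a counting recursion over the pooled doubled
mid-ranks (doubling makes tied mid-ranks integers), giving p =
2·min(P(W ≤ w), P(W ≥ w)) capped at 1 — identical to full enumeration of
all C(n_a+n_b, n_a) labelings at a fraction of the cost. Larger samples use
a normal approximation with tie-corrected variance, continuity correction,
and an Edgeworth kurtosis term using the exact excess kurtosis of the null,
γ₂ = −(6/5)(m²+n²+mn+m+n)/(mn(N+1)); this keeps the approximation within a
few 10⁻⁴ of the exact test already at m = n = 8, versus ~10⁻² for the plain
normal approximation. Stars follow the convention * p<0.05, ** p<0.01,
*** p<0.001, **** p<0.0001; no multiple-testing correction is applied by
default (a Holm adjustment is available). Whether nested designs should be
tested per cell or per experiment is genuinely ambiguous; both are
supported, per-cell being the default.

## Pipelines and reproducibility

The 2D and 3D drivers validate the channel-role configuration before any
computation, log per-stage counts, and write a JSON manifest (inputs,
parameters, seed, software version — no timestamps) alongside every run.
All randomness flows from the config seed through fixed derivation, so
identical config + seed reproduces byte-identical CSVs. Demo fixtures are
generated in-process from the synthetic module.

## Problem sizes

Validation runs use one 128² synapse per cell for 2D measurements, 20 cells
per mixing level for the colocalization sweep, 24×64×64 stacks (220 of
them) for the count-recovery experiment, 20-frame movies of 5 clusters for
tracking, and 40–50 events per population for transfer tables. These sizes
were chosen so each property is measured with comfortable margins while the
whole validation suite completes in well under a minute per stage.

## Known limitations

- No optics model: tests validate the measurement chain, not deconvolution
  or resolution limits.
- No touching-cell splitting (no watershed); one cell per fixture.
- The radial average assumes an approximately circular synapse; kinapses
  (broken symmetry) are out of scope.
- The F test's curve families are descriptive, not mechanistic.
- No mixed-effects modelling of the cell-within-experiment hierarchy.
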