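# Methods

This note documents the models and numerical choices behind `scaffoldmri`:
what the processing sequence assumes, what the phantom generator emulates
(and deliberately does not), and where the design was genuinely open.

## The processing sequence

**Background model.** MRI coil inhomogeneity scales the received signal,
so the background is treated as a smooth multiplicative field over the
slice plane. It is estimated from a single reference slice containing only
liquid (by default the last slice of the stack; the first is equivalent) as
the grayscale morphological opening of that slice with a disk of radius
9 px. Opening (erosion then dilation) removes bright features smaller than
the disk while following smooth large-scale variation; it is
anti-extensive (estimate ≤ slice everywhere), idempotent, and monotone —
properties the test suite asserts against a brute-force oracle. One
background image is subtracted from every slice of the stack; this assumes
the inhomogeneity varies little along the thin (≈ 3 mm) slab, which holds
for the phantom's default z-independent bias and is the documented
limitation of the single-reference design (a per-slice variant would need
a liquid-only region in every slice, which scaffold-bearing slices do not
offer). Subtraction clips at zero because downstream thresholding assumes
non-negative intensities. Opening a noisy slice tracks the lower envelope
of the noise, so the corrected liquid level sits a small positive offset
(≈ 2σ) above zero rather than at zero; the calibrated threshold absorbs
this offset automatically, which is why calibration and correction must use
identical parameters.

**Morphology conventions.** All morphological operations — grayscale
opening (radius 9), binary mask opening (radius 2), and the median filter's
neighborhood (radius 2) — share one disk discretization (pixels whose
center distance is ≤ radius) and reflective border handling, so a single
independent oracle covers them. The median filter is applied per slice
in 2D, matching slice-wise processing of multi-slice acquisitions.

**Segmentation.** Tissue is `corrected ≥ T` inside the circular ROI,
followed by per-slice binary opening (radius 2) to drop sub-disk outliers.
Scaffold is `raw ≤ T_low` inside the ROI — the dark class is segmented on
the unprocessed stack because background subtraction is tuned for the
bright class and drives both scaffold and liquid toward zero. Because the
two masks come from different images their disjointness is enforced
explicitly (`tissue &= ~scaffold`) and asserted on every pipeline run.
The scaffold threshold defaults to the lower multi-Otsu (3-class) boundary
of the mid-stack ROI histogram; a fixed value can be supplied instead.

**Threshold calibration.** The tissue threshold is the smallest value at
which a bare (cell-free) scaffold scan, processed identically, shows a
false-positive tissue fraction within tolerance. False positives are
counted after binary opening (post-opening masks are what enters
quantification; a pre-opening count is available as a flag) and bounded
**slice-wise**: the worst slice's fraction of pore pixels must respect the
tolerance, which guarantees that every per-slice record of a tissue-free
scan stays within it. The false-positive fraction is non-increasing in the
threshold, so a binary search over the observed intensity values returns
the exact minimum. The default tolerance is 0.1 % of pore pixels — one
reading of "a limited amount of false positive signal"; it is configurable.
One calibrated threshold serves all stacks of an experiment.

**Quantification.** Per slice, inside the ROI:
`pore_px = roi_px − scaffold_px` and
`tissue_pct = 100 · tissue_px / pore_px` (tissue pixels overlapping
scaffold are never counted; a slice with zero pore pixels is an explicit
error, not a silent zero). The counting ROI is the circle matching the
scaffold's outer ring. Sections (top/middle/bottom) default to near-equal
thirds of the informative slice range — slices whose scaffold coverage
exceeds 0.5 % of the ROI — with remainder slices assigned to the earlier
sections; explicit boundaries override. Section error bars use the sample
(n−1) standard deviation. Sections are compared by classical one-way
ANOVA; the post-test is all three pairwise pooled-variance t-tests with
Bonferroni multiplication (capped at 1) and the conventional star
notation (0.05/0.01/0.001). Degenerate all-identical input returns
F = 0, p = 1 by convention.

**4-stage projections.** Per section, each pixel's count of
tissue-positive slices (0…n) maps to stages 0–4: stage 0 iff the count is
0, and counts 1…n split into four equal-width bins with upper edges
⌈kn/4⌉; a full column always reaches stage 4 (including when n < 4, where
fewer than four distinct bins exist). For n = 15 the bins are 1–4, 5–8,
9–12, 13–15. Projections are written as 5-entry indexed-color PNGs.

**Surface models.** Marching cubes at isolevel 0.5 on the binary volume,
padded with one empty voxel shell so every component is closed; the
"resampling factor" f downsamples the volume by f per axis (block mean,
re-binarized at 0.5) before surfacing — factor 1 for scaffold, 2 for
tissue by default. Vertices are in physical mm via the pixel size and
slice thickness. Smoothing is the two-coefficient Taubin filter with
uniform Laplacian weights: alternating steps of weight λ and µ under the
pass-band condition 0 < λ < −µ < 1; the defaults λ = 0.5, µ = −0.53,
10 iterations are the filter's canonical values (the tests verify volume
preservation within 2 % on a voxel sphere, that a pure-Laplacian control
shrinks strictly more, and agreement with an independent implementation).

## The phantom generator

The generator defines the conditions under which the pipeline is tested.

**Scaffold.** Fibers are cylinders of diameter 0.2 mm whose axes lie in
the mid-plane of each 0.15 mm layer, running alternately along x and y at
1.0 mm pitch; since the layer thickness is below the fiber diameter,
consecutive layers interpenetrate as fused deposited fibers do. The
cylinder (8 mm × 3 mm) is centered in a 45-slice, 0.07 mm-thick stack
(128 px, 10 mm field of view), leaving the first and last slices
liquid-only so a background reference always exists. The scaffold sits in
a 9 mm liquid-filled tube; outside the tube the signal is near zero.

**Tissue.** Three morphologies, all placed in the pore space (counting
ROI minus scaffold) with per-section occupancy targets hit to one voxel by
truncating the last structure in its compactness order:

* `sheet` (default) — a connected layer hugging the section's outward
  scaffold face, the dominant pattern observed in such cultures (cell
  sheets at the construct faces);
* `string` — pore-channel ribbons: in-plane persistent random walks
  stamped with a disk of the component diameter and extruded over a flat
  slice band, emulating string-like tissue filling the channels between
  fiber layers;
* `blob` — spheroid aggregates.

The component scale defaults to 0.4 mm. An unreachable target (e.g. a
sheet asked to fill a whole section) raises an error reporting the
achievable maximum.

**Intensities.** Classes are phenomenological — no relaxation physics:
native contrast scaffold 15 / liquid 100 / tissue 120 (8-bit a.u.). The
tissue–liquid contrast (20) is deliberately *below* the bias swing at the
default amplitudes (20–30 at a = 0.2–0.3): this is the regime that makes
background correction necessary, and it is the package's choice of
"realistic" because it reproduces the motivating failure — on an
uncorrected stack at amplitude 0.3, every global threshold that retains
all tissue voxels also misclassifies liquid. Agent contrast (scaffold 85 /
liquid 100 / tissue 160) emulates an iron-oxide agent in the liquid:
tissue–liquid contrast rises, scaffold–liquid contrast collapses, and
low-threshold scaffold segmentation floods the ROI (the pore-closure
failure, for which `segment_scaffold` carries a warning heuristic).

**Bias and noise.** The bias is multiplicative, `1 + a·b`, with `b` a
seeded low-order 2D polynomial normalized to extremes ±1 over the tube
region (so the liquid max/min ratio is exactly (1+a)/(1−a)); an optional
3D Gaussian random field of length scale ≥ 2 mm can be mixed in (weight 0
by default, consistent with the single-2D-background correction). Noise
is Gaussian (σ = 5, i.e. 5 % of the liquid level) with a Rician option.
All randomness derives from one seed through independent sub-streams;
phantoms are bit-reproducible from their parameter record.

**What the phantom does not emulate** — and hence what passing tests do
not show about real scans: partial-volume mixing at class boundaries
(voxels are pure classes), T1/T2-dependent contrast and its drift,
susceptibility artifacts near the polymer, through-plane bias variation
(unless the GRF option is enabled), and anatomically realistic tissue
texture. Recovery results on the phantom are therefore best-case with
respect to these effects.

## Test problem sizes and known limitations

The default test stack is 128 × 128 × 45 (the acquisition geometry above);
the occupancy-recovery study uses nine phantoms (occupancies 1 / 2.5 / 4 %
× three seeds) at bias 0.2 and noise 5 %, chosen to span the method's
stated 1–4 volume-% detection regime while keeping the full suite around a
minute of compute. The morphology oracle runs on 200 random 16 × 16 images
at radii 1–3.

Known limitations:

* The median filter and binary opening erode roughly a one-pixel shell
  from every convex structure boundary, and slice-wise processing removes
  thin z-cross-sections of curved 3D structures. Sheet-like tissue is
  recovered nearly unbiased; thin tubes and small blobs near the
  structuring-element scale are systematically under-counted (about 15–20
  % relative at a 0.4–0.8 mm diameter). This is a property of the method,
  not of the implementation, and bounds its sensitivity to fine tissue.
* The per-slice tissue percentages of sparse, clumped tissue have large
  slice-to-slice variance, so ANOVA significance for a single scan
  fluctuates with the realization even when the section ordering is
  recovered; the star level reported for one phantom is not a stable
  statistic.
* A single 2D background cannot correct through-plane inhomogeneity; with
  the 3D bias option enabled the corrected liquid spread grows with the
  GRF weight.
* `fit_roi` assumes the liquid tube is the largest bright connected
  region of a mid-stack slice and covers ≥ 10 % of the frame; anything
  else requires a manual ROI (the intended workflow for real scans).
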