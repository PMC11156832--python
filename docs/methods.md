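# Methods

`angioqa` implements the quantitative pipeline used to compare angiographic
acquisitions of the intracranial circulation: repeat-acquisition SNR and
paired-ROI CNR on registered volumes, reader-score aggregation, Canny
edge-pixel quantification of angiogram quality, and a complex-wavelet
structural similarity index between renderings of the same vessels from two
modalities. Because clinical TOF-MRA and catheter-angiography data cannot
be redistributed, every stage is exercised on a digital vascular phantom
whose statistical structure matches what the estimators assume.

## The phantom

**Geometry.** A deterministic bifurcating tree of capsules (straight tubes
with hemispherical caps). The trunk has radius 2 mm and radii halve per
branching level, so the default five-level tree spans diameters 4 mm (the
scale of a carotid siphon or basilar artery) down to 0.25 mm
(perforator scale, below most clinical voxel sizes). Caliber classes are
defined by disjoint radius ranges: large (r >= 1 mm), medium (0.4-1 mm),
small (0.15-0.4 mm), perforator (< 0.15 mm). Child segments start exactly
at their parent's endpoint, which keeps connectivity checks exact.

**Rasterization.** Voxels are classified analytically against each capsule
using half the voxel diagonal as a guard band; only boundary-band voxels
are estimated by partial-volume subsampling (8 x 8 x 8 midpoint samples per
voxel, configurable), so a full 200 x 200 x 93 grid rasterizes in seconds.
Interior voxels carry the vessel intensity exactly; overlapping tubes take
the maximum in-tube fraction. Tubes thinner than half the largest voxel
dimension are permitted but logged as a partial-volume warning.

**Acquisition model.** Repeat acquisitions differ only by independent
additive zero-mean Gaussian noise (plus an optional recorded rigid
misalignment of the second acquisition). Gaussian rather than Rician noise
is a deliberate simplification: the difference-method estimators assume
noise cancels symmetrically in A - B, and the Gaussian model keeps every
recovery oracle closed-form (`std(A - B) = sqrt(2) sigma`,
`SNR -> S / (2 sigma)` under the halved convention). At the low-SNR
extreme of real magnitude MR data the Rician floor would bias both
estimators; passing tests therefore validate the estimators, not the noise
physics of any scanner.

**Default intensities and regimes.** Vessel 300, background 60, base noise
sigma 10 (arbitrary units): configuration values, not claims about
hardware. The four default regimes are voxel sizes 0.2 x 0.2 x 0.5,
0.2 x 0.2 x 0.4, 0.2 x 0.2 x 0.3 and 0.4 x 0.4 x 0.5 mm^3, with noise
scaled inversely to voxel volume relative to the coarse regime. This
reproduces the direction of the resolution trade-off (mean SNR falls as
voxels shrink; finer grids detect more vessel-border pixels) without
modelling field-strength-dependent background suppression — background
intensity is an explicit free parameter, not saturation physics.

**Projection partner.** The stand-in for a second-modality angiogram is a
maximum-intensity projection subjected to in-plane rotation, Gaussian blur,
gamma remapping of [0, 1]-normalized intensities, and mild additive noise.
It shares anatomy with the MRA MIP but differs in geometry and intensity
transfer, which is exactly the regime the similarity index is meant for.
It does not emulate projective (cone-beam) geometry, contrast dynamics, or
vessel overlap from true integral projection of contrast medium.

## Registration and ROI propagation

Rigid (6 degrees-of-freedom) transforms are value objects with closed-form
composition and inversion (verified against homogeneous-matrix arithmetic
to 1e-9 on probe grids). Estimation maximizes Mattes mutual information
(32 bins, dense sampling for determinism) under a coarse-to-fine pyramid
(shrink 4/2/1, smoothing 2/1/0 voxels) with regular-step gradient descent
and physical-shift parameter scaling, via SimpleITK. The accuracy contract
— 20 random transforms up to 5 mm / 5 degrees recovered within 0.25 voxel
and 0.5 degrees on the noiseless phantom — is what tests enforce; the
optimizer is an implementation detail. Estimation interpolates linearly;
label and value propagation is strictly nearest-neighbour so resampling can
never invent intensity or label values.

ROI geometry (not specified by any source, exposed in config): vessel ROIs
are spheres of radius 0.8x the local tube radius centered on centerlines,
floored so that every sphere keeps several voxels on the coarsest grid it
will be propagated to (one-voxel ROIs have no defined standard deviation).
Each parenchymal partner is the same voxel-offset sphere translated
perpendicular to the vessel into tube-free background, checked for exact
index-space disjointness — which guarantees the identical-voxel-count
pairing the CNR estimator requires. The round-trip propagation contract
(fine -> coarse -> fine Dice >= 0.7 per label) holds for ROIs of
large-vessel scale; it is quantization-limited and degrades for ROIs whose
radius approaches the coarse voxel size.

## SNR and CNR

For a repeat couple (A, B) on a common grid and an ROI:

    SNR = (1/sqrt(2)) * mean_ROI((A + B)/2) / sd_ROI(A - B)

implemented exactly in this form (convention "halved"). Note that the
conventional difference-method estimator is `sqrt(2) * mean / sd_diff`, so
this form is half the conventional value (a constant-100 phantom
with sigma 10 recovers 5.0, not 10.0). `convention="nema"` selects the
conventional variant; both are recorded on the result. The numerator reads
"mean of A and B" as the ROI mean of the voxelwise average — the standard
difference-method numerator.

    CNR = (mean_vessel - mean_parenchyma) / sqrt(sd_vessel^2 + sd_parenchyma^2)

computed on the A acquisition only, sign preserved. Sample (n-1) standard
deviations are used throughout; zero denominators raise a degenerate-input
error rather than returning infinities. Box-plot aggregation uses linear
interpolation between closest ranks for all percentiles; groups of one
report an undefined (NaN) standard deviation.

## Paired comparison

Two-sided Wilcoxon signed-rank test: zero differences dropped, tied
absolute differences mid-ranked. For n <= 25 remaining pairs the null is
enumerated exactly by dynamic programming over the observed (doubled, hence
integer) ranks — chosen because scipy's exact method declines ties, and the
study-scale n = 17 ROIs sits squarely in the exact regime. Above 25, a
normal approximation with continuity and tie correction is used and is
cross-checked against scipy. Report tables carry the conventional asterisk
annotations (* p < 0.05, ** p < 0.01, *** p < 0.001) and an optional Holm
column next to the unadjusted p-values.

## Edge quantification

The Canny detector is implemented in full — Gaussian smoothing (default
sigma 1.4 px), Sobel gradients, non-maximum suppression with nearest-of-8
direction quantization, double-threshold hysteresis with 8-connectivity —
because the statistic of interest is the raw count of detected border
pixels and must be fully specified. Thresholds are fractions of the
maximum gradient magnitude (defaults low 0.1, high 0.2), which makes the
edge map invariant to positive intensity scaling; all parameters are
recorded on the edge map. On a high-contrast digital disk the count agrees
with the disk's border-pixel count under 8-adjacency within 15% (the
quantized suppression produces 8-connected staircases, so the 8-adjacency
border is the matching brute-force reference; an independent scikit-image
run agrees within the same band).

## The similarity index

Both images are first percentile-normalized (1st-99th), resampled to a
common grid (bilinear, larger onto smaller — nearest-neighbour after
binarization would destroy thin vessels), and Otsu-binarized (default;
grayscale mode retained for sensitivity analysis). Otsu thresholding
maximizes between-class variance over a 256-bin histogram with exact
integer arithmetic on bin indices, so plateau ties (empty valley bins)
resolve deterministically to the lowest threshold.

**Transform.** A complex steerable pyramid built in the frequency domain:
raised-cosine radial octave windows and cos^(Q-1) angular windows covering
a single half-plane per orientation (default 4 scales x 6 orientations).
The squared analysis masks partition unity exactly — including on discrete
Nyquist lines, where the angular normalization is computed against the
grid's own Hermitian-partner map — so the frame is tight: reconstruction
and Parseval energy balance hold to machine precision (tested at 1e-6 and
1%, measured at ~1e-15). Oriented sub-bands are decimated by frequency-
domain cropping, alias-free because each band's support fits its decimated
Nyquist box; grids shrink dyadically with scale.

**Index.** Per sub-band,

    CW-SSI = (2 |sum_i c_x,i conj(c_y,i)| + K) / (sum |c_x,i|^2 + sum |c_y,i|^2 + K)

with the algebraically identical factored form (magnitude term x
phase-consistency term) implemented independently as a cross-check; the
two agree to 1e-12 on random inputs. All sums go through the same complex
product-and-sum path so that identical inputs score exactly 1.0 in
floating point.

**Aggregation and K (measured design choices).**
- Scores are computed over 7 x 7 sliding windows and averaged with each
  window weighted by its local signal energy. Within a window a rigid shift
  is a near-constant coefficient phase ramp, which the windowed cross-term
  modulus absorbs; energy weighting keeps the many empty background windows
  of a sparse angiogram — whose score is set entirely by K — from either
  inflating the index or making it K-sensitive. An unweighted global
  per-band variant remains available (`aggregation="global_per_band_mean"`).
- `K = "auto"` is 1% of the mean sub-band energy (`k_fraction`
  configurable). Tying K to the coefficient count instead makes it 20-60x
  the typical band energy of a [0, 1]-normalized sparse vessel image and
  lets K dominate the score; with the energy-relative rule, halving K moves
  the index by under 1e-3 on non-degenerate pairs, i.e. K matters only
  where energy vanishes, as intended.
- The finest octave is excluded from the aggregate by default
  (`min_scale=2`). The index's insensitivity argument requires the
  translation to be small relative to the wavelet filter size; a 2-3 px
  shift is comparable to the ~2 px wavelets of scale 1, whose phase
  coherence it destroys, but small for every coarser scale. With scales
  >= 2 the contracts hold simultaneously on 180-256 px phantom MIPs:
  identity exactly 1, 1-3 px shifts >= 0.9 (2 px: ~0.97), 3-degree
  rotation >= 0.85 (~0.97), independent-noise null pairs ~0.1-0.15.

These thresholds are artifact-level contracts operationalizing a
qualitative robustness claim; they were fixed from the harness
measurements recorded here and are asserted as such by the tests.

## Pipelines and reproducibility

`run_protocol_comparison` chains phantom -> repeat pair -> (registration if
misaligned) -> ROI propagation -> per-ROI SNR/CNR -> aggregation + paired
Wilcoxon -> MIP edge counts, per regime; `run_similarity_comparison` chains
phantom -> MIP + perturbed projection -> similarity index over a
perturbation sweep. Per-stage seeds are spawned from the global seed via
`numpy.random.SeedSequence` in a fixed order, so a rerun of the same config
is byte-identical (enforced by a replay test). Every report row traces to
a logged config with hash, seeds and software version. Pipeline failures
abort with the stage name and config hash.

Problem sizes used by the test suite and the reproduction script — 72^3 to
256 x 256 x 44 grids, 10-seed estimator recoveries at ~1e5 voxels, a
20-transform registration sweep — were chosen so the full analysis runs on
a laptop-class single core in minutes while keeping every estimator in its
asymptotic regime (estimator standard errors well under the 2% acceptance
bands).

## Known limitations

- Gaussian, spatially white noise: no Rician magnitude floor, no coil
  shading, no physiological or motion artifacts.
- Piecewise-linear tube geometry with hard intensity boundaries: no flow
  effects, no multi-slab boundary artifacts, no background texture, so
  absolute edge counts and similarity values are not comparable to clinical
  magnitudes — only directions and estimator recoveries are.
- The projection partner is an in-plane perturbation of a parallel MIP,
  not cone-beam projective geometry.
- Reader scores are input data; the package aggregates them and makes no
  attempt to model readers (no blinding, no inter-rater statistics).
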