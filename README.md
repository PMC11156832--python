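# angioqa

Quantitative image-quality and cross-modality-similarity analysis for
intracranial angiography, built for researchers comparing acquisition
protocols (e.g. ultra-high-field time-of-flight MR angiography at several
voxel sizes against a conventional acquisition) and comparing MR angiograms
against catheter angiography (DSA). Because clinical angiograms cannot be
redistributed, the package ships a digital vascular phantom — a branching
tree of bright tubes (diameters ~4 mm down to 0.25 mm) on a suppressed
background, with repeat acquisitions differing only by independent noise —
on which every stage of the analysis runs end to end.

## What it computes

**Difference-method SNR.** For a repeat couple (A, B) registered to a
common grid and an ROI_j:

    SNR_{i,ROI_j} = (1/√2) · mean_{ROI_j}((A + B)/2) / σ_{ROI_j}(A − B)

implemented exactly in this form (it is half the conventional NEMA value;
`convention="nema"` selects √2·mean/σ instead).

**Paired-ROI CNR.** Each vessel ROI_j has a same-size parenchymal partner
ROI′_j beside it:

    CNR_{i,ROI_j} = (mean_{ROI_j} − mean_{ROI′_j}) / √(σ²_{ROI_j} + σ²_{ROI′_j})

**Registration.** Multiscale 6-DoF rigid alignment maximizing mutual
information (32-bin), with closed-form transform composition/inversion and
strictly nearest-neighbour ROI propagation (no interpolation smoothing).

**Angiogram quality.** Full Canny edge detection (Gaussian → Sobel →
non-maximum suppression → double-threshold hysteresis) on maximum-intensity
projections, with gradient-relative thresholds and edge-pixel counting.

**Reader scores.** Aggregation of 0–4 vessel-visibility grades
(category × volunteer × field strength), plus detection-rate arithmetic.

**CW-SSI.** A complex-wavelet structural similarity index on Otsu-segmented
image pairs: per sub-band of a complex steerable pyramid (4 scales × 6
orientations),

    CW-SSI(c_x, c_y) = (2·|Σᵢ c_{x,i} c*_{y,i}| + K) / (Σᵢ|c_{x,i}|² + Σᵢ|c_{y,i}|² + K)

with both algebraic forms (direct ratio and magnitude-times-phase-consistency)
implemented independently. A small rigid shift becomes a near-constant
coefficient phase ramp, which the modulus of the cross-sum absorbs — the
index is insensitive to small relative translations and rotations, unlike
pixelwise comparison. See `docs/methods.md` for the transform, the
aggregation, and the choice of K.

## Worked example

The analysis is organised as numbered drivers under `analysis/`:

```
python analysis/01_simulate_phantom.py     # phantom volumes, MIP, projection
python analysis/02_protocol_comparison.py  # SNR/CNR/edges across regimes
python analysis/03_edge_quantification.py  # fine vs coarse edge counts
python analysis/04_modality_similarity.py  # CW-SSI perturbation sweep
python analysis/05_reader_scores.py        # score-table aggregation
```

`analysis/05_reader_scores.py` prints:

```
field_strength  grand_mean  small_vessel_mean  pontine_mean  total_volunteer1  total_volunteer2  total_volunteer3  total_volunteer4
            7T        2.89              3.500           1.0                21                23                18                19
            3T        2.29              1.625           0.0                20                15                14                15

stenosis detection rate: 84.2% (16 of 19)
diagnostic-parameter detection rate: 84% (27 of 32)
```

The grand means (2.89 vs 2.29) say the higher-field protocol scores better
on average across all vessel categories and volunteers; the gap widens for
the smallest vessels (3.50 vs 1.63), which is where resolution matters
most, while pontine perforators stay poorly visible in both (1 vs 0).

`analysis/02_protocol_comparison.py` reproduces the resolution trade-off on
the phantom (regime names carry the voxel size in mm; noise scales
inversely with voxel volume): mean SNR falls monotonically as voxels shrink
(2.71 → 2.01 → 1.54 across the three fine regimes, per-ROI means over 17
ROIs) while the coarse regime sits far higher (11.98), and the fine-regime
MIP yields more Canny border pixels than the coarse one (476 vs 200) —
smaller voxels pay in noise but resolve more vessel border. All pairwise
regime differences carry exact Wilcoxon signed-rank p-values.

`analysis/04_modality_similarity.py` compares the MRA MIP with its
angiogram-like projection partner (rotated, blurred, gamma-remapped): the
CW-SSI decays monotonically as the geometric perturbation grows (0.632 at
0° down to 0.522 at 10° rotation under default Otsu binarization for the
default phantom) and stays far above the ~0.1 score of an unrelated image.

A thin CLI mirrors the library (`angioqa simulate|register|propagate-rois|
snr|cnr|scores|edges|cwssim|report`); all computation lives in the
importable modules under `src/angioqa/`.

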