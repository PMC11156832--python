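"""Protocol-optimization analysis on the phantom.

Runs the full regime comparison — three progressively finer high-field
voxel regimes plus the coarser conventional regime, noise scaled inversely
with voxel volume — and reports per-ROI SNR/CNR aggregates with paired
Wilcoxon comparisons and per-regime Canny edge counts. The expected
directions: mean SNR falls as voxels shrink at matched hardware (the noise
penalty of resolution), while finer voxels detect more vessel-border pixels.

Outputs: results/protocol/ (metrics.csv, summaries, comparisons.csv,
edge_counts.csv, provenance.json).
"""

import logging

logging.getLogger("angioqa").setLevel(logging.ERROR)

from angioqa.report import RunConfig, run_protocol_comparison

cfg = RunConfig(seed=1, out_dir="results/protocol")
bundle = run_protocol_comparison(cfg)

print("mean SNR by regime (halved convention, mean / (sqrt(2) sd_diff)):")
print(bundle.summaries["snr_by_acquisition"][["group", "n", "mean", "sd", "median"]].to_string(index=False))
print("\nmean CNR by regime:")
print(bundle.summaries["cnr_by_acquisition"][["group", "n", "mean", "sd", "median"]].to_string(index=False))
print("\nedge pixels per regime (axial MIP, Canny low=0.1 high=0.2 sigma=1.4):")
print(bundle.edge_counts[["acquisition_id", "edge_pixels"]].to_string(index=False))
print("\npaired Wilcoxon comparisons (unadjusted p, Holm column alongside):")
print(bundle.comparisons.to_string(index=False))
print(f"\nreport bundle written to {bundle.out_dir}/")
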