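"""Angiogram-quality quantification by edge-pixel counting.

Renders axial MIPs of the same vessel tree at a fine (0.2 mm in-plane) and
a coarse (0.4 mm in-plane) regime at matched noise, runs the Canny detector
on both, and counts border pixels over the whole image and over a crop box
around the smallest vessels — reproducing the direction "finer acquisition,
more detected vessel border" at both image scales.
"""

import logging
from pathlib import Path

import pandas as pd

logging.getLogger("angioqa").setLevel(logging.ERROR)

from angioqa.edges import canny, count_edges, mip
from angioqa.phantom import PhantomSpec, add_noise, build_vessel_tree, rasterize

OUT = Path("results")
OUT.mkdir(exist_ok=True)

tree = build_vessel_tree(seed=1, n_branch_levels=5)
regimes = {
    "fine_0.2mm": PhantomSpec(grid_shape=(200, 200, 56), voxel_size=(0.2, 0.2, 0.5)),
    "coarse_0.4mm": PhantomSpec(grid_shape=(100, 100, 56), voxel_size=(0.4, 0.4, 0.5)),
}
rows = []
for name, spec in regimes.items():
    vol = add_noise(rasterize(tree, spec), 10.0, seed=7)
    img = mip(vol, "axial")
    emap = canny(img, gaussian_sigma=1.4, low=0.1, high=0.2)
    # crop box around the distal (smallest-caliber) half of the projection
    h, w = emap.data.shape
    box = (0, 0, h, w // 2)
    rows.append({
        "regime": name,
        "edge_pixels_total": count_edges(emap),
        "edge_pixels_small_vessel_box": count_edges(emap, box=box),
        **emap.parameters,
    })

df = pd.DataFrame(rows)
df.to_csv(OUT / "edge_counts.csv", index=False)
print(df.to_string(index=False))
fine, coarse = df["edge_pixels_total"]
print(f"\nfine regime detects {fine} border pixels vs {coarse} at the coarse regime "
      f"({'more' if fine > coarse else 'fewer'} border detected at higher resolution)")
print(f"table written to {OUT / 'edge_counts.csv'}")
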