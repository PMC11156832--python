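"""Aggregate the bundled reader-study vessel-visibility scores.

The table holds 0-4 visibility grades for seven vessel categories in four
volunteers, each imaged at two field strengths. This script reproduces the
summary statistics the comparison rests on: grand means per field strength,
the small-vessel and pontine-perforator subset means, per-volunteer totals,
and the detection-rate arithmetic for the pathology comparison.
"""

from pathlib import Path

import pandas as pd

from angioqa.quality_metrics import (
    detection_rate,
    load_reference_scores,
    score_mean,
    score_total,
)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

table = load_reference_scores()
small = ("lenticulostriate", "thalamic_perforating")

rows = []
for fs in ("7T", "3T"):
    rows.append({
        "field_strength": fs,
        "grand_mean": round(score_mean(table, fs), 2),
        "small_vessel_mean": round(score_mean(table, fs, small), 3),
        "pontine_mean": round(score_mean(table, fs, ("pontine_perforating",)), 2),
        **{f"total_volunteer{v}": score_total(table, v, fs) for v in (1, 2, 3, 4)},
    })
df = pd.DataFrame(rows)
df.to_csv(OUT / "score_summary.csv", index=False)
print(df.to_string(index=False))

print(f"\nstenosis detection rate: {detection_rate(16, 19):.1f}% (16 of 19)")
print(f"diagnostic-parameter detection rate: {detection_rate(27, 32):.0f}% (27 of 32)")
print(f"table written to {OUT / 'score_summary.csv'}")
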