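"""ROI-based SNR and CNR estimators, paired nonparametric comparison, and
qualitative-score aggregation.

SNR follows the two-acquisition difference method: for a repeat couple
(A, B) acquired back to back, the ROI mean of the voxelwise average of A
and B is divided by the ROI standard deviation of A - B. The default
``convention="halved"`` estimator is

    SNR = (1 / sqrt(2)) * mean_ROI((A + B) / 2) / sd_ROI(A - B),

half the conventional NEMA difference-method value
(sqrt(2) * mean / sd_diff); ``convention="nema"`` selects the latter. CNR is
the vessel-minus-parenchyma mean difference over the root-sum-squared of the
two ROI standard deviations, computed on the A acquisition only. Standard
deviations are sample (n - 1) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .phantom import AcquisitionPair
from .volume import Volume3D

__all__ = [
    "DegenerateInputError",
    "NoVariabilityError",
    "SnrResult",
    "CnrResult",
    "ScoreTable",
    "load_reference_scores",
    "snr_difference",
    "cnr",
    "aggregate_metric",
    "paired_wilcoxon",
    "score_mean",
    "score_total",
    "detection_rate",
]


class DegenerateInputError(ValueError):
    """An estimator's denominator is identically zero (e.g. a noiseless pair)."""


class NoVariabilityError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass(frozen=True)
class SnrResult:
    acquisition_id: str
    roi_label: str
    snr: float
    mean_signal: float
    sigma_diff: float
    caliber_class: str = ""
    convention: str = "halved"


@dataclass(frozen=True)
class CnrResult:
    acquisition_id: str
    roi_label: str
    cnr: float
    vessel_mean: float
    parenchyma_mean: float
    vessel_sd: float
    parenchyma_sd: float
    caliber_class: str = ""


def _roi_indices(roi_voxels) -> tuple[np.ndarray, ...]:
    """Accept a boolean mask, an (N, 3) index array, or an np.nonzero tuple."""
    if isinstance(roi_voxels, np.ndarray) and roi_voxels.dtype == bool:
        return np.nonzero(roi_voxels)
    if isinstance(roi_voxels, tuple):
        return roi_voxels
    arr = np.asarray(roi_voxels)
    if arr.ndim == 2 and arr.shape[1] == 3:
        return (arr[:, 0], arr[:, 1], arr[:, 2])
    raise ValueError("roi_voxels must be a boolean mask, (N, 3) indices, or an index tuple")


def snr_difference(
    pair: AcquisitionPair,
    roi_voxels,
    acquisition_id: str = "",
    roi_label: str = "",
    caliber_class: str = "",
    convention: str = "halved",
) -> SnrResult:
    """Difference-method SNR over one ROI of a repeat-acquisition pair.

    The pair must already be on a common grid (register first if
    ``true_misalignment`` is not the identity).
    """
    if convention not in ("halved", "nema"):
        raise ValueError(f"convention must be 'halved' or 'nema', got {convention!r}")
    idx = _roi_indices(roi_voxels)
    a = np.asarray(pair.volume_a.data)[idx].astype(float)
    b = np.asarray(pair.volume_b.data)[idx].astype(float)
    if a.size == 0:
        raise ValueError("roi_voxels is empty")
    mean_signal = float(np.mean((a + b) / 2.0))
    sigma_diff = float(np.std(a - b, ddof=1)) if a.size > 1 else 0.0
    if sigma_diff == 0.0:
        raise DegenerateInputError(
            "sd of (A - B) over the ROI is zero; the difference-method SNR is undefined"
        )
    factor = 1.0 / math.sqrt(2.0) if convention == "halved" else math.sqrt(2.0)
    return SnrResult(
        acquisition_id=acquisition_id,
        roi_label=roi_label,
        snr=factor * mean_signal / sigma_diff,
        mean_signal=mean_signal,
        sigma_diff=sigma_diff,
        caliber_class=caliber_class,
        convention=convention,
    )


def cnr(
    volume: Volume3D,
    vessel_roi,
    parenchyma_roi,
    acquisition_id: str = "",
    roi_label: str = "",
    caliber_class: str = "",
) -> CnrResult:
    """Contrast-to-noise ratio between a vessel ROI and its same-size
    adjacent parenchymal ROI, on a single acquisition."""
    v_idx, p_idx = _roi_indices(vessel_roi), _roi_indices(parenchyma_roi)
    v = np.asarray(volume.data)[v_idx].astype(float)
    p = np.asarray(volume.data)[p_idx].astype(float)
    if v.size == 0 or p.size == 0:
        raise ValueError("both ROIs must be non-empty")
    if v.size != p.size:
        raise ValueError(f"paired ROIs must have equal voxel counts, got {v.size} and {p.size}")
    v_sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    p_sd = float(np.std(p, ddof=1)) if p.size > 1 else 0.0
    denom = math.hypot(v_sd, p_sd)
    if denom == 0.0:
        raise DegenerateInputError("both ROI standard deviations are zero; CNR is undefined")
    return CnrResult(
        acquisition_id=acquisition_id,
        roi_label=roi_label,
        cnr=(float(np.mean(v)) - float(np.mean(p))) / denom,
        vessel_mean=float(np.mean(v)),
        parenchyma_mean=float(np.mean(p)),
        vessel_sd=v_sd,
        parenchyma_sd=p_sd,
        caliber_class=caliber_class,
    )


def aggregate_metric(results: list, group_by: str = "acquisition") -> pd.DataFrame:
    """Box-plot-convention summary per group: mean, sd, median, quartiles and
    5th/95th percentiles (linear interpolation between closest ranks).

    Groups with fewer than two entries report sd as NaN (undefined marker).
    """
    if not results:
        raise ValueError("results must be non-empty")
    if group_by not in ("acquisition", "caliber_class"):
        raise ValueError("group_by must be 'acquisition' or 'caliber_class'")
    rows = []
    for r in results:
        value = r.snr if isinstance(r, SnrResult) else r.cnr
        key = r.acquisition_id if group_by == "acquisition" else r.caliber_class
        rows.append({"group": key, "value": value})
    df = pd.DataFrame(rows)
    out = []
    for key in sorted(df["group"].unique()):
        vals = np.sort(df.loc[df["group"] == key, "value"].to_numpy())
        out.append(
            {
                "group": key,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
                "p5": float(np.percentile(vals, 5)),
                "p95": float(np.percentile(vals, 95)),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test (paired, two-sided)
# ---------------------------------------------------------------------------

def _exact_sf_cdf(doubled_ranks: np.ndarray, w2: int) -> float:
    """P(W2 <= w2) under the exact signed-rank null, with W2 the sum of the
    doubled ranks carrying a negative sign; counts by dynamic programming."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return float(counts[: w2 + 1].sum() / counts.sum())


def paired_wilcoxon(values_a, values_b, exact_threshold: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    The null distribution is enumerated exactly (over all sign assignments of
    the observed ranks) for n <= ``exact_threshold`` remaining pairs; above
    that, a normal approximation with continuity and tie correction is used.

    Returns ``(statistic, p_value)`` with the statistic being the sum of the
    ranks of the negative differences.
    """
    from scipy.stats import norm, rankdata

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be 1-D of equal length")
    if a.size < 5:
        raise ValueError(f"need at least 5 pairs, got {a.size}")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise NoVariabilityError("all paired differences are zero")
    ranks = rankdata(np.abs(d))  # mid-ranks for ties
    w_neg = float(ranks[d < 0].sum())
    w_pos = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_threshold:
        doubled = np.round(2.0 * ranks).astype(np.int64)  # mid-ranks -> integers
        w_small2 = int(round(2.0 * min(w_neg, w_pos)))
        p = min(1.0, 2.0 * _exact_sf_cdf(doubled, w_small2))
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(((tie_counts**3 - tie_counts) / 48.0).sum())
        w = min(w_neg, w_pos)
        z = (w - mu + 0.5) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * float(norm.cdf(z)))
    return w_neg, p


# ---------------------------------------------------------------------------
# qualitative score tables
# ---------------------------------------------------------------------------

class ScoreTable:
    """Vessel-category x volunteer x field-strength reader scores (0-4 scale:
    0 not visible, 1 poor, 2 satisfactory, 3 good, 4 excellent visibility)."""

    FIELD_STRENGTHS = ("3T", "7T")

    def __init__(self, frame: pd.DataFrame):
        required = {"vessel_category", "volunteer_id", "field_strength", "score"}
        if not required.issubset(frame.columns):
            raise ValueError(f"score table must have columns {sorted(required)}")
        bad = set(frame["score"]) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"scores must be integers in 0..4, found {sorted(bad)}")
        bad_fs = set(frame["field_strength"]) - set(self.FIELD_STRENGTHS)
        if bad_fs:
            raise ValueError(f"field_strength must be one of {self.FIELD_STRENGTHS}, found {sorted(bad_fs)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls(pd.read_csv(path))

    def categories(self) -> list[str]:
        return sorted(self.frame["vessel_category"].unique())

    def volunteers(self) -> list:
        return sorted(self.frame["volunteer_id"].unique())

    def select(self, field_strength: str, vessel_subset=None, volunteer_id=None) -> pd.DataFrame:
        df = self.frame[self.frame["field_strength"] == field_strength]
        if vessel_subset is not None:
            df = df[df["vessel_category"].isin(list(vessel_subset))]
        if volunteer_id is not None:
            df = df[df["volunteer_id"] == volunteer_id]
        return df


def load_reference_scores() -> ScoreTable:
    """The bundled reader-study score table (7 vessel categories x 4
    volunteers x 2 field strengths) used by the aggregation examples."""
    with resources.files("angioqa.data").joinpath("reader_scores.csv").open("r") as fh:
        return ScoreTable(pd.read_csv(fh))


def score_mean(table: ScoreTable, field_strength: str, vessel_subset=None) -> float:
    """Arithmetic mean score over (category x volunteer) cells at one field
    strength, optionally restricted to a subset of vessel categories."""
    df = table.select(field_strength, vessel_subset)
    if df.empty:
        raise ValueError(
            f"no score cells for field_strength={field_strength!r}, subset={vessel_subset!r}"
        )
    return float(df["score"].mean())


def score_total(table: ScoreTable, volunteer_id, field_strength: str) -> int:
    """Integer sum of the per-category scores for one volunteer; every
    category in the table must be present for that volunteer."""
    df = table.select(field_strength, volunteer_id=volunteer_id)
    missing = set(table.categories()) - set(df["vessel_category"])
    if missing:
        raise ValueError(f"volunteer {volunteer_id!r} is missing categories {sorted(missing)}")
    return int(df["score"].sum())


def detection_rate(n_detected: int, n_reference: int) -> float:
    """Percentage of reference findings detected, 100 * n_detected / n_reference."""
    if n_reference <= 0:
        raise ValueError("n_reference must be > 0")
    if not 0 <= n_detected <= n_reference:
        raise ValueError(f"need 0 <= n_detected <= n_reference, got {n_detected}/{n_reference}")
    return 100.0 * n_detected / n_reference
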