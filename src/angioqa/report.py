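"""End-to-end pipelines: protocol comparison and cross-modality similarity.

``run_protocol_comparison`` mirrors the optimization experiment: for each
acquisition regime (a voxel-size / noise-level pair) it simulates a repeat
pair from one shared vessel tree, registers B to A when misaligned,
propagates the reference-space ROIs into each regime, computes per-ROI SNR
and CNR, aggregates them with box-plot statistics, compares regimes with the
paired Wilcoxon signed-rank test, and counts Canny edge pixels on the axial
MIPs. ``run_similarity_comparison`` renders an angiogram-like perturbed
projection of the same phantom and scores it against the MRA MIP with the
complex-wavelet similarity index.

Seed discipline: every stochastic stage derives its seed from the global
seed through ``numpy.random.SeedSequence(global_seed).spawn``, in a fixed
documented order (per regime: noise A, noise B; then projection noise), so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edges as edges_mod
from . import phantom as phantom_mod
from . import quality_metrics as qm
from . import registration as reg_mod
from . import similarity as sim_mod
from .rigid import RigidTransform, compose, invert
from .volume import write_nifti, write_png

logger = logging.getLogger(__name__)

__all__ = ["Regime", "RunConfig", "ReportBundle", "run_protocol_comparison", "run_similarity_comparison"]


@dataclass(frozen=True)
class Regime:
    """One acquisition regime: grid, voxel size and noise level."""

    name: str
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    noise_sigma: float


def default_regimes(extent_mm: tuple[float, float, float] = (40.0, 40.0, 28.0)) -> list[Regime]:
    """The four voxel-size regimes the analysis compares: three progressively
    finer high-field regimes (0.2 x 0.2 x {0.5, 0.4, 0.3} mm^3) and a coarser
    conventional regime (0.4 x 0.4 x 0.5 mm^3). Noise scales inversely with
    voxel volume relative to the coarse regime so that finer voxels pay the
    expected SNR price."""
    sizes = {
        "acq1_0.2x0.2x0.5": (0.2, 0.2, 0.5),
        "acq2_0.2x0.2x0.4": (0.2, 0.2, 0.4),
        "acq3_0.2x0.2x0.3": (0.2, 0.2, 0.3),
        "acq4_3T_0.4x0.4x0.5": (0.4, 0.4, 0.5),
    }
    ref_vol = float(np.prod(sizes["acq4_3T_0.4x0.4x0.5"]))
    base_sigma = 10.0
    regimes = []
    for name, vs in sizes.items():
        shape = tuple(int(round(e / v)) for e, v in zip(extent_mm, vs))
        sigma = base_sigma * ref_vol / float(np.prod(vs))
        regimes.append(Regime(name=name, grid_shape=shape, voxel_size=vs, noise_sigma=sigma))
    return regimes


@dataclass
class RunConfig:
    """Fully serializable configuration of a pipeline run."""

    seed: int = 0
    extent_mm: tuple[float, float, float] = (40.0, 40.0, 28.0)
    n_branch_levels: int = 5
    regimes: list[Regime] = field(default_factory=default_regimes)
    n_rois: int = 17
    vessel_intensity: float = 300.0
    background_intensity: float = 60.0
    misalignment_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    snr_convention: str = "halved"
    edge_low: float = 0.1
    edge_high: float = 0.2
    edge_sigma: float = 1.4
    similarity: sim_mod.SimilarityConfig = field(default_factory=sim_mod.SimilarityConfig)
    projection_rotation_deg: float = 2.0
    projection_blur_px: float = 1.0
    projection_gamma: float = 1.5
    projection_noise: float = 0.01
    rasterize_subsamples: int = 8
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regimes"] = [asdict(r) for r in self.regimes]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    metrics: pd.DataFrame | None
    summaries: dict
    comparisons: pd.DataFrame | None
    edge_counts: pd.DataFrame | None
    similarity: list
    provenance: dict
    out_dir: Path


def _derive_seeds(global_seed: int, n: int) -> list[int]:
    """Stable per-stage seeds spawned from the global seed, kept below 2^31."""
    ss = np.random.SeedSequence(global_seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def _significance_marks(p: float) -> str:
    # asterisk convention: * p<0.050, ** p<0.010, *** p<0.001
    return "***" if p < 0.001 else "**" if p < 0.010 else "*" if p < 0.050 else ""


def run_protocol_comparison(config: RunConfig, write_files: bool = True) -> ReportBundle:
    out_dir = Path(config.out_dir)
    stage = "setup"
    try:
        if write_files:
            out_dir.mkdir(parents=True, exist_ok=True)
        seeds = _derive_seeds(config.seed, 2 * len(config.regimes) + 1)
        tree = phantom_mod.build_vessel_tree(seeds[-1], config.n_branch_levels, config.extent_mm)

        stage = "reference rasterization"
        finest = min(config.regimes, key=lambda r: float(np.prod(r.voxel_size)))
        ref_spec = phantom_mod.PhantomSpec(
            grid_shape=finest.grid_shape,
            voxel_size=finest.voxel_size,
            vessel_intensity=config.vessel_intensity,
            background_intensity=config.background_intensity,
            noise_sigma=finest.noise_sigma,
        )
        ref_clean = phantom_mod.rasterize(tree, ref_spec, config.rasterize_subsamples)
        stage = "ROI placement"
        # spheres must keep several voxels on every regime's grid after
        # propagation (a one-voxel ROI has no defined SD): floor the radius
        # at the largest voxel dimension and half diagonal across regimes
        half_diag = max(0.5 * float(np.linalg.norm(r.voxel_size)) for r in config.regimes)
        max_dim = max(max(r.voxel_size) for r in config.regimes)
        rois = reg_mod.build_roi_set(
            tree, ref_clean, n_rois=config.n_rois, seed=config.seed,
            min_sphere_radius_mm=max(0.45, half_diag + 0.05, max_dim + 0.05),
        )

        misalign = RigidTransform.from_euler_deg((0, 0, 0), config.misalignment_mm)
        rows: list[dict] = []
        edge_rows: list[dict] = []
        for ridx, regime in enumerate(config.regimes):
            stage = f"regime {regime.name}"
            spec = phantom_mod.PhantomSpec(
                grid_shape=regime.grid_shape,
                voxel_size=regime.voxel_size,
                vessel_intensity=config.vessel_intensity,
                background_intensity=config.background_intensity,
                noise_sigma=regime.noise_sigma,
            )
            clean = (
                ref_clean
                if regime.voxel_size == finest.voxel_size
                else phantom_mod.rasterize(tree, spec, config.rasterize_subsamples)
            )
            pair = phantom_mod.make_pair(
                clean, regime.noise_sigma, seeds[2 * ridx], seeds[2 * ridx + 1], misalignment=misalign
            )
            if not misalign.is_identity():
                res = reg_mod.estimate_rigid(pair.volume_b, pair.volume_a, n_levels=3)
                vol_b = reg_mod.resample_linear(pair.volume_b, res.transform, pair.volume_a)
                pair = phantom_mod.AcquisitionPair(pair.volume_a, vol_b, pair.true_misalignment)
            # propagate reference-space ROIs into this regime's native grid
            regime_rois = (
                rois
                if regime.voxel_size == finest.voxel_size
                else reg_mod.propagate_rois(rois, RigidTransform.identity(), clean)
            )
            for v_lab in regime_rois.vessel_labels():
                meta = regime_rois.labels[v_lab]
                v_idx = regime_rois.indices(v_lab)
                p_idx = regime_rois.indices(regime_rois.pairing[v_lab])
                snr_res = qm.snr_difference(
                    pair, v_idx, acquisition_id=regime.name, roi_label=meta.name,
                    caliber_class=meta.caliber_class, convention=config.snr_convention,
                )
                n_pair = min(len(v_idx[0]), len(p_idx[0]))  # propagated counts may differ
                cnr_res = qm.cnr(
                    pair.volume_a,
                    tuple(ix[:n_pair] for ix in v_idx),
                    tuple(ix[:n_pair] for ix in p_idx),
                    acquisition_id=regime.name, roi_label=meta.name, caliber_class=meta.caliber_class,
                )
                rows.append(
                    {
                        "acquisition_id": regime.name,
                        "roi_label": meta.name,
                        "caliber_class": meta.caliber_class,
                        "snr": snr_res.snr,
                        "cnr": cnr_res.cnr,
                    }
                )
            stage = f"edges for {regime.name}"
            m = edges_mod.mip(pair.volume_a, "axial")
            emap = edges_mod.canny(m, config.edge_sigma, config.edge_low, config.edge_high)
            edge_rows.append(
                {
                    "acquisition_id": regime.name,
                    "edge_pixels": edges_mod.count_edges(emap),
                    "image_shape": str(m.shape),
                    **emap.parameters,
                }
            )
            if write_files:
                write_nifti(pair.volume_a, out_dir / f"{regime.name}_A.nii.gz")
                write_png(m, out_dir / f"{regime.name}_mip.png")

        stage = "aggregation"
        metrics = pd.DataFrame(rows)
        snr_results = [
            qm.SnrResult(r["acquisition_id"], r["roi_label"], r["snr"], 0, 1, r["caliber_class"])
            for r in rows
        ]
        cnr_results = [
            qm.CnrResult(r["acquisition_id"], r["roi_label"], r["cnr"], 0, 0, 1, 1, r["caliber_class"])
            for r in rows
        ]
        summaries = {
            "snr_by_acquisition": qm.aggregate_metric(snr_results, "acquisition"),
            "cnr_by_acquisition": qm.aggregate_metric(cnr_results, "acquisition"),
            "cnr_by_caliber": qm.aggregate_metric(cnr_results, "caliber_class"),
        }

        stage = "paired comparisons"
        comp_rows = []
        names = [r.name for r in config.regimes]
        for metric in ("snr", "cnr"):
            wide = metrics.pivot(index="roi_label", columns="acquisition_id", values=metric)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a = wide[names[i]].to_numpy()
                    b = wide[names[j]].to_numpy()
                    try:
                        stat, p = qm.paired_wilcoxon(a, b)
                        mark = _significance_marks(p)
                    except qm.NoVariabilityError:
                        stat, p, mark = float("nan"), float("nan"), "degenerate"
                    comp_rows.append(
                        {"metric": metric, "a": names[i], "b": names[j], "statistic": stat,
                         "p_value": p, "significance": mark}
                    )
        comparisons = pd.DataFrame(comp_rows)
        if not comparisons["p_value"].isna().all():
            # optional Holm adjustment column alongside the unadjusted p-values
            pvals = comparisons["p_value"].to_numpy()
            order = np.argsort(pvals)
            holm = np.full_like(pvals, np.nan)
            m = np.sum(~np.isnan(pvals))
            running = 0.0
            for rank, idx in enumerate(order[:m]):
                running = max(running, (m - rank) * pvals[idx])
                holm[idx] = min(1.0, running)
            comparisons["p_holm"] = holm

        edge_counts = pd.DataFrame(edge_rows)
        provenance = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seeds": _derive_seeds(config.seed, 2 * len(config.regimes) + 1),
            "software": "angioqa 0.1.0",
        }
        if write_files:
            metrics.sort_values(["acquisition_id", "roi_label"]).to_csv(out_dir / "metrics.csv", index=False)
            comparisons.to_csv(out_dir / "comparisons.csv", index=False)
            edge_counts.to_csv(out_dir / "edge_counts.csv", index=False)
            for name, df in summaries.items():
                df.to_csv(out_dir / f"summary_{name}.csv", index=False)
            (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
        return ReportBundle(metrics, summaries, comparisons, edge_counts, [], provenance, out_dir)
    except Exception as exc:  # annotate failures with the stage and config hash
        raise RuntimeError(f"protocol comparison failed at stage '{stage}' (config {config.config_hash()})") from exc


def run_similarity_comparison(config: RunConfig, rotations_deg: list[float] | None = None,
                              write_files: bool = True) -> ReportBundle:
    """MRA MIP vs perturbed same-phantom projection, over a perturbation sweep."""
    out_dir = Path(config.out_dir)
    stage = "setup"
    try:
        if write_files:
            out_dir.mkdir(parents=True, exist_ok=True)
        rotations = rotations_deg if rotations_deg is not None else [config.projection_rotation_deg]
        seeds = _derive_seeds(config.seed, len(rotations) + 1)
        tree = phantom_mod.build_vessel_tree(seeds[-1], config.n_branch_levels, config.extent_mm)
        finest = min(config.regimes, key=lambda r: float(np.prod(r.voxel_size)))
        spec = phantom_mod.PhantomSpec(
            grid_shape=finest.grid_shape,
            voxel_size=finest.voxel_size,
            vessel_intensity=config.vessel_intensity,
            background_intensity=config.background_intensity,
            noise_sigma=finest.noise_sigma,
        )
        stage = "rasterization"
        clean = phantom_mod.rasterize(tree, spec, config.rasterize_subsamples)
        mra = phantom_mod.add_noise(clean, finest.noise_sigma, seeds[0])
        mra_mip = edges_mod.mip(mra, "axial")
        results = []
        for k, rot in enumerate(rotations):
            stage = f"projection rot={rot}"
            dsa_like = phantom_mod.project_dsa_like(
                mra, "axial", rotation_deg=rot, blur_sigma_px=config.projection_blur_px,
                intensity_gamma=config.projection_gamma, seed=seeds[k],
                noise_sigma=config.projection_noise,
            )
            stage = f"similarity rot={rot}"
            res = sim_mod.compare_modality(mra_mip, dsa_like, config.similarity)
            results.append({"rotation_deg": rot, "cwssi": res.cwssi,
                            "per_band": {f"{s}_{o}": v for (s, o), v in res.per_band.items()},
                            "preprocessing_log": res.preprocessing_log})
        provenance = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seeds": seeds,
            "software": "angioqa 0.1.0",
        }
        if write_files:
            (out_dir / "similarity.json").write_text(json.dumps(
                {"results": results, "provenance": provenance}, indent=2, default=str))
        return ReportBundle(None, {}, None, None, results, provenance, out_dir)
    except Exception as exc:
        raise RuntimeError(f"similarity comparison failed at stage '{stage}' (config {config.config_hash()})") from exc
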