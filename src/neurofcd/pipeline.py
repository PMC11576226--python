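"""End-to-end study orchestration.

``run_study`` executes the whole analysis on a synthetic (or ingested)
study: SUVR normalization per participant, per-participant FCD maps, group
mean maps, whole-map and within-ROI/network associations, the two-step
Bonferroni + spin correction, and the second-level correlation between FCD
magnitude and SUVR-FCD coupling strength.  Everything is deterministic given
the study seed.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import (
    bonferroni_step,
    normality_check,
    roi_mean,
    second_level_association,
    within_roi_association,
)
from .fcd import FcdConfig, log_fcd, participant_fcd, smooth_log_fcd
from .io_volumes import Parcellation, Volume3D, write_table
from .masks_suvr import (
    compute_suvr,
    gaussian_smooth,
    gray_matter_mask,
    threshold_suvr,
    white_matter_reference_mask,
)
from .spin_perm import (
    attach_shell_coordinates,
    build_icosphere,
    sample_volume_at_vertices,
    spin_pvalue,
    spin_test_roi,
)
from .synthetic import SyntheticConfig, SyntheticStudy, default_study_config, generate_study


class StageError(RuntimeError):
    def __init__(self, stage: str, participant=None, cause: Exception | None = None):
        self.stage = stage
        self.participant = participant
        who = f" (participant {participant})" if participant is not None else ""
        super().__init__(f"pipeline stage '{stage}'{who} failed: {cause}")


@dataclass
class StudyConfig:
    """Desk-scale study defaults.

    The synthetic head is roughly a third of a real head's extent, so the
    default smoothing kernels are scale-matched at 4 mm FWHM; set both to
    8 mm (the operation defaults) together with a full-size grid for
    paper-scale settings.
    """

    synthetic: SyntheticConfig = None
    fcd: FcdConfig = field(default_factory=lambda: FcdConfig(smoothing_fwhm_mm=4.0))
    alpha: float = 0.05
    m_tests: int | None = None  # defaults to n_rois + n_networks
    n_perm: int = 200
    mesh_order: int = 3
    suvr_fwhm_mm: float = 4.0
    n_rois: int = 10
    seed: int = 0
    include_gfcd: bool = True

    def __post_init__(self):
        if self.synthetic is None:
            self.synthetic = default_study_config(seed=self.seed)


@dataclass
class StudyReport:
    whole_map: dict  # metric -> {rho, p, p_spin, ...}
    roi_results: dict  # metric -> list[AssociationResult]
    network_results: dict
    second_level: dict  # metric -> {rho, p, n_rois} or {"status": "not computed"}
    normality: pd.DataFrame
    roi_mean_table: pd.DataFrame
    manifest: dict


def _suvr_pipeline(pet, wm, gm_prob, csf, gm_mask, fwhm_mm):
    ref = white_matter_reference_mask(wm, gm_prob, csf)
    raw = compute_suvr(pet, ref)
    smoothed = gaussian_smooth(Volume3D(raw.grid, raw.values), fwhm_mm)
    from .masks_suvr import SuvrMap

    return threshold_suvr(SuvrMap(raw.grid, smoothed.values, raw.reference_mean), gm_mask)


def _mean_map(maps, grid) -> Volume3D:
    """Missing-aware voxel-wise mean over participants (all-missing stays missing)."""
    import warnings as _warnings

    stack = np.stack([m.values for m in maps])
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return Volume3D(grid, mean)


def load_study(directory: str, sampling_interval_s: float = 2.5) -> SyntheticStudy:
    """Ingest a study from a directory laid out like the simulator's output.

    Expects manifest.tsv (columns participant/bold/pet, paths relative to the
    directory), wm_prob/gm_prob/csf_prob volumes, parcellation.nii.gz and
    labels.tsv.  Ground truth is taken from truth_*_degree volumes when
    present, else left all-zero (real data has no planted truth).
    """
    from .io_volumes import read_parcellation, read_volume
    from .synthetic import GroundTruth

    def vol(name):
        return read_volume(os.path.join(directory, name))

    manifest = pd.read_csv(os.path.join(directory, "manifest.tsv"), sep="\t")
    bold = [read_volume(os.path.join(directory, os.path.basename(row.bold)),
                        sampling_interval_s=sampling_interval_s)
            for row in manifest.itertuples()]
    pet = [vol(os.path.basename(row.pet)) for row in manifest.itertuples()]
    wm, gm, csf = vol("wm_prob.nii.gz"), vol("gm_prob.nii.gz"), vol("csf_prob.nii.gz")
    parc = read_parcellation(os.path.join(directory, "parcellation.nii.gz"),
                             os.path.join(directory, "labels.tsv"))
    from .io_volumes import check_grid_compatibility

    check_grid_compatibility(bold + pet + [wm, gm, csf, parc])
    grid = wm.grid
    syn = SyntheticConfig(grid_shape=grid.shape, voxel_size_mm=grid.voxel_size_mm[0],
                          n_participants=len(bold),
                          sampling_interval_s=sampling_interval_s)
    zeros = np.zeros(grid.shape, dtype=np.int64)
    try:
        local = vol("truth_local_degree.nii.gz").values.astype(np.int64)
        longd = vol("truth_long_degree.nii.gz").values.astype(np.int64)
    except FileNotFoundError:
        local, longd = zeros, zeros.copy()
    truth = GroundTruth(local, longd, beta=0.0, participant_seeds=())
    return SyntheticStudy(syn, truth, wm, gm, csf, parc, bold, pet)


def run_study(config: StudyConfig, study: SyntheticStudy | None = None,
              progress=None) -> StudyReport:
    """Execute the full pipeline; see the module docstring for the stage order."""
    log = progress if progress is not None else (lambda msg: None)
    syn = config.synthetic

    def stage(name, fn, participant=None):
        log(name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, participant, exc) from exc

    if study is None:
        study = stage("generate-study", lambda: generate_study(syn, n_rois=config.n_rois))
    parc = study.parcellation
    gm_mask = stage("gray-matter-mask", lambda: gray_matter_mask(study.gm_prob))

    suvr_maps, fcd_maps = [], []
    for p in range(syn.n_participants):
        suvr_maps.append(stage(
            "suvr", lambda p=p: _suvr_pipeline(
                study.pet[p], study.wm_prob, study.gm_prob, study.csf_prob,
                gm_mask, config.suvr_fwhm_mm), participant=p))
        fcd_maps.append(stage(
            "fcd", lambda p=p: participant_fcd(study.bold[p], gm_mask, config.fcd),
            participant=p))

    grid = syn.grid
    mean_suvr = _mean_map(suvr_maps, grid)
    metric_means = {
        "srfcd": _mean_map([f.srfcd for f in fcd_maps], grid),
        "lrfcd": _mean_map([f.lrfcd for f in fcd_maps], grid),
    }
    if config.include_gfcd:
        log_g = [smooth_log_fcd(log_fcd(f.gfcd_raw, config.fcd, allow_gfcd=True),
                                config.fcd.smoothing_fwhm_mm) for f in fcd_maps]
        metric_means["gfcd"] = _mean_map(log_g, grid)

    rois = parc.roi_labels
    networks = sorted(parc.networks)
    m_tests = config.m_tests if config.m_tests is not None else len(rois) + len(networks)

    whole_map = {}
    for metric, mean_fcd in metric_means.items():
        whole_map[metric] = stage(
            f"whole-map-association-{metric}",
            lambda mf=mean_fcd: _whole_map(mean_suvr, mf, parc))

    participant_metric_maps = {
        "srfcd": [f.srfcd for f in fcd_maps],
        "lrfcd": [f.lrfcd for f in fcd_maps],
    }
    roi_results, network_results = {}, {}
    for metric, maps in participant_metric_maps.items():
        roi_results[metric] = [
            stage(f"within-roi-{metric}",
                  lambda r=r, maps=maps: within_roi_association(suvr_maps, maps, parc, r, metric))
            for r in rois
        ]
        network_results[metric] = [
            stage(f"within-network-{metric}",
                  lambda g=g, maps=maps: within_roi_association(suvr_maps, maps, parc, g, metric))
            for g in networks
        ]
        stage(f"bonferroni-{metric}", lambda metric=metric: bonferroni_step(
            roi_results[metric] + network_results[metric], alpha=config.alpha, m=m_tests))

    # --- spin step (only on Bonferroni survivors, spinnable regions only) ---
    mesh = stage("mesh", lambda: _study_mesh(config))
    vertex_suvr = stage("vertex-sampling", lambda: sample_volume_at_vertices(mean_suvr, mesh))
    vertex_labels = sample_volume_at_vertices(parc_as_volume(parc), mesh, mode="nearest")
    vertex_metrics = {
        metric: sample_volume_at_vertices(mean_map, mesh)
        for metric, mean_map in metric_means.items()
    }
    net_spinnable = {
        g: any(parc.label_table[lab].spinnable for lab in labs)
        for g, labs in parc.networks.items()
    }

    for metric in participant_metric_maps:
        vm = vertex_metrics[metric]
        whole_map[metric]["p_spin"] = stage(
            f"spin-whole-{metric}",
            lambda vm=vm: spin_pvalue(vertex_suvr, vm, n_perm=config.n_perm,
                                      seed=config.seed).p)
        for res in roi_results[metric]:
            if not res.p_bonferroni_passed:
                continue
            try:
                spin = spin_test_roi(
                    vertex_suvr, vm, vertex_labels, int(res.roi),
                    n_perm=config.n_perm, seed=config.seed,
                    spinnable=parc.label_table[int(res.roi)].spinnable)
            except ValueError:
                # too few usable vertices: the spherical projection does not
                # cover this region at the configured mesh resolution
                res.spin_status = "not_covered"
                continue
            res.p_spin = None if spin.status == "not_covered" else spin.p
            res.spin_status = spin.status
        for res in network_results[metric]:
            if not res.p_bonferroni_passed:
                continue
            if not net_spinnable[res.roi]:
                res.spin_status = "not_covered"
                continue
            labs = [lab for lab in parc.networks[res.roi] if parc.label_table[lab].spinnable]
            restrict = np.isin(vertex_labels.values, labs)
            if restrict.sum() < 10:
                res.spin_status = "not_covered"
                continue
            try:
                spin = spin_pvalue(vertex_suvr, vm, n_perm=config.n_perm,
                                   seed=config.seed, restrict=restrict)
            except ValueError:
                res.spin_status = "not_covered"
                continue
            res.p_spin = spin.p
            res.spin_status = "tested"

    # --- second level: FCD magnitude vs coupling strength across survivors ---
    second_level = {}
    for metric in participant_metric_maps:
        fcd_roi_means = {}
        for r in rois:
            try:
                fcd_roi_means[r] = roi_mean(metric_means[metric], parc, r)
            except ValueError:
                fcd_roi_means[r] = np.nan
        try:
            second_level[metric] = second_level_association(roi_results[metric], fcd_roi_means)
        except ValueError as exc:
            second_level[metric] = {"status": "not computed", "reason": str(exc)}

    normality = stage("normality", lambda: _normality_table(
        mean_suvr, metric_means, roi_results))

    roi_mean_table = _roi_mean_table(mean_suvr, metric_means, parc)
    manifest = _manifest(config)
    return StudyReport(
        whole_map=whole_map,
        roi_results=roi_results,
        network_results=network_results,
        second_level=second_level,
        normality=normality,
        roi_mean_table=roi_mean_table,
        manifest=manifest,
    )


def _whole_map(mean_suvr, mean_fcd, parc):
    from .association_stats import whole_map_association

    out = whole_map_association(mean_suvr, mean_fcd, parc)
    return {"rho": out["rho"], "p": out["p"], "n_rois": out["n_rois"]}


def parc_as_volume(parc: Parcellation) -> Volume3D:
    return Volume3D(parc.grid, parc.labels.astype(np.float64))


def _study_mesh(config: StudyConfig):
    syn = config.synthetic
    grid = syn.grid
    center_mm = grid.voxel_to_mm((np.asarray(grid.shape) - 1) / 2.0)
    shell_frac = 0.5 * (syn.gm_inner_frac + syn.gm_outer_frac)
    radius_mm = shell_frac * min(grid.shape) * min(grid.voxel_size_mm)
    mesh = build_icosphere(config.mesh_order)
    return attach_shell_coordinates(mesh, center_mm, radius_mm)


def _normality_table(mean_suvr, metric_means, roi_results) -> pd.DataFrame:
    rows = []
    vals = mean_suvr.values[~np.isnan(mean_suvr.values)]
    rows.append({"quantity": "mean_suvr_voxels", **normality_check(vals, "ks")})
    for metric, vol in metric_means.items():
        vals = vol.values[~np.isnan(vol.values)]
        rows.append({"quantity": f"mean_{metric}_voxels", **normality_check(vals, "ks")})
    for metric, results in roi_results.items():
        zs = np.array([r.mean_z for r in results])
        if len(zs) >= 3 and not np.all(zs == zs[0]):
            rows.append({"quantity": f"roi_mean_z_{metric}", **normality_check(zs, "shapiro_wilk")})
    return pd.DataFrame(rows)


def _roi_mean_table(mean_suvr, metric_means, parc) -> pd.DataFrame:
    rows = []
    for r in parc.roi_labels:
        row = {"roi": r, "name": parc.label_table[r].name, "group": parc.label_table[r].group}
        for tag, vol in [("suvr", mean_suvr)] + list(metric_means.items()):
            try:
                row[f"mean_{tag}"] = roi_mean(vol, parc, r)
            except ValueError:
                row[f"mean_{tag}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _manifest(config: StudyConfig) -> dict:
    import nibabel
    import scipy

    cfg = {
        "synthetic": asdict(config.synthetic),
        "fcd": asdict(config.fcd),
        "alpha": config.alpha,
        "m_tests": config.m_tests,
        "n_perm": config.n_perm,
        "mesh_order": config.mesh_order,
        "suvr_fwhm_mm": config.suvr_fwhm_mm,
        "n_rois": config.n_rois,
        "seed": config.seed,
    }
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "versions": {
            "python": sys.version.split()[0],
            "neurofcd": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
        },
    }


def _result_rows(results: dict, kind: str) -> list[dict]:
    rows = []
    for metric, items in results.items():
        for res in items:
            rows.append({
                "id": res.roi,
                "kind": kind,
                "metric": metric,
                "mean_z": res.mean_z,
                "mean_rho": res.mean_rho_backtransformed,
                "mean_rho_arithmetic": res.mean_rho_arithmetic,
                "p_raw": res.p_raw,
                "bonferroni_passed": bool(res.p_bonferroni_passed),
                "p_spin": res.p_spin if res.p_spin is not None else np.nan,
                "spin_status": (res.spin_status if res.p_bonferroni_passed
                                else "failed_bonferroni"),
                "significant": bool(
                    res.p_bonferroni_passed
                    and (res.spin_status == "not_covered"
                         or (res.p_spin is not None and res.p_spin < 0.05))
                ),
                "n_voxels": res.n_voxels,
            })
    return rows


def summarize(report: StudyReport, out_dir: str | None = None) -> str:
    """Human-readable summary; optionally write the result tables under ``out_dir``."""
    rows = _result_rows(report.roi_results, "roi") + _result_rows(report.network_results, "network")
    table = pd.DataFrame(rows).sort_values("mean_z", ascending=False).reset_index(drop=True)

    lines = ["== whole-map associations (Spearman across ROIs) =="]
    for metric, res in report.whole_map.items():
        spin = f", spin p = {res['p_spin']:.4g}" if "p_spin" in res else ""
        lines.append(f"  SUVR vs {metric}: rho = {res['rho']:.3f}, p = {res['p']:.3g}{spin}")
    lines.append("== per-ROI/network results (sorted by mean z) ==")
    for _, row in table.iterrows():
        status = ("failed Bonferroni" if row["spin_status"] == "failed_bonferroni"
                  else "not covered" if row["spin_status"] == "not_covered"
                  else "survived both steps" if row["significant"]
                  else "failed spin")
        lines.append(
            f"  {row['kind']} {row['id']} [{row['metric']}]: mean z = {row['mean_z']:.3f} "
            f"(rho = {row['mean_rho']:.3f}), p = {row['p_raw']:.3g} -> {status}"
        )
    lines.append("== second-level (FCD magnitude vs coupling strength) ==")
    for metric, res in report.second_level.items():
        if "rho" in res:
            lines.append(f"  {metric}: rho = {res['rho']:.3f}, p = {res['p']:.3g} "
                         f"over {res['n_rois']} surviving ROIs")
        else:
            lines.append(f"  {metric}: not computed ({res.get('reason', '')})")
    text = "\n".join(lines)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_table(table, os.path.join(out_dir, "associations.tsv"))
        write_table(report.roi_mean_table, os.path.join(out_dir, "roi_means.tsv"))
        write_table(report.normality, os.path.join(out_dir, "normality.tsv"))
        wm_rows = [{"metric": m, **{k: v for k, v in r.items()}}
                   for m, r in report.whole_map.items()]
        write_table(pd.DataFrame(wm_rows), os.path.join(out_dir, "whole_map.tsv"))
        sl_rows = [{"metric": m, **{k: str(v) for k, v in r.items()}}
                   for m, r in report.second_level.items()]
        write_table(pd.DataFrame(sl_rows), os.path.join(out_dir, "second_level.tsv"))
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(report.manifest, fh, indent=2, default=str)
        with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
            fh.write(text + "\n")
    return text
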