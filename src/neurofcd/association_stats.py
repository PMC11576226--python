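"""Two-level association between receptor density (SUVR) and FCD maps.

Level one works on group-mean maps: ROI means of the mean SUVR and mean FCD
maps are correlated across ROIs with Spearman's rank test.  Level two works
within each ROI (or network): for every participant, the voxel-wise Spearman
correlation between the participant's SUVR and FCD maps inside the ROI is
computed, Fisher z-transformed, and the per-ROI group p-value comes from a
two-sided one-sample t-test of the z values against zero.  Multiple
comparisons over ROIs plus networks are handled with a strict Bonferroni
step (p < alpha/m); a spherical permutation (spin) step may follow.

All inference is rank-based, so the base of the FCD log transform and any
monotone rescaling of either map leave every statistic unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io_volumes import Parcellation, check_grid_compatibility

Z_CLIP = np.arctanh(1 - 1e-7)


@dataclass
class AssociationResult:
    roi: object  # ROI label (int) or network name (str)
    metric: str
    rhos: np.ndarray  # per-participant Spearman rho
    zs: np.ndarray  # per-participant Fisher z
    mean_z: float
    mean_rho_backtransformed: float
    mean_rho_arithmetic: float
    p_raw: float
    n_voxels: int
    p_bonferroni_passed: bool | None = None
    p_spin: float | None = None
    spin_status: str = "pending"  # pending | tested | not_covered


def roi_mean(vol, parc: Parcellation, roi: int) -> float:
    """Arithmetic mean over present (non-missing) voxels carrying the ROI label."""
    check_grid_compatibility([vol, parc])
    sel = parc.roi_mask(roi) & ~np.isnan(vol.values)
    if not sel.any():
        raise ValueError(f"ROI {roi} has no present voxels")
    return float(vol.values[sel].mean())


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with the large-sample two-sided p.

    ``exact=True`` replaces the t approximation with full permutation
    enumeration of the second argument's ranks (only for n <= 8, where the
    8! = 40,320 arrangements are enumerable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    if exact:
        if x.size > 8:
            raise ValueError("exact permutation p is only supported for n <= 8")
        from itertools import permutations

        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        null = np.array([np.corrcoef(rx, np.asarray(perm))[0, 1]
                         for perm in permutations(ry)])
        p = float((np.abs(null) >= abs(rho) - 1e-12).mean())
    return float(rho), float(p)


def fisher_z(rho: float) -> float:
    """Variance-stabilizing atanh transform; |rho| = 1 is clipped with a warning."""
    if abs(rho) > 1:
        raise ValueError("|rho| must not exceed 1")
    if abs(rho) == 1:
        warnings.warn("|rho| = 1 clipped before Fisher z", stacklevel=2)
        return float(np.sign(rho) * Z_CLIP)
    return float(np.arctanh(rho))


def whole_map_association(mean_suvr, mean_fcd, parc: Parcellation,
                          rois: list[int] | None = None) -> dict:
    """Spearman correlation of ROI means of two group-mean maps across ROIs."""
    rois = parc.roi_labels if rois is None else list(rois)
    if len(rois) < 5:
        raise ValueError("need at least 5 ROIs")
    a = np.array([roi_mean(mean_suvr, parc, r) for r in rois])
    b = np.array([roi_mean(mean_fcd, parc, r) for r in rois])
    rho, p = spearman(a, b)
    return {"rho": rho, "p": p, "n_rois": len(rois),
            "roi_means_suvr": a, "roi_means_fcd": b, "rois": rois}


def paired_association(x_per_participant, y_per_participant, roi, metric: str,
                       min_voxels: int = 5) -> AssociationResult:
    """Group inference from per-participant paired value vectors.

    Each participant contributes one Spearman rho over the paired values;
    rhos are Fisher z-transformed and tested against zero with a two-sided
    one-sample t-test.
    """
    rhos, ns = [], []
    for x, y in zip(x_per_participant, y_per_participant):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < min_voxels:
            raise ValueError(
                f"ROI {roi}: fewer than {min_voxels} present paired voxels for a participant"
            )
        rho, _ = spearman(x[ok], y[ok])
        rhos.append(rho)
        ns.append(int(ok.sum()))
    rhos = np.asarray(rhos)
    zs = np.array([fisher_z(r) for r in rhos])
    t_res = sps.ttest_1samp(zs, 0.0)
    return AssociationResult(
        roi=roi,
        metric=metric,
        rhos=rhos,
        zs=zs,
        mean_z=float(zs.mean()),
        mean_rho_backtransformed=float(np.tanh(zs.mean())),
        mean_rho_arithmetic=float(rhos.mean()),
        p_raw=float(t_res.pvalue),
        n_voxels=int(np.mean(ns)),
    )


def within_roi_association(suvr_maps, fcd_maps, parc: Parcellation, roi,
                           metric: str = "srfcd") -> AssociationResult:
    """Per-participant voxel-wise Spearman inside one ROI (or network), pooled.

    ``roi`` may be an integer ROI label or a network name from the label
    table groups.
    """
    if isinstance(roi, str):
        sel = parc.network_mask(roi)
    else:
        sel = parc.roi_mask(int(roi))
    if not sel.any():
        raise ValueError(f"ROI/network {roi} selects no voxels")
    xs = [m.values[sel] for m in suvr_maps]
    ys = [m.values[sel] for m in fcd_maps]
    return paired_association(xs, ys, roi, metric)


def normality_check(values, method: str = "ks") -> dict:
    """Normality diagnostics: Lilliefors-corrected KS or Shapiro-Wilk.

    Reporting only — downstream inference is always rank-based.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if np.all(values == values[0]):
        raise ValueError("constant input")
    if method == "ks":
        if values.size < 8:
            raise ValueError("KS check needs at least 8 values")
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(values, dist="norm")
    elif method == "shapiro_wilk":
        if values.size < 3:
            raise ValueError("Shapiro-Wilk needs at least 3 values")
        stat, p = sps.shapiro(values)
    else:
        raise ValueError("method must be 'ks' or 'shapiro_wilk'")
    return {"statistic": float(stat), "p": float(p), "method": method, "n": int(values.size)}


def bonferroni_step(results: list[AssociationResult], alpha: float = 0.05,
                    m: int | None = None) -> list[AssociationResult]:
    """Strict Bonferroni: passed iff p_raw < alpha/m (m defaults to len(results))."""
    if m is None:
        m = len(results)
    if m < 1:
        raise ValueError("m must be at least 1")
    if m < len(results):
        raise ValueError(f"m = {m} smaller than the number of tests ({len(results)})")
    for res in results:
        res.p_bonferroni_passed = bool(res.p_raw < alpha / m)
    return results


def second_level_association(results: list[AssociationResult], fcd_roi_means: dict) -> dict:
    """Correlation, across surviving ROIs, between FCD magnitude and coupling strength.

    ``fcd_roi_means`` maps ROI id to the ROI's group-mean FCD value; only
    ROIs that survived both correction steps enter.
    """
    surv = [
        r for r in results
        if r.p_bonferroni_passed
        and (r.spin_status == "not_covered" or (r.p_spin is not None and r.p_spin < 0.05))
    ]
    if len(surv) < 5:
        raise ValueError(f"need at least 5 surviving ROIs, got {len(surv)}")
    fcd_vals = np.array([fcd_roi_means[r.roi] for r in surv])
    zs = np.array([r.mean_z for r in surv])
    rho, p = spearman(fcd_vals, zs)
    return {"rho": rho, "p": p, "n_rois": len(surv), "rois": [r.roi for r in surv]}
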