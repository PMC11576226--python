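"""Independent brute-force oracles, written separately from the library code.

These deliberately use the most literal formulations available — full
correlation matrices from ``np.corrcoef``, explicit queue-based breadth-first
search over python sets, direct kernel sums — so they share no code path with
the implementations they check.
"""

from __future__ import annotations

import numpy as np


def correlation_matrix(bold, mask) -> tuple[np.ndarray, np.ndarray]:
    """(N, N) Pearson matrix over mask voxels plus the (N, 3) coordinates."""
    coords = np.argwhere(mask.membership)
    series = np.array([bold.data[tuple(c)] for c in coords])
    return np.corrcoef(series), coords


def gfcd_oracle(bold, mask, threshold: float = 0.6) -> np.ndarray:
    """Exhaustive pair counting: for each voxel, #{j != i : C_ij > T}."""
    corr, coords = correlation_matrix(bold, mask)
    n = len(coords)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and corr[i, j] > threshold:
                counts[i] += 1
    out = np.full(mask.grid.shape, np.nan)
    out[tuple(coords.T)] = counts
    return out


def _adjacent(a, b, neighborhood: int) -> bool:
    d = np.abs(np.asarray(a) - np.asarray(b))
    if np.any(d > 1) or np.all(d == 0):
        return False
    nd = int((d > 0).sum())
    if neighborhood == 6:
        return nd == 1
    if neighborhood == 18:
        return nd <= 2
    return True  # 26-connected


def lfcd_oracle(bold, mask, threshold: float = 0.6, neighborhood: int = 26) -> np.ndarray:
    """Breadth-first cluster growing from each seed.

    A voxel may join the cluster when its correlation with the *seed* exceeds
    the threshold and it is adjacent to some voxel already in the cluster;
    the count is the final cluster size minus one.
    """
    corr, coords = correlation_matrix(bold, mask)
    n = len(coords)
    coord_list = [tuple(c) for c in coords]
    counts = np.zeros(n, dtype=int)
    for seed in range(n):
        supra = {j for j in range(n) if j != seed and corr[seed, j] > threshold}
        cluster = {seed}
        queue = [seed]
        while queue:
            current = queue.pop(0)
            for j in list(supra):
                if j not in cluster and _adjacent(coord_list[current], coord_list[j], neighborhood):
                    cluster.add(j)
                    queue.append(j)
        counts[seed] = len(cluster) - 1
    out = np.full(mask.grid.shape, np.nan)
    out[tuple(coords.T)] = counts
    return out


def masked_smooth_oracle(values, present, grid, fwhm_mm: float, at_voxel) -> float:
    """Renormalized Gaussian-weighted average over present voxels at one voxel."""
    sigma = np.asarray([fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / v
                        for v in grid.voxel_size_mm])
    center = np.asarray(at_voxel, dtype=float)
    num = den = 0.0
    for idx in np.argwhere(present):
        d = (idx - center) / sigma
        w = np.exp(-0.5 * float(d @ d))
        num += w * values[tuple(idx)]
        den += w
    return num / den
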