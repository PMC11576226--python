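"""Voxel-wise functional connectivity density (FCD) mapping.

Every in-mask voxel is a node; an edge joins voxels i and j when the Pearson
correlation of their BOLD time series C_ij strictly exceeds the threshold
(default 0.6, one-sided: only positive correlations count).

* gFCD (global FCD) at voxel i counts all in-mask voxels j with C_ij > T,
  wherever they are — degree centrality on the thresholded graph.
* lFCD (local FCD) grows a spatially contiguous cluster from the seed: a
  voxel joins when it correlates with the *seed* above threshold and touches
  the growing cluster under the chosen voxel neighborhood (6/18/26-connected,
  default 26); growth stops when no adjacent supra-threshold voxel remains.
  The count is the cluster size minus one (edges convention), i.e. the
  connected component, containing the seed, of the seed's supra-threshold set.
* long-range FCD = gFCD - lFCD, the seed's connections to spatially disjoint
  regions (interregional centrality).

Counts are log-transformed (natural log; zero counts become missing by
default) into srFCD = log lFCD and lrFCD = log (gFCD - lFCD), then smoothed
with a missing-aware 8 mm FWHM Gaussian kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_volumes import BoldSeries, Mask, check_grid_compatibility
from .masks_suvr import masked_gaussian_smooth

_NEIGHBOR_OFFSETS = {
    6: np.array([d for d in np.ndindex(3, 3, 3) if sum(abs(x - 1) for x in d) == 1]) - 1,
    18: np.array([d for d in np.ndindex(3, 3, 3) if 0 < sum((x - 1) ** 2 for x in d) <= 2]) - 1,
    26: np.array([d for d in np.ndindex(3, 3, 3) if any(x != 1 for x in d)]) - 1,
}


@dataclass(frozen=True)
class FcdConfig:
    correlation_threshold: float = 0.6
    neighborhood: int = 26
    count_convention: str = "edges"  # or "cluster_size"
    zero_handling: str = "mask_missing"  # or "add_one"
    smoothing_fwhm_mm: float = 8.0

    def __post_init__(self):
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation threshold must be in (0, 1)")
        if self.neighborhood not in (6, 18, 26):
            raise ValueError("neighborhood must be one of 6, 18, 26")
        if self.count_convention not in ("edges", "cluster_size"):
            raise ValueError("count convention must be 'edges' or 'cluster_size'")
        if self.zero_handling not in ("mask_missing", "add_one"):
            raise ValueError("zero handling must be 'mask_missing' or 'add_one'")


@dataclass
class DensityMap:
    """Raw integer edge counts per in-mask voxel; NaN outside the mask."""

    grid: "VolumeGrid"
    counts: np.ndarray
    kind: str  # lfcd | gfcd | long_range

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != self.grid.shape:
            raise ValueError("count array shape must equal grid shape")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.nanmin(self.counts) < 0:
                raise ValueError("FCD counts must be nonnegative")

    @property
    def values(self) -> np.ndarray:  # uniform surface for writers / ROI means
        return self.counts

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.counts)


@dataclass
class LogFcdMap:
    grid: "VolumeGrid"
    values: np.ndarray
    kind: str  # srfcd | lrfcd | log_gfcd
    smoothed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("value array shape must equal grid shape")

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)


def pairwise_correlation(bold: BoldSeries, i: tuple[int, int, int], j: tuple[int, int, int]) -> float:
    """Pearson correlation C_ij between the series of two voxels (float64, textbook formula)."""
    x = bold.data[tuple(i)].astype(np.float64)
    y = bold.data[tuple(j)].astype(np.float64)
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError(f"zero-variance series at voxel {i if nx == 0 else j}")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _standardized_series(bold: BoldSeries, mask: Mask) -> tuple[np.ndarray, np.ndarray]:
    """Centered, unit-norm series for all mask voxels (N x T) plus mask coordinates.

    Zero-variance voxels get an all-zero row: they correlate with nothing and
    are reported via a warning (connected to nothing, as printed in the map).
    """
    coords = np.argwhere(mask.membership)
    x = bold.data[mask.membership].astype(np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    dead = norms[:, 0] == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance voxels inside the mask; "
            "treated as connected to nothing",
            stacklevel=3,
        )
        norms[dead] = 1.0
    return x / norms, coords


def _neighbor_table(coords: np.ndarray, shape, neighborhood: int) -> np.ndarray:
    """(N, k) table of mask-local neighbor indices, -1 padded."""
    offsets = _NEIGHBOR_OFFSETS[neighborhood]
    index_vol = np.full(shape, -1, dtype=np.int64)
    index_vol[tuple(coords.T)] = np.arange(len(coords))
    table = np.full((len(coords), len(offsets)), -1, dtype=np.int64)
    for k, off in enumerate(offsets):
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
        table[ok, k] = index_vol[tuple(nb[ok].T)]
    return table


def _exact_supra(r_chunk: np.ndarray, x: np.ndarray, x_chunk: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean supra-threshold matrix; borderline float32 products re-checked in float64."""
    supra = r_chunk > threshold
    near = np.abs(r_chunk - threshold) < 1e-4
    if near.any():
        rows, cols = np.nonzero(near)
        exact = np.einsum(
            "ij,ij->i", x_chunk[rows].astype(np.float64), x[cols].astype(np.float64)
        )
        supra[rows, cols] = exact > threshold
    return supra


def _fcd_counts(
    bold: BoldSeries, mask: Mask, config: FcdConfig, want_lfcd: bool, chunk: int = 256
):
    """Shared gFCD/lFCD engine: chunked correlation rows + vectorized cluster growth."""
    check_grid_compatibility([bold, mask])
    mask.require_nonempty("analysis mask")
    if bold.n_timepoints < 16:
        raise ValueError("FCD needs at least 16 timepoints")
    xs, coords = _standardized_series(bold, mask)
    n = len(coords)
    x32 = xs.astype(np.float32)
    gf = np.zeros(n, dtype=np.int64)
    lf = np.zeros(n, dtype=np.int64) if want_lfcd else None
    neighbors = _neighbor_table(coords, mask.grid.shape, config.neighborhood) if want_lfcd else None
    t = config.correlation_threshold
    visited = np.zeros(n, dtype=bool)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        r = x32[start:stop] @ x32.T
        supra = _exact_supra(r, xs, xs[start:stop], t)
        idx = np.arange(start, stop)
        supra[np.arange(stop - start), idx] = False  # no self edges
        gf[start:stop] = supra.sum(axis=1)
        if want_lfcd:
            for row, seed in enumerate(idx):
                allowed = supra[row]
                visited[:] = False
                visited[seed] = True
                frontier = np.array([seed], dtype=np.int64)
                size = 0
                while frontier.size:
                    nb = neighbors[frontier].ravel()
                    nb = nb[nb >= 0]
                    nb = nb[allowed[nb] & ~visited[nb]]
                    if nb.size == 0:
                        break
                    nb = np.unique(nb)
                    visited[nb] = True
                    size += nb.size
                    frontier = nb
                lf[seed] = size  # cluster size - 1 == voxels added beyond the seed
    return gf, (lf if want_lfcd else None), coords


def _counts_to_map(counts: np.ndarray, coords: np.ndarray, grid, kind: str,
                   convention: str) -> DensityMap:
    vol = np.full(grid.shape, np.nan)
    c = counts.astype(np.float64)
    if convention == "cluster_size":
        c = c + 1.0
    vol[tuple(coords.T)] = c
    return DensityMap(grid, vol, kind=kind)


def compute_gfcd(bold: BoldSeries, mask: Mask, config: FcdConfig = FcdConfig()) -> DensityMap:
    """Global FCD: per-voxel count of in-mask voxels with C_ij > threshold."""
    gf, _, coords = _fcd_counts(bold, mask, config, want_lfcd=False)
    return _counts_to_map(gf, coords, bold.grid, "gfcd", "edges")


def compute_lfcd(bold: BoldSeries, mask: Mask, config: FcdConfig = FcdConfig()) -> DensityMap:
    """Local FCD via cluster growing around each seed voxel."""
    _, lf, coords = _fcd_counts(bold, mask, config, want_lfcd=True)
    return _counts_to_map(lf, coords, bold.grid, "lfcd", config.count_convention)


def compute_fcd_pair(bold: BoldSeries, mask: Mask, config: FcdConfig = FcdConfig()):
    """gFCD and lFCD from one pass over the correlation rows (identical to the
    separate calls, but each correlation chunk is computed once)."""
    gf, lf, coords = _fcd_counts(bold, mask, config, want_lfcd=True)
    gmap = _counts_to_map(gf, coords, bold.grid, "gfcd", "edges")
    lmap = _counts_to_map(lf, coords, bold.grid, "lfcd", config.count_convention)
    return gmap, lmap


def long_range_map(gfcd: DensityMap, lfcd: DensityMap) -> DensityMap:
    """gFCD - lFCD: connections to spatially disjoint clusters."""
    if gfcd.kind != "gfcd" or lfcd.kind != "lfcd":
        raise ValueError("long_range_map expects a (gfcd, lfcd) pair")
    check_grid_compatibility([gfcd, lfcd])
    if not np.array_equal(gfcd.present, lfcd.present):
        raise ValueError("gFCD and lFCD maps come from different masks/runs")
    diff = gfcd.counts - lfcd.counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if np.nanmin(diff) < 0:
            raise ValueError(
                "negative gFCD - lFCD: maps are inconsistent (different runs or conventions)"
            )
    return DensityMap(gfcd.grid, diff, kind="long_range")


_LOG_KIND = {"lfcd": "srfcd", "long_range": "lrfcd", "gfcd": "log_gfcd"}


def log_fcd(dmap: DensityMap, config: FcdConfig = FcdConfig(), allow_gfcd: bool = False) -> LogFcdMap:
    """Natural log of the counts; zero counts become missing (default) or ln(1+n)."""
    if dmap.kind == "gfcd" and not allow_gfcd:
        raise ValueError(
            "only lFCD and gFCD-lFCD are log-transformed in this pipeline; "
            "pass allow_gfcd=True to log-transform gFCD explicitly"
        )
    out = np.full(dmap.counts.shape, np.nan)
    present = dmap.present
    with np.errstate(divide="ignore"):
        if config.zero_handling == "add_one":
            out[present] = np.log1p(dmap.counts[present])
        else:
            pos = present & (dmap.counts > 0)
            out[pos] = np.log(dmap.counts[pos])
    return LogFcdMap(dmap.grid, out, kind=_LOG_KIND[dmap.kind], smoothed=False)


def smooth_log_fcd(lmap: LogFcdMap, fwhm_mm: float = 8.0) -> LogFcdMap:
    """Missing-aware Gaussian smoothing (kernel renormalized over present voxels)."""
    if lmap.smoothed:
        raise ValueError("map is already smoothed")
    out = masked_gaussian_smooth(lmap.values, lmap.present, lmap.grid, fwhm_mm)
    return LogFcdMap(lmap.grid, out, kind=lmap.kind, smoothed=True)


@dataclass
class ParticipantFcd:
    srfcd: LogFcdMap
    lrfcd: LogFcdMap
    gfcd_raw: DensityMap
    lfcd_raw: DensityMap
    long_range_raw: DensityMap


def participant_fcd(bold: BoldSeries, analysis_mask: Mask, config: FcdConfig = FcdConfig()) -> ParticipantFcd:
    """Full per-participant pipeline: counts -> difference -> log -> smooth."""
    gmap, lmap = compute_fcd_pair(bold, analysis_mask, config)
    lr = long_range_map(gmap, lmap)
    srfcd = smooth_log_fcd(log_fcd(lmap, config), config.smoothing_fwhm_mm)
    lrfcd = smooth_log_fcd(log_fcd(lr, config), config.smoothing_fwhm_mm)
    return ParticipantFcd(srfcd=srfcd, lrfcd=lrfcd, gfcd_raw=gmap, lfcd_raw=lmap, long_range_raw=lr)
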