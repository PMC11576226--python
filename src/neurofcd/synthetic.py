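"""Synthetic study generator with planted hub structure and exposed ground truth.

A "study" is a toy head on an isotropic grid: a central white-matter core, a
gray-matter shell around it, and cerebrospinal fluid outside.  Hubs are
spherical blobs of gray-matter voxels that share a latent time series; voxels
in a hub are pairwise correlated at rho_w, and hubs joined by a long-range
pair additionally share a second latent giving cross-hub correlation rho_b
(the hubs in a pair are spatially disjoint, so their mutual edges are
long-range by construction).  A receptor-density (PET-like) volume is a
monotone function of each voxel's planted centrality plus Gaussian noise,
shifted so the gray-matter minimum exceeds 1 after white-matter reference
scaling.

The latent-factor construction gives exact control of the planted
correlations at any grid size: a hub voxel's series is

    sqrt(rho_b) * s_pair + sqrt(rho_w - rho_b) * u_hub + sqrt(1 - rho_w) * noise

with every component bandpass-shaped to 0.01-0.08 Hz before mixing and the
final series standardized, so the pipeline's optional bandpass is a near
no-op on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volumes import BoldSeries, Parcellation, RoiInfo, Volume3D, VolumeGrid
from .masks_suvr import bandpass_weights

NETWORK_NAMES = ("Visual", "Somatomotor", "DAN", "SN", "Limbic", "CEN", "DMN")

# ball sizes by squared radius: r2 -> voxel count of {d : |d|^2 <= r2}
_BALL_SIZES = {1: 7, 2: 19, 3: 27, 4: 33, 5: 57, 6: 81}


@dataclass(frozen=True)
class HubSpec:
    center: tuple[int, int, int]
    radius: float  # voxels; ball = offsets with squared distance <= radius**2
    within_correlation: float

    def voxels(self) -> np.ndarray:
        r = int(np.floor(self.radius))
        offs = np.array(
            [d for d in np.ndindex(2 * r + 1, 2 * r + 1, 2 * r + 1)]
        ) - r
        offs = offs[(offs**2).sum(axis=1) <= self.radius**2 + 1e-9]
        return offs + np.asarray(self.center)


@dataclass(frozen=True)
class LongRangePair:
    hub_a: int
    hub_b: int
    shared_correlation: float


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults are the desk-scale study."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    n_timepoints: int = 120
    sampling_interval_s: float = 2.5
    n_participants: int = 10
    hubs: tuple[HubSpec, ...] = ()
    long_range: tuple[LongRangePair, ...] = ()
    coupling_beta: float = 0.8
    suvr_noise_sd: float = 0.1
    bandpass_hz: tuple[float, float] = (0.01, 0.08)
    # head geometry, as fractions of the smallest grid axis
    wm_core_frac: float = 0.22
    gm_inner_frac: float = 0.25
    gm_outer_frac: float = 0.47
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if min(self.grid_shape) < 4:
            raise ValueError("grid too small")
        shape = np.asarray(self.grid_shape)
        occupied: set[tuple[int, int, int]] = set()
        for k, hub in enumerate(self.hubs):
            if not 0 <= hub.within_correlation <= 1:
                raise ValueError("within-hub correlation must be in [0, 1]")
            vox = hub.voxels()
            if np.any(vox < 0) or np.any(vox >= shape):
                raise ValueError(f"hub {k} exceeds the grid")
            cells = set(map(tuple, vox))
            if occupied & cells:
                raise ValueError(f"hub {k} overlaps another hub")
            occupied |= cells
        seen_pairs = set()
        for pair in self.long_range:
            if pair.hub_a == pair.hub_b:
                raise ValueError("a long-range pair must join two distinct hubs")
            if not 0 <= pair.shared_correlation <= 1:
                raise ValueError("shared correlation must be in [0, 1]")
            for h in (pair.hub_a, pair.hub_b):
                if not 0 <= h < len(self.hubs):
                    raise ValueError(f"long-range pair references unknown hub {h}")
                if pair.shared_correlation > self.hubs[h].within_correlation + 1e-12:
                    raise ValueError(
                        "shared correlation may not exceed the within-hub correlation "
                        "(planted local structure must dominate locally)"
                    )
                if h in seen_pairs:
                    raise ValueError(f"hub {h} appears in more than one long-range pair")
                seen_pairs.add(h)

    @property
    def grid(self) -> VolumeGrid:
        v = self.voxel_size_mm
        return VolumeGrid(self.grid_shape, (v, v, v))


@dataclass
class GroundTruth:
    """Planted per-voxel centrality, the oracle for recovery tests."""

    planted_local_degree: np.ndarray  # hub size - 1 inside a hub, 0 outside
    planted_long_degree: np.ndarray  # partner hub size for paired hubs, 0 otherwise
    beta: float
    participant_seeds: tuple[int, ...]


def _radial_distance(config: SyntheticConfig) -> np.ndarray:
    shape = np.asarray(config.grid_shape)
    center = (shape - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    return np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3 - 2 * t)


def generate_tissue_maps(config: SyntheticConfig):
    """WM core / GM shell / CSF exterior probability maps (radial profile).

    The WM core satisfies wm >= 0.95 well inside; the GM shell reaches
    gm >= 0.5; probabilities are in [0, 1] and sum to <= 1 per voxel.
    """
    s = min(config.grid_shape)
    if s < 16:
        raise ValueError("grid too small for a WM core plus GM shell (need >= 16 voxels per axis)")
    r = _radial_distance(config)
    w = 0.7  # transition width in voxels
    r_wm = config.wm_core_frac * s
    r_gm_in = config.gm_inner_frac * s
    r_gm_out = config.gm_outer_frac * s
    wm = 0.98 * _smoothstep((r_wm - r) / w + 0.5)
    gm = 0.95 * _smoothstep((r - r_gm_in) / w + 0.5) * _smoothstep((r_gm_out - r) / w + 0.5)
    csf = 0.9 * _smoothstep((r - r_gm_out) / w + 0.5)
    total = wm + gm + csf
    over = total > 1.0
    for arr in (wm, gm, csf):
        arr[over] /= total[over]
    grid = config.grid
    return Volume3D(grid, wm), Volume3D(grid, gm), Volume3D(grid, csf)


def gm_region(config: SyntheticConfig) -> np.ndarray:
    """The nominal GM shell (gm probability above one half), the analysis domain."""
    _, gm, _ = generate_tissue_maps(config)
    return gm.values > 0.5


def compute_ground_truth(config: SyntheticConfig) -> GroundTruth:
    local = np.zeros(config.grid_shape, dtype=np.int64)
    longd = np.zeros(config.grid_shape, dtype=np.int64)
    sizes = [len(h.voxels()) for h in config.hubs]
    for hub, size in zip(config.hubs, sizes):
        local[tuple(hub.voxels().T)] = size - 1
    for pair in config.long_range:
        va = config.hubs[pair.hub_a].voxels()
        vb = config.hubs[pair.hub_b].voxels()
        longd[tuple(va.T)] += sizes[pair.hub_b]
        longd[tuple(vb.T)] += sizes[pair.hub_a]
    seeds = tuple(int(s) for s in
                  np.random.SeedSequence(config.seed).generate_state(config.n_participants) >> 1)
    return GroundTruth(local, longd, beta=config.coupling_beta, participant_seeds=seeds)


def _shaped_standardized(rng: np.random.Generator, n_series: int, config: SyntheticConfig) -> np.ndarray:
    """White noise -> bandpass shaping -> zero mean, unit variance per series."""
    n = config.n_timepoints
    x = rng.standard_normal((n_series, n))
    w = bandpass_weights(n, config.sampling_interval_s, *config.bandpass_hz)
    spec = np.fft.rfft(x, axis=1)
    spec *= w[None, :]
    x = np.fft.irfft(spec, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_bold(config: SyntheticConfig, participant: int) -> BoldSeries:
    """One participant's 4D series; deterministic given (config.seed, participant)."""
    config.validate()
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 101, participant])
    n_vox = int(np.prod(config.grid_shape))
    noise = _shaped_standardized(rng, n_vox, config).reshape(config.grid_shape + (config.n_timepoints,))
    hub_latents = _shaped_standardized(rng, max(len(config.hubs), 1), config)
    pair_latents = _shaped_standardized(rng, max(len(config.long_range), 1), config)
    data = noise  # modified in place below; noise rows are unique per voxel
    pair_of_hub = {}
    for p_idx, pair in enumerate(config.long_range):
        pair_of_hub[pair.hub_a] = (p_idx, pair.shared_correlation)
        pair_of_hub[pair.hub_b] = (p_idx, pair.shared_correlation)
    for h_idx, hub in enumerate(config.hubs):
        rho_w = hub.within_correlation
        rho_b = 0.0
        series = np.zeros(config.n_timepoints)
        if h_idx in pair_of_hub:
            p_idx, rho_b = pair_of_hub[h_idx]
            series = series + np.sqrt(rho_b) * pair_latents[p_idx]
        series = series + np.sqrt(max(rho_w - rho_b, 0.0)) * hub_latents[h_idx]
        vox = hub.voxels()
        idx = tuple(vox.T)
        data[idx] = series[None, :] + np.sqrt(max(1.0 - rho_w, 0.0)) * data[idx]
    flat = data.reshape(-1, config.n_timepoints)
    flat -= flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    flat /= sd
    return BoldSeries(config.grid, data, sampling_interval_s=config.sampling_interval_s)


def generate_suvr_volume(
    truth: GroundTruth, config: SyntheticConfig, participant: int = 0,
    beta_map: np.ndarray | None = None,
) -> Volume3D:
    """PET-like volume: monotone in planted centrality plus noise, GM minimum > 1.

    The white-matter core sits near 1 (it is the reference region), so after
    SUVR division the gray-matter values keep the planted gradient and stay
    strictly above 1, and the SUVR>1 restriction removes nothing in GM.

    ``beta_map`` optionally replaces the scalar coupling with a per-voxel
    coupling strength (e.g. to plant a gradient of coupling across regions).
    """
    if truth.beta < 0:
        raise ValueError("coupling beta must be nonnegative")
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 202, participant])
    total = (truth.planted_local_degree + truth.planted_long_degree).astype(np.float64)
    dmax = total.max()
    norm = total / dmax if dmax > 0 else total
    beta = truth.beta if beta_map is None else np.asarray(beta_map, dtype=np.float64)
    values = np.full(config.grid_shape, 0.3)
    wm, gm, _ = generate_tissue_maps(config)
    wm_core = wm.values > 0.9
    gm_mask = gm.values > 0.5
    values[wm_core] = 1.0 + 0.01 * rng.standard_normal(int(wm_core.sum()))
    gm_vals = (beta * norm)[gm_mask] if beta_map is not None else beta * norm[gm_mask]
    gm_vals = gm_vals + config.suvr_noise_sd * rng.standard_normal(int(gm_mask.sum()))
    gm_vals += 1.02 - gm_vals.min()  # margin above 1 survives the WM-reference division
    values[gm_mask] = gm_vals
    return Volume3D(config.grid, values)


def generate_parcellation(config: SyntheticConfig, n_rois: int,
                          non_spinnable: tuple[int, ...] = ()) -> Parcellation:
    """Partition the GM shell into azimuthal-sector ROIs; hubs stay whole.

    Every voxel of a hub gets the label of the sector containing the hub
    center, so each hub belongs entirely to one ROI.  ROI groups cycle over
    seven canonical network names.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    region = gm_region(config)
    if n_rois > int(region.sum()):
        raise ValueError("more ROIs than gray-matter voxels")
    shape = np.asarray(config.grid_shape)
    center = (shape - 1) / 2.0
    coords = np.argwhere(region)
    rel = coords - center
    azimuth = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    sector = np.minimum((azimuth / (2 * np.pi) * n_rois).astype(np.int64), n_rois - 1)
    labels = np.zeros(config.grid_shape, dtype=np.int64)
    labels[tuple(coords.T)] = sector + 1
    for hub in config.hubs:
        c_rel = np.asarray(hub.center) - center
        az = np.mod(np.arctan2(c_rel[1], c_rel[0]), 2 * np.pi)
        lab = int(min(az / (2 * np.pi) * n_rois, n_rois - 1)) + 1
        vox = hub.voxels()
        inside = region[tuple(vox.T)]
        labels[tuple(vox[inside].T)] = lab
    table = {
        lab: RoiInfo(
            name=f"roi_{lab:02d}",
            group=NETWORK_NAMES[(lab - 1) % len(NETWORK_NAMES)],
            spinnable=lab not in non_spinnable,
        )
        for lab in range(1, n_rois + 1)
    }
    return Parcellation(config.grid, labels, table)


def generate_smooth_vertex_map(mesh, correlation_length: float, seed: int,
                               n_features: int = 800):
    """Zero-mean Gaussian random field on the sphere via random Fourier features.

    The field has (expected) squared-exponential covariance in chordal
    distance with length scale ``correlation_length`` (radians ~ chordal
    units for short distances); hemispheres are drawn independently.
    Deterministic given ``seed``.
    """
    from .spin_perm import VertexMap  # local import to avoid a cycle

    if correlation_length <= 0:
        raise ValueError("correlation length must be positive")
    values = np.empty(len(mesh.vertices))
    for h_idx, hemi in enumerate(sorted(set(mesh.hemispheres))):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 303, h_idx])
        omega = rng.standard_normal((n_features, 3)) / correlation_length
        phase = rng.uniform(0, 2 * np.pi, n_features)
        amp = rng.standard_normal(n_features)
        sel = mesh.hemispheres == hemi
        proj = mesh.vertices[sel] @ omega.T + phase[None, :]
        values[sel] = np.sqrt(2.0 / n_features) * (np.cos(proj) @ amp)
    return VertexMap(mesh=mesh, values=values)


# ---------------------------------------------------------------------------
# default desk-scale study


def _sector_hub_positions(n_sectors: int, ring_frac: float, shape) -> list[dict]:
    """Centers for two hubs per azimuthal sector (upper and lower ring)."""
    s = min(shape)
    center = (np.asarray(shape) - 1) / 2.0
    radius = ring_frac * s
    out = []
    for k in range(n_sectors):
        phi = 2 * np.pi * (k + 0.5) / n_sectors
        # stagger elevations so neighboring hubs keep their distance
        theta_small = np.deg2rad(50.0 if k % 2 == 0 else 62.0)
        theta_large = np.deg2rad(118.0 if k % 2 == 0 else 132.0)
        pos = {}
        for tag, theta in (("small", theta_small), ("large", theta_large)):
            d = np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
            pos[tag] = tuple(int(round(c)) for c in center + radius * d)
        out.append(pos)
    return out


def default_study_config(
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    n_participants: int = 10,
    n_timepoints: int = 120,
    rho_w: float = 0.9,
    rho_b: float = 0.7,
    coupling_beta: float = 0.8,
    suvr_noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticConfig:
    """The default synthetic study: ten azimuthal-sector ROIs, two hubs each.

    Each sector holds a small and a large hub; antipodal sectors (k, k+5)
    carry size-matched hubs joined by long-range pairs, so every hub has a
    spatially disjoint partner and the planted long-range degree mirrors the
    local one.  Hub-size combinations grade the sectors so ROI-mean SUVR,
    srFCD and lrFCD share a planted ranking.
    """
    s = min(grid_shape)
    if s < 20:
        raise ValueError("the default study layout needs at least 20 voxels per axis")
    # squared radii (small, large) per antipodal pair index; grids below 22
    # voxels use a reduced ladder so the large hubs still fit the GM shell
    if s >= 22:
        ladder = [(1, 3), (1, 4), (2, 4), (2, 5), (3, 5)]
        ring_frac = 0.355
    else:
        ladder = [(1, 2), (1, 3), (2, 3), (1, 2), (1, 3)]
        ring_frac = 0.365
    n_sectors = 10
    positions = _sector_hub_positions(n_sectors, ring_frac, grid_shape)
    hubs: list[HubSpec] = []
    pairs: list[LongRangePair] = []
    hub_id: dict[tuple[int, str], int] = {}
    for k in range(n_sectors):
        r2_small, r2_large = ladder[k % 5]
        for tag, r2 in (("small", r2_small), ("large", r2_large)):
            hub_id[(k, tag)] = len(hubs)
            hubs.append(
                HubSpec(center=positions[k][tag], radius=float(np.sqrt(r2)),
                        within_correlation=rho_w)
            )
    for k in range(n_sectors // 2):
        for tag in ("small", "large"):
            pairs.append(
                LongRangePair(hub_id[(k, tag)], hub_id[(k + n_sectors // 2, tag)], rho_b)
            )
    return SyntheticConfig(
        grid_shape=tuple(grid_shape),
        n_timepoints=n_timepoints,
        n_participants=n_participants,
        hubs=tuple(hubs),
        long_range=tuple(pairs),
        coupling_beta=coupling_beta,
        suvr_noise_sd=suvr_noise_sd,
        seed=seed,
    )


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    truth: GroundTruth
    wm_prob: Volume3D
    gm_prob: Volume3D
    csf_prob: Volume3D
    parcellation: Parcellation
    bold: list[BoldSeries]
    pet: list[Volume3D]


def generate_study(config: SyntheticConfig, n_rois: int = 10,
                   non_spinnable: tuple[int, ...] = ()) -> SyntheticStudy:
    """Generate the full multi-participant study (deterministic given config.seed)."""
    truth = compute_ground_truth(config)
    wm, gm, csf = generate_tissue_maps(config)
    parc = generate_parcellation(config, n_rois, non_spinnable=non_spinnable)
    bold = [generate_bold(config, p) for p in range(config.n_participants)]
    pet = [generate_suvr_volume(truth, config, participant=p) for p in range(config.n_participants)]
    return SyntheticStudy(config, truth, wm, gm, csf, parc, bold, pet)
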