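"""Spin-based spatial permutation testing on icosphere meshes.

Spatial autocorrelation makes naive permutation tests of map-to-map
correlations anti-conservative.  The spin test builds the null by rotating
one map over the sphere: rotations preserve the map's spatial covariance
while destroying its alignment with the other map.  The workflow is

1. project volumetric maps onto spherical vertex meshes (one per hemisphere,
   order-5 icospheres with 10,242 vertices each in the full-scale analysis),
   reading each vertex from the 1 mm-resampled volume;
2. draw rotations with Euler angles uniform on [0, 2pi) about x, y and z
   (the printed recipe; a Haar-uniform option exists for sensitivity checks);
3. reassign each vertex the value of the nearest original vertex to its
   rotated position (the left hemisphere uses the sagittally mirrored
   rotation so the two hemispheres spin consistently);
4. p = (number of null statistics >= observed) / n_perm, one-sided, with
   ties counting against the hypothesis.

Regions the spherical projection cannot cover (subcortex, cerebellum) are
flagged non-spinnable and skipped with an explicit "not covered" status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .io_volumes import Volume3D

_MIRROR = np.diag([-1.0, 1.0, 1.0])  # sagittal mirror (x = left-right)


@dataclass
class SphereMesh:
    """Unit-sphere vertices for both hemispheres plus their volume-space coordinates."""

    vertices: np.ndarray  # (n, 3) unit vectors
    hemispheres: np.ndarray  # (n,) 'L' or 'R'
    volume_coords_mm: np.ndarray | None = None  # (n, 3)
    subdivision_order: int | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.hemispheres = np.asarray(self.hemispheres)
        norms = np.linalg.norm(self.vertices, axis=1)
        if np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError("mesh vertices must be unit vectors (|norm - 1| <= 1e-9)")
        if self.volume_coords_mm is not None:
            self.volume_coords_mm = np.asarray(self.volume_coords_mm, dtype=np.float64)
            if self.volume_coords_mm.shape != self.vertices.shape:
                raise ValueError("volume coordinates must match the vertex array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def hemisphere_index(self, hemi: str) -> np.ndarray:
        return np.nonzero(self.hemispheres == hemi)[0]


@dataclass
class VertexMap:
    mesh: SphereMesh
    values: np.ndarray
    labels: np.ndarray | None = None  # optional per-vertex ROI label
    # provenance of a spun map: the unspun source values and the accumulated
    # rotation, so successive spins compose exactly (one resampling from the
    # source, no compounding of nearest-vertex quantization)
    spin_source: np.ndarray | None = None
    spin_rotation: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.mesh.n_vertices:
            raise ValueError("value count must equal vertex count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.mesh.n_vertices:
                raise ValueError("label count must equal vertex count")


@dataclass
class SpinResult:
    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    seed: int
    status: str = "tested"  # tested | not_covered


def icosphere_vertex_count(order: int) -> int:
    return 10 * 4**order + 2


def build_icosphere(order: int) -> SphereMesh:
    """Regular icosahedron subdivided ``order`` times, duplicated for L and R."""
    if not 0 <= order <= 7:
        raise ValueError("subdivision order must be in [0, 7]")
    import trimesh

    sphere = trimesh.creation.icosphere(subdivisions=order, radius=1.0)
    v = np.asarray(sphere.vertices, dtype=np.float64)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    vertices = np.vstack([v, v])
    hemis = np.array(["L"] * len(v) + ["R"] * len(v))
    return SphereMesh(vertices=vertices, hemispheres=hemis, subdivision_order=order)


def attach_shell_coordinates(mesh: SphereMesh, center_mm, radius_mm: float,
                             hemisphere_offset_mm: float = 0.8) -> SphereMesh:
    """Place vertex volume coordinates on a spherical shell inside a synthetic head.

    The two hemisphere spheres sit on slightly different shell radii so their
    sampled values are not duplicates of one another.
    """
    center = np.asarray(center_mm, dtype=float)
    radii = np.where(mesh.hemispheres == "L",
                     radius_mm - hemisphere_offset_mm,
                     radius_mm + hemisphere_offset_mm)
    coords = center[None, :] + mesh.vertices * radii[:, None]
    return SphereMesh(mesh.vertices.copy(), mesh.hemispheres.copy(),
                      volume_coords_mm=coords, subdivision_order=mesh.subdivision_order)


def _trilinear(values: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Missing-aware trilinear interpolation at fractional voxel coordinates.

    Weights are renormalized over the present corner voxels; a point is
    missing only when every surrounding voxel is missing.
    """
    shape = np.asarray(values.shape)
    base = np.floor(pts).astype(np.int64)
    frac = pts - base
    num = np.zeros(len(pts))
    den = np.zeros(len(pts))
    for corner in np.ndindex(2, 2, 2):
        c = np.asarray(corner)
        idx = np.clip(base + c, 0, shape - 1)
        w = np.prod(np.where(c == 1, frac, 1 - frac), axis=1)
        v = values[tuple(idx.T)]
        ok = ~np.isnan(v)
        num[ok] += (w * np.where(ok, v, 0.0))[ok]
        den[ok] += w[ok]
    out = np.full(len(pts), np.nan)
    good = den > 0
    out[good] = num[good] / den[good]
    return out


def sample_volume_at_vertices(vol: Volume3D, mesh: SphereMesh,
                              mode: str = "trilinear") -> VertexMap:
    """Read each vertex's value from the 1 mm-resampled volume.

    The volume is conceptually resampled to a 1 mm isotropic grid with
    trilinear interpolation; every vertex then takes the value of the 1 mm
    voxel whose center is nearest its mm coordinate.  (The composition is
    evaluated directly: trilinear interpolation of the source volume at the
    snapped 1 mm voxel center.)  ``mode='nearest'`` reads the nearest source
    voxel instead, for label volumes.
    """
    if mesh.volume_coords_mm is None:
        raise ValueError("mesh carries no volume-space coordinates")
    offset0 = np.asarray(vol.grid.origin_offset_mm)
    # snap to the centers of the 1 mm resampled grid (anchored at the volume origin)
    mm = offset0 + np.round(mesh.volume_coords_mm - offset0)
    voxel = np.asarray(vol.grid.voxel_size_mm)
    offset = np.asarray(vol.grid.origin_offset_mm)
    pts = (mm - offset) / voxel
    shape = np.asarray(vol.grid.shape)
    if np.any(pts < -0.5) or np.any(pts > shape - 0.5):
        raise ValueError("mesh vertex falls outside the volume bounds")
    if mode == "nearest":
        idx = np.clip(np.rint(pts).astype(np.int64), 0, shape - 1)
        vals = vol.values[tuple(idx.T)]
    else:
        vals = _trilinear(vol.values, pts)
    if np.all(np.isnan(vals)):
        raise ValueError("all sampled vertex values are missing")
    return VertexMap(mesh=mesh, values=vals)


def random_rotation(seed: int, draw: int, haar: bool = False) -> np.ndarray:
    """Rotation for permutation ``draw``: Rz(g) Ry(b) Rx(a), angles uniform on [0, 2pi).

    ``haar=True`` draws from the uniform (Haar) measure on SO(3) instead of
    the printed per-axis recipe.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 404, int(draw)])
    if haar:
        return Rotation.random(rng=rng).as_matrix()
    a, b, g = rng.uniform(0, 2 * np.pi, 3)
    return Rotation.from_euler("zyx", [g, b, a]).as_matrix()


def apply_spin(vmap: VertexMap, rotation: np.ndarray, mirror_left: bool = True,
               trees: dict | None = None) -> VertexMap:
    """Permute vertex values by rotation + nearest-vertex reassignment.

    Vertex i receives the value of the original vertex nearest to R v_i.
    The left hemisphere applies the sagittally mirrored rotation M R M when
    ``mirror_left`` (the standard construction; configurable off).

    Spinning an already-spun map composes the rotations and resamples once
    from the original source values, so a rotation followed by its inverse
    recovers the original map instead of compounding nearest-vertex
    quantization error.
    """
    mesh = vmap.mesh
    if vmap.spin_rotation is not None:
        source = vmap.spin_source
        rotation = rotation @ vmap.spin_rotation
    else:
        source = vmap.values
    out = np.empty_like(source)
    for hemi in ("L", "R"):
        sel = mesh.hemisphere_index(hemi)
        if sel.size == 0:
            continue
        r = rotation
        if hemi == "L" and mirror_left:
            r = _MIRROR @ rotation @ _MIRROR
        rotated = mesh.vertices[sel] @ r.T
        if trees is not None and hemi in trees:
            tree = trees[hemi]
        else:
            tree = cKDTree(mesh.vertices[sel])
            if trees is not None:
                trees[hemi] = tree
        _, nearest = tree.query(rotated, k=1)
        out[sel] = source[sel][nearest]
    return VertexMap(mesh=mesh, values=out, labels=vmap.labels,
                     spin_source=source.copy(), spin_rotation=rotation)


def _paired_statistic(a: np.ndarray, b: np.ndarray, statistic: str,
                      min_vertices: int = 10) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < min_vertices:
        return np.nan
    if np.all(a[ok] == a[ok][0]) or np.all(b[ok] == b[ok][0]):
        return np.nan
    from scipy import stats as sps

    if statistic == "pearson":
        return float(sps.pearsonr(a[ok], b[ok]).statistic)
    return float(sps.spearmanr(a[ok], b[ok]).statistic)


def spin_pvalue(map_a: VertexMap, map_b: VertexMap, n_perm: int = 1000, seed: int = 0,
                statistic: str = "spearman", restrict: np.ndarray | None = None,
                mirror_left: bool = True, add_one: bool = False) -> SpinResult:
    """One-sided spin permutation p-value for the correlation of two vertex maps.

    Only ``map_a`` is spun (the printed procedure spins the SUVR map); the
    statistic is evaluated on ``restrict`` (a boolean vertex subset) if
    given.  p = #(null >= observed)/n_perm, so null ties count against the
    hypothesis; ``add_one`` switches to the (k+1)/(n+1) estimator (off by
    default: the printed rule divides by exactly n_perm).  Null draws that
    are undefined on the restriction (too few paired vertices after the
    spin) also count against it.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if restrict is None:
        restrict = np.ones(map_a.mesh.n_vertices, dtype=bool)
    a = np.where(restrict, map_a.values, np.nan)
    b = np.where(restrict, map_b.values, np.nan)
    observed = _paired_statistic(a, b, statistic)
    if np.isnan(observed):
        raise ValueError("too few paired non-missing vertices for the observed statistic")
    null = np.empty(n_perm)
    trees: dict = {}
    for k in range(n_perm):
        rot = random_rotation(seed, k)
        spun = apply_spin(map_a, rot, mirror_left=mirror_left, trees=trees)
        null[k] = _paired_statistic(np.where(restrict, spun.values, np.nan), b, statistic)
    k = int((np.isnan(null) | (null >= observed)).sum())
    p = (k + 1) / (n_perm + 1) if add_one else k / n_perm
    return SpinResult(observed=observed, null=null, p=float(p), n_perm=n_perm, seed=seed)


def spin_test_roi(map_a: VertexMap, map_b: VertexMap, parc_vertices: VertexMap,
                  roi: int, n_perm: int = 1000, seed: int = 0,
                  spinnable: bool = True, force: bool = False,
                  statistic: str = "spearman") -> SpinResult:
    """Spin test restricted to the vertices of one ROI (the rotation stays global).

    Non-spinnable ROIs (regions the spherical projection does not cover) are
    returned with status ``not_covered`` unless ``force`` is set.
    """
    if not spinnable and not force:
        return SpinResult(observed=np.nan, null=np.empty(0), p=np.nan,
                          n_perm=0, seed=seed, status="not_covered")
    if parc_vertices.labels is None:
        labels = parc_vertices.values
    else:
        labels = parc_vertices.labels
    restrict = np.asarray(labels) == roi
    if restrict.sum() < 10:
        raise ValueError(f"ROI {roi}: fewer than 10 vertices on the mesh")
    return spin_pvalue(map_a, map_b, n_perm=n_perm, seed=seed,
                       statistic=statistic, restrict=restrict)
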