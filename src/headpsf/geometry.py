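"""Synthetic four-shell head geometry.

Builds every geometric input the comparative analysis needs — nested
scalp/skull/CSF/brain surfaces, a labeled voxel volume, a scalp electrode
montage and a cortex-like source space — as a stand-in for segmented-MRI
anatomy.  In the undeformed limit the head is exactly the concentric-sphere
model the analytic solver assumes, which is what makes cross-solver
validation possible.

All lengths are millimetres, conductivities S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "ShellSpec",
    "SensorArray",
    "SourceSpace",
    "LabeledVoxelGrid",
    "TISSUE_LABELS",
    "make_shell_spec",
    "make_sphere_mesh",
    "make_nested_head",
    "place_electrodes",
    "make_cortex_source_space",
    "select_probe_sources",
    "voxelize",
]

#: integer label per tissue in the voxel volume
TISSUE_LABELS = {"outside": 0, "scalp": 1, "skull": 2, "csf": 3, "brain": 4}

#: layer radius proportions outer→inner (scalp : skull : CSF : brain)
DEFAULT_RATIOS = (1.0, 0.95, 0.87, 0.84)
#: tissue conductivities outer→inner, S/m
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 1.79, 0.33)
#: adult-scale scalp radius, mm
DEFAULT_OUTER_RADIUS = 92.0


@dataclass(frozen=True)
class ShellSpec:
    """Radii (mm) and conductivities (S/m) of the four layers, outer→inner."""

    radii: tuple[float, float, float, float]
    conductivities: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        c = np.asarray(self.conductivities, dtype=float)
        if r.shape != (4,) or c.shape != (4,):
            raise ValueError("ShellSpec needs exactly 4 radii and 4 conductivities")
        if not np.all(np.diff(r) < 0):
            raise ValueError(f"radii must be strictly decreasing, got {tuple(r)}")
        if np.any(r <= 0):
            raise ValueError("radii must be positive")
        if np.any(c <= 0):
            raise ValueError(f"conductivities must be positive, got {tuple(c)}")

    @property
    def brain_radius(self) -> float:
        return self.radii[3]

    @property
    def scalp_radius(self) -> float:
        return self.radii[0]

    def rescaled(self, outer_radius: float) -> "ShellSpec":
        """Same proportions and conductivities at a different scalp radius."""
        scale = outer_radius / self.radii[0]
        return ShellSpec(tuple(r * scale for r in self.radii), self.conductivities)


def make_shell_spec(
    outer_radius: float = DEFAULT_OUTER_RADIUS,
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
    conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES,
) -> ShellSpec:
    """Shell radii from a scalp radius and strictly decreasing proportions."""
    ratios = tuple(float(x) for x in ratios)
    if len(ratios) != 4 or ratios[0] != 1.0:
        raise ValueError("ratios must be 4 values starting at 1")
    if not all(a > b for a, b in zip(ratios, ratios[1:])):
        raise ValueError(f"ratios must be strictly decreasing, got {ratios}")
    radii = tuple(outer_radius * x for x in ratios)
    return ShellSpec(radii, tuple(float(c) for c in conductivities))


def project_to_surface(
    mesh: trimesh.Trimesh, directions: np.ndarray, k_candidates: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radial (star-shaped) projection of unit directions onto a closed mesh.

    Casts a ray from the origin along each direction and intersects it with
    candidate triangles found through a KD-tree of triangle-centroid
    directions (exact Möller–Trumbore test on the candidates).  Head surfaces
    here are star-shaped about the origin, so exactly one forward hit exists.

    Returns (points_on_surface, triangle_ids, barycentric_coords).
    """
    directions = np.asarray(directions, dtype=float)
    u = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    tri = np.asarray(mesh.triangles)  # (n_tri, 3, 3)
    cent = tri.mean(axis=1)
    cent_dir = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    tree = cKDTree(cent_dir)
    k = min(k_candidates, len(tri))
    _, cand = tree.query(u, k=k)
    cand = np.atleast_2d(cand)

    v0 = tri[cand, 0]  # (n, k, 3)
    e1 = tri[cand, 1] - v0
    e2 = tri[cand, 2] - v0
    d = u[:, None, :]
    pvec = np.cross(d, e2)
    det = np.einsum("nkj,nkj->nk", e1, pvec)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(np.abs(det) > 1e-300, 1.0 / det, 0.0)
        tvec = -v0
        bu = np.einsum("nkj,nkj->nk", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        bv = np.einsum("nkj,nkj->nk", np.broadcast_to(d, e1.shape), qvec) * inv_det
        t = np.einsum("nkj,nkj->nk", e2, qvec) * inv_det
    eps = 1e-9
    hit = (bu >= -eps) & (bv >= -eps) & (bu + bv <= 1 + eps) & (t > 0)
    # pick the first (and normally only) forward hit per point
    ok = hit.any(axis=1)
    if not np.all(ok):
        # widen the candidate set once for stragglers
        if k < len(tri):
            miss = ~ok
            pts2, tid2, bar2 = project_to_surface(
                mesh, u[miss], k_candidates=min(4 * k, len(tri))
            )
            pts, tid, bar = _select_hits(u, cand, hit, t, bu, bv, mesh)
            pts[miss], tid[miss], bar[miss] = pts2, tid2, bar2
            return pts, tid, bar
        raise ValueError("radial projection failed: mesh not star-shaped?")
    return _select_hits(u, cand, hit, t, bu, bv, mesh)


def _select_hits(u, cand, hit, t, bu, bv, mesh):
    t_masked = np.where(hit, t, np.inf)
    best = np.argmin(t_masked, axis=1)
    rows = np.arange(len(u))
    tid = cand[rows, best]
    tb = t_masked[rows, best]
    tb = np.where(np.isfinite(tb), tb, np.nan)
    pts = u * tb[:, None]
    w1 = bu[rows, best]
    w2 = bv[rows, best]
    bar = np.column_stack([1.0 - w1 - w2, w1, w2])
    return pts, tid, bar


def surface_radius(mesh: trimesh.Trimesh, directions: np.ndarray) -> np.ndarray:
    """Exact radial distance from the origin to the mesh along directions."""
    pts, _, _ = project_to_surface(mesh, directions)
    return np.linalg.norm(pts, axis=1)


def fibonacci_sphere(n: int, cap_cos: float = -1.0) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the spherical cap ``cos θ ≥ cap_cos``.

    Golden-angle spiral; ``cap_cos=-1`` covers the full sphere.  Deterministic.
    """
    i = np.arange(n, dtype=float)
    # even steps in z over the cap, half-offset to avoid the poles
    z = 1.0 - (1.0 - cap_cos) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def make_sphere_mesh(radius: float, target_vertices: int = 1500) -> trimesh.Trimesh:
    """Closed outward-oriented triangle sphere with exactly ``target_vertices``.

    A Fibonacci point set is triangulated by its convex hull, so any vertex
    budget is met exactly (icosphere subdivision only allows 12, 42, 162, ...).
    """
    if target_vertices < 12:
        raise ValueError("need at least 12 vertices for a sensible sphere mesh")
    pts = fibonacci_sphere(target_vertices) * radius
    hull = ConvexHull(pts)
    mesh = trimesh.Trimesh(vertices=pts, faces=hull.simplices, process=False)
    mesh.fix_normals()  # consistent outward winding
    return mesh


def _real_sh_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Real spherical harmonics Y_lm(direction) for 1 <= l <= lmax, unit norm.

    Columns ordered (l, m) with m = -l..l.  l=0 is excluded: a monopole term
    would just rescale the radii.
    """
    from scipy.special import sph_harm_y

    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    for l in range(1, lmax + 1):
        for m in range(-l, l + 1):
            Y = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.real)
            elif m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.imag)
            else:
                cols.append(Y.real)
    return np.column_stack(cols)


def _deformation_field(coeffs: np.ndarray, lmax: int):
    """Smooth unit-amplitude radial modulation f(u) on the sphere, max|f| = 1."""
    # normalise on a dense probe grid so "amplitude" has a uniform meaning
    probe = fibonacci_sphere(2000)
    basis = _real_sh_basis(probe, lmax)
    peak = np.max(np.abs(basis @ coeffs))
    if peak == 0:
        raise ValueError("deformation coefficients are all zero")

    def f(directions: np.ndarray) -> np.ndarray:
        return (_real_sh_basis(directions, lmax) @ coeffs) / peak

    return f


def make_nested_head(
    shells: ShellSpec,
    amplitude: float | tuple[float, float, float, float] = 0.0,
    target_vertices: int = 1500,
    lmax: int = 4,
    seed: int = 0,
) -> list[trimesh.Trimesh]:
    """Four nested closed surfaces, outer→inner (scalp, skull, CSF, brain).

    ``amplitude`` is the peak relative radial deformation.  A scalar applies
    one smooth low-order spherical-harmonic field coherently to all four
    surfaces (thickness proportions preserved; nesting guaranteed); a 4-tuple
    applies per-surface amplitudes of the same field, which can break nesting
    and then raises.  ``amplitude == 0`` reproduces exact spheres.
    """
    amps = np.broadcast_to(np.asarray(amplitude, dtype=float), (4,)).copy()
    if np.any(np.abs(amps) >= 1.0):
        raise ValueError("deformation amplitude must be < 1 in magnitude")
    rng = np.random.default_rng(seed)
    n_coef = (lmax + 1) ** 2 - 1
    coeffs = rng.standard_normal(n_coef)
    f = _deformation_field(coeffs, lmax) if np.any(amps != 0) else None

    meshes = []
    for k, (R, a) in enumerate(zip(shells.radii, amps)):
        base = make_sphere_mesh(1.0, target_vertices)
        u = np.asarray(base.vertices)
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        radial = R * (1.0 + a * f(u)) if f is not None else np.full(len(u), R)
        mesh = trimesh.Trimesh(vertices=u * radial[:, None], faces=base.faces, process=False)
        mesh.fix_normals()
        meshes.append(mesh)

    _check_nesting(meshes, shells, amps, f)
    return meshes


def _check_nesting(meshes, shells, amps, f) -> None:
    """Radial nesting check: surfaces are star-shaped, so compare the radial
    functions of consecutive surfaces along the inner surface's directions."""
    names = ["scalp", "skull", "CSF", "brain"]
    for k in range(3):
        inner = np.asarray(meshes[k + 1].vertices)
        u = inner / np.linalg.norm(inner, axis=1, keepdims=True)
        r_inner = np.linalg.norm(inner, axis=1)
        if f is not None:
            r_outer = shells.radii[k] * (1.0 + amps[k] * f(u))
        else:
            r_outer = np.full(len(u), shells.radii[k])
        if np.any(r_inner >= r_outer):
            raise ValueError(
                f"surfaces intersect after deformation: {names[k + 1]} "
                f"crosses {names[k]}"
            )


@dataclass(frozen=True)
class SensorArray:
    """Electrode positions (mm) lying on the scalp surface."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d == 0):
            raise ValueError("electrode positions must be pairwise distinct")
        object.__setattr__(self, "positions", p)

    def __len__(self) -> int:
        return len(self.positions)


def place_electrodes(
    scalp: trimesh.Trimesh, n: int = 62, cap_degrees: float = 130.0
) -> SensorArray:
    """``n`` quasi-evenly spaced electrodes on the scalp.

    A golden-angle spiral on the upper polar cap (default upper 130° of polar
    angle, i.e. no electrodes below the "neck") projected onto the mesh.
    Deterministic.
    """
    if n < 4:
        raise ValueError("need at least 4 electrodes")
    cap_cos = float(np.cos(np.radians(cap_degrees)))
    u = fibonacci_sphere(n, cap_cos=cap_cos)
    pts, _, _ = project_to_surface(scalp, u)
    return SensorArray(pts)


@dataclass(frozen=True)
class SourceSpace:
    """Candidate dipole positions on a cortex-like surface.

    Orientations are the three Cartesian unit vectors; ``probe_indices`` are
    the subset treated as "true" sources in the comparison.
    """

    positions: np.ndarray
    probe_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    #: dipole orientations used throughout the analysis
    orientations: tuple[str, ...] = ("x", "y", "z")

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        idx = np.asarray(self.probe_indices, dtype=int)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("positions must be (m, 3)")
        if idx.size and (idx.min() < 0 or idx.max() >= len(p) or len(set(idx.tolist())) != idx.size):
            raise ValueError("probe_indices must be distinct and in range")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "probe_indices", idx)

    def __len__(self) -> int:
        return len(self.positions)


def make_cortex_source_space(
    brain: trimesh.Trimesh,
    m: int = 5000,
    depth: float = 0.08,
    wrinkle: float = 0.0,
    wrinkle_lmax: int = 12,
    seed: int = 0,
) -> SourceSpace:
    """``m`` evenly spaced source points strictly inside the brain surface.

    Points follow the brain surface shrunk radially by ``depth`` (fraction of
    the local radius); ``wrinkle`` adds a smooth high-order radial modulation
    mimicking gyral/sulcal depth variation.  Deterministic given ``seed``.
    """
    u = fibonacci_sphere(m)
    # local brain radius: barycentric interpolation of vertex radii (smooth
    # in the facet, exact for a spherical surface)
    _, tri_id, bary = project_to_surface(brain, u)
    vert_r = np.linalg.norm(np.asarray(brain.vertices), axis=1)
    r_surf = np.einsum("nk,nk->n", bary, vert_r[np.asarray(brain.faces)[tri_id]])
    r = r_surf * (1.0 - depth)
    if wrinkle:
        rng = np.random.default_rng(seed)
        n_coef = (wrinkle_lmax + 1) ** 2 - 1
        g = _deformation_field(rng.standard_normal(n_coef), wrinkle_lmax)
        r = r * (1.0 - wrinkle * (0.5 + 0.5 * g(u)))
    if np.any(r >= r_surf):
        raise ValueError("source points must stay inside the brain surface")
    return SourceSpace(u * r[:, None])


def select_probe_sources(space: SourceSpace, p: int = 26, seed: int = 0) -> np.ndarray:
    """``p`` probe indices by farthest-point sampling (uniform spatial coverage).

    Starts from the point closest to the +z pole for determinism, then greedily
    adds the point farthest from the chosen set.
    """
    m = len(space)
    if p > m:
        raise ValueError(f"cannot select {p} probes from {m} sources")
    pos = space.positions
    if p == m:
        return np.arange(m)
    start = int(np.argmax(pos[:, 2]))
    chosen = [start]
    dmin = np.linalg.norm(pos - pos[start], axis=1)
    for _ in range(p - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(pos - pos[nxt], axis=1))
    return np.asarray(chosen, dtype=int)


@dataclass(frozen=True)
class LabeledVoxelGrid:
    """Regular voxel grid with an integer tissue label per voxel.

    ``labels`` is (nx, ny, nz) with codes from :data:`TISSUE_LABELS`;
    ``conductivity`` maps labels to S/m via the shell spec.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray
    shells: ShellSpec

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def conductivity(self) -> np.ndarray:
        """Per-voxel conductivity (S/m); 0 outside the head."""
        lut = np.zeros(5)
        lut[1:] = self.shells.conductivities  # scalp, skull, CSF, brain
        return lut[self.labels]

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) world coordinates of voxel centers, C-order."""
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()])
        return self.origin + (idx + 0.5) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each point (no bounds clipping)."""
        return np.floor((np.asarray(points) - self.origin) / self.spacing).astype(int)


def voxelize(
    meshes: list[trimesh.Trimesh], shells: ShellSpec, spacing: float = 2.0
) -> LabeledVoxelGrid:
    """Label a regular grid by the innermost surface containing each voxel center.

    Surfaces are star-shaped here, so containment reduces to comparing each
    center's radius with the surface's radial function along that direction —
    exact and fast compared with general point-in-mesh queries.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    R = shells.scalp_radius
    half = R * 1.02  # small air margin
    n = int(np.ceil(2 * half / spacing))
    origin = np.full(3, -n * spacing / 2.0)
    nx = ny = nz = n
    centers_axis = origin[0] + (np.arange(n) + 0.5) * spacing
    X, Y, Z = np.meshgrid(centers_axis, centers_axis, centers_axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.linalg.norm(pts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(r[:, None] > 0, pts / np.maximum(r, 1e-300)[:, None], [0.0, 0.0, 1.0])

    labels = np.zeros(len(pts), dtype=np.int8)
    # radial surface functions sampled on a KD-tree of mesh vertex directions:
    # nearest vertex direction gives the local radius (meshes are dense)
    for label, mesh in zip((1, 2, 3, 4), meshes):
        v = np.asarray(mesh.vertices)
        rv = np.linalg.norm(v, axis=1)
        uv = v / rv[:, None]
        tree = cKDTree(uv)
        _, nn = tree.query(u, k=1)
        inside = r <= rv[nn]
        labels[inside] = label
    grid = LabeledVoxelGrid(labels.reshape(nx, ny, nz), float(spacing), origin, shells)
    return grid
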