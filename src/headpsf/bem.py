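"""Surface boundary-element EEG forward solver on four nested surfaces.

Linear (vertex) collocation on closed triangle meshes with analytically
integrated solid-angle weights, deflation of the undetermined potential
constant, and the isolated problem approach (IPA) for the poorly conducting
skull.  The double-layer potential formulation is

    (s_in + s_out)/2 V(r) = s_src V_inf(r)
        + 1/(4 pi) sum_k (s_in_k - s_out_k) int_{S_k} V(r') dOmega_r(r')

discretised with piecewise-linear potential on each surface; the weights
int_T lambda_i dOmega of a linear shape function over a flat triangle have a
closed form (the classic analytically-integrated-element result), so no
numerical quadrature is involved.

Surfaces are ordered outer→inner: scalp, skull, CSF, brain.  Conductivities
come from the shell spec in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .geometry import SensorArray, ShellSpec, SourceSpace
from .sphere import Dipole

__all__ = [
    "BemSystem",
    "assemble_bem",
    "bem_potential",
    "bem_leadfield",
    "double_layer_operator",
    "linear_collocation_weights",
]

#: apply IPA when sigma_out/sigma_in at the isolation surface is below this
IPA_CONTRAST_LIMIT = 0.1


def linear_collocation_weights(
    obs: np.ndarray,
    tri_pts: np.ndarray,
    tri_nn: np.ndarray,
) -> np.ndarray:
    """Analytic weights ``int_T lambda_k dOmega`` for linear collocation.

    Parameters
    ----------
    obs : (n_obs, 3) observation points.
    tri_pts : (n_tri, 3, 3) triangle vertex coordinates.
    tri_nn : (n_tri, 3) unit triangle normals.

    Returns
    -------
    (n_obs, n_tri, 3) weights, one per triangle vertex (shape function).
    """
    # vertex vectors relative to each observation point: (n_obs, n_tri, 3, 3)
    y = tri_pts[None, :, :, :] - obs[:, None, None, :]
    y1, y2, y3 = y[:, :, 0], y[:, :, 1], y[:, :, 2]
    l1 = np.linalg.norm(y1, axis=-1)
    l2 = np.linalg.norm(y2, axis=-1)
    l3 = np.linalg.norm(y3, axis=-1)
    triple = np.einsum("otj,otj->ot", y1, np.cross(y2, y3))
    ss = (
        l1 * l2 * l3
        + np.einsum("otj,otj->ot", y1, y2) * l3
        + np.einsum("otj,otj->ot", y1, y3) * l2
        + np.einsum("otj,otj->ot", y2, y3) * l1
    )
    solid = 2.0 * np.arctan2(triple, ss)  # signed solid angle of the triangle

    # points (numerically) in the triangle plane: weights vanish
    bad = np.abs(solid) < 1e-12

    def edge_beta(a, la, b, lb):
        e = b - a
        le = np.linalg.norm(e, axis=-1)
        le = np.where(le == 0, 1.0, le)
        u = e / le[..., None]
        num = la + np.einsum("otj,otj->ot", a, u)
        den = lb + np.einsum("otj,otj->ot", b, u)
        num = np.where(bad | (num <= 0), 1.0, num)
        den = np.where(bad | (den <= 0), 1.0, den)
        return np.log(num / den) / le

    b12 = edge_beta(y1, l1, y2, l2)
    b23 = edge_beta(y2, l2, y3, l3)
    b31 = edge_beta(y3, l3, y1, l1)
    vec_omega = (
        (b31 - b12)[..., None] * y1
        + (b12 - b23)[..., None] * y2
        + (b23 - b31)[..., None] * y3
    )

    # 2*area from the triangle itself (independent of obs)
    n_scaled = np.cross(tri_pts[:, 1] - tri_pts[:, 0], tri_pts[:, 2] - tri_pts[:, 0])
    area2 = np.linalg.norm(n_scaled, axis=-1)  # (n_tri,)
    inv_a2 = 1.0 / (area2 * area2)

    w = np.empty(obs.shape[:1] + tri_pts.shape[:1] + (3,))
    ys = (y1, y2, y3)
    for k in range(3):
        y_next, y_prev = ys[(k + 1) % 3], ys[(k + 2) % 3]
        zdot = np.einsum("otj,tj->ot", np.cross(y_next, y_prev), tri_nn)
        diff = y_prev - y_next
        w[:, :, k] = -inv_a2[None, :] * (
            area2[None, :] * zdot * solid
            - triple * np.einsum("otj,otj->ot", diff, vec_omega)
        )
    w[bad] = 0.0
    return w


def _surface_block(
    obs: np.ndarray,
    mesh: trimesh.Trimesh,
    obs_vertex_offset: int | None,
    chunk: int = 64,
) -> np.ndarray:
    """(n_obs, n_verts) solid-angle weight matrix of one source surface.

    Sign convention: the returned block is the *negated* sum of the analytic
    weights, so that each row of a same-surface block sums to +2 pi for a
    closed outward-oriented surface (the on-surface solid-angle identity used
    by the auto-element correction).

    ``obs_vertex_offset`` is the index of the first observation row that is a
    vertex of ``mesh`` itself (or None): own-triangle contributions of an
    on-surface collocation point are skipped (they vanish in the plane; the
    non-planar remainder is restored by the auto-element correction).
    """
    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)
    nn = np.asarray(mesh.face_normals)
    out = np.zeros((len(obs), len(verts)))
    for lo in range(0, len(faces), chunk):
        f = faces[lo : lo + chunk]
        w = linear_collocation_weights(obs, verts[f], nn[lo : lo + chunk])
        if obs_vertex_offset is not None:
            rows = np.arange(len(obs)) - obs_vertex_offset
            for c in range(3):
                hit = rows[:, None] == f[None, :, c]  # obs row is a tri vertex
                w[hit] = 0.0
        for c in range(3):
            np.subtract.at(out, (slice(None), f[:, c]), w[:, :, c])
    return out


def _auto_element_correction(mesh: trimesh.Trimesh, block: np.ndarray) -> None:
    """Fix diagonal (auto) elements so each on-surface row integrates to 2*pi.

    The analytic weights of the triangles meeting the collocation vertex are
    zero/skipped; the missing solid angle is assigned half to the vertex and
    the rest evenly to its neighbours in the member triangles.
    """
    faces = np.asarray(mesh.faces)
    miss = 2.0 * np.pi - block.sum(axis=1)
    vf = mesh.vertex_faces  # (n_verts, max_deg) padded with -1
    for j in range(len(block)):
        memb = vf[j][vf[j] >= 0]
        block[j, j] += miss[j] / 2.0
        share = miss[j] / (4.0 * len(memb))
        for t in memb:
            for v in faces[t]:
                if v != j:
                    block[j, v] += share
    return


def double_layer_operator(
    surfaces: list[trimesh.Trimesh], shells: ShellSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the gamma-weighted double-layer matrix M and vertex offsets.

    The discrete equation is ``V = M V + c`` with
    ``M[i, j] = gamma(surf_i, surf_j) * W[i, j] / (2 pi)`` and ``c`` the scaled
    infinite-medium potential; ``(I - M)`` is singular (constant vectors) until
    deflated.  Returns (M, offsets).
    """
    _check_surfaces(surfaces)
    sigma_in = np.asarray(shells.conductivities)
    sigma_out = np.r_[0.0, sigma_in[:-1]]
    gamma = (sigma_in - sigma_out)[None, :] / (sigma_in + sigma_out)[:, None]

    nps = [len(s.vertices) for s in surfaces]
    offsets = np.concatenate([[0], np.cumsum(nps)])
    obs_all = np.concatenate([np.asarray(s.vertices) for s in surfaces])
    n_tot = offsets[-1]
    M = np.empty((n_tot, n_tot))
    for sj, mesh in enumerate(surfaces):
        col = slice(offsets[sj], offsets[sj + 1])
        block = _surface_block(obs_all, mesh, obs_vertex_offset=offsets[sj])
        # own-surface sub-block rows get the auto-element correction
        own = block[offsets[sj] : offsets[sj + 1]]
        _auto_element_correction(mesh, own)
        for si in range(len(surfaces)):
            row = slice(offsets[si], offsets[si + 1])
            M[row, col] = (gamma[si, sj] / (2.0 * np.pi)) * block[row]
    return M, offsets


def _check_surfaces(surfaces) -> None:
    if len(surfaces) != 4:
        raise ValueError("expected 4 surfaces (scalp, skull, CSF, brain)")
    for i, s in enumerate(surfaces):
        if not s.is_watertight:
            raise ValueError(f"surface {i} is not closed")
        if s.volume < 0:
            raise ValueError(f"surface {i} has inward orientation")


@dataclass
class BemSystem:
    """Assembled and inverted BEM operator plus geometry bookkeeping."""

    surfaces: list
    shells: ShellSpec
    solution: np.ndarray  # (n_tot, n_tot) inverted (deflated, IPA-modified)
    offsets: np.ndarray
    use_ipa: bool

    @property
    def n_total(self) -> int:
        return int(self.offsets[-1])

    @property
    def source_mult(self) -> np.ndarray:
        """Per-vertex source scaling 2 / (sigma_in + sigma_out) / (4 pi)."""
        sigma_in = np.asarray(self.shells.conductivities)
        sigma_out = np.r_[0.0, sigma_in[:-1]]
        per_surf = 2.0 / (sigma_in + sigma_out) / (4.0 * np.pi)
        nps = np.diff(self.offsets)
        return np.repeat(per_surf, nps)


def _multi_solution(M: np.ndarray) -> np.ndarray:
    """Invert (I - M) with rank-one deflation of the constant nullspace."""
    n = len(M)
    return np.linalg.inv(np.eye(n) - M + 1.0 / n)


def assemble_bem(
    surfaces: list[trimesh.Trimesh],
    shells: ShellSpec,
    use_ipa: bool = True,
) -> BemSystem:
    """Assemble, deflate, invert and (optionally) IPA-modify the BEM operator.

    The isolation surface for the IPA is the skull's inner boundary (the
    skull/CSF interface): the isolated sub-problem contains the CSF and brain
    surfaces with an insulating boundary, and the combined solution follows
    the standard isolated-problem algebra with
    ``ip_mult = sigma_skull / sigma_CSF``.
    """
    M, offsets = double_layer_operator(surfaces, shells)
    solution = _multi_solution(M)
    sigma = np.asarray(shells.conductivities)
    ip_mult = sigma[1] / sigma[2]  # skull / CSF
    if use_ipa and ip_mult < IPA_CONTRAST_LIMIT:
        solution = _ipa_solution(M, solution, surfaces, shells, offsets)
    return BemSystem(list(surfaces), shells, solution, offsets, bool(use_ipa))


def _ipa_solution(M, A, surfaces, shells: ShellSpec, offsets) -> np.ndarray:
    """Exact isolated-problem reformulation of the solution operator.

    Decompose V = V1 + chi V0: V0 solves the sub-problem on the surfaces
    inside the skull's inner boundary (CSF interface + brain surface) with an
    insulating boundary there; V1 solves the original system driven by a
    residual source proportional to sigma_skull carrying V0 on the isolation
    surface (the primary source and the double layer of V0 cancel exactly on
    the outer surfaces in the continuum, and the cancelled form is used).
    The correction problem's data are O(sigma_skull), so the discretisation
    error of the large interior potentials no longer leaks into the
    skull-attenuated scalp potentials — the classical isolated-problem
    accuracy gain, generalised here to the two-surface isolated region
    (CSF + brain) of the four-shell model.
    """
    sigma = np.asarray(shells.conductivities)
    s_csf, s_skull = sigma[2], sigma[1]
    tau_K = s_csf + s_skull  # row normalisation of the isolation surface
    n = offsets[-1]
    iK = slice(offsets[2], offsets[3])  # skull/CSF interface block
    iI = slice(offsets[2], offsets[4])  # CSF + brain blocks
    n_I = offsets[4] - offsets[2]
    n_K = offsets[3] - offsets[2]

    J = _isolated_solution(surfaces[2:], shells)
    # isolated source = g scaled by tau/tau0 on the isolation surface
    scale = np.ones(n_I)
    scale[:n_K] = tau_K / s_csf
    JD = J * scale[None, :]  # V0 = JD @ g[I]

    # residual source (all rows):
    #   ghat = -s_skull [ M[:, K]/(s_csf - s_skull) + delta_K/tau_K ] V0_K
    X_I = (-s_skull / (s_csf - s_skull)) * (M[:, iK] @ JD[:n_K])
    X_I[iK] += -s_skull / tau_K * JD[:n_K]

    S = np.zeros((n, n))
    S[iI, iI] = JD  # chi V0
    S[:, iI] += A @ X_I
    return S


def _isolated_solution(inner_surfaces, shells: ShellSpec) -> np.ndarray:
    """Solution operator of the isolated sub-problem (insulated at the
    skull/CSF interface): surfaces [CSF, brain], conductivities (CSF, brain),
    zero outside."""
    sigma_in = np.asarray(shells.conductivities[2:])
    sigma_out = np.r_[0.0, sigma_in[:-1]]
    gamma = (sigma_in - sigma_out)[None, :] / (sigma_in + sigma_out)[:, None]
    nps = [len(s.vertices) for s in inner_surfaces]
    offsets = np.concatenate([[0], np.cumsum(nps)])
    obs_all = np.concatenate([np.asarray(s.vertices) for s in inner_surfaces])
    M = np.empty((offsets[-1], offsets[-1]))
    for sj, mesh in enumerate(inner_surfaces):
        col = slice(offsets[sj], offsets[sj + 1])
        block = _surface_block(obs_all, mesh, obs_vertex_offset=offsets[sj])
        _auto_element_correction(mesh, block[offsets[sj] : offsets[sj + 1]])
        for si in range(len(inner_surfaces)):
            row = slice(offsets[si], offsets[si + 1])
            M[row, col] = (gamma[si, sj] / (2.0 * np.pi)) * block[row]
    return _multi_solution(M)


def infinite_potential(
    positions: np.ndarray, moments: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """sigma-free infinite-medium dipole potential q.(r-r0)/|r-r0|^3.

    Returns (n_dipoles, n_points).
    """
    d = points[None, :, :] - np.atleast_2d(positions)[:, None, :]
    dist3 = np.linalg.norm(d, axis=-1) ** 3
    return np.einsum("dpj,dj->dp", d, np.atleast_2d(moments)) / dist3


def _vertex_potentials(system: BemSystem, dipoles_pos, dipoles_mom) -> np.ndarray:
    obs = np.concatenate([np.asarray(s.vertices) for s in system.surfaces])
    v0 = infinite_potential(dipoles_pos, dipoles_mom, obs)
    return (v0 * system.source_mult[None, :]) @ system.solution.T


def electrode_interpolator(system: BemSystem, electrodes: SensorArray) -> np.ndarray:
    """(n_electrodes, n_total) barycentric interpolation weights of
    scalp-vertex potentials at the electrode positions (radial projection
    onto the scalp mesh)."""
    from .geometry import project_to_surface

    scalp = system.surfaces[0]
    _, tri_id, bary = project_to_surface(scalp, electrodes.positions)
    faces = np.asarray(scalp.faces)[tri_id]
    W = np.zeros((len(electrodes), system.n_total))
    for e in range(len(electrodes)):
        W[e, faces[e]] = bary[e]
    return W


def bem_potential(
    system: BemSystem, dipole: Dipole, electrodes: SensorArray
) -> np.ndarray:
    """Average-referenced electrode potentials of one dipole."""
    from .geometry import surface_radius

    brain = system.surfaces[3]
    r = np.linalg.norm(dipole.position)
    if r > 0 and r >= surface_radius(brain, dipole.position[None])[0]:
        raise ValueError(f"dipole at radius {r:.1f} mm is outside the brain surface")
    V = _vertex_potentials(system, dipole.position[None], dipole.moment[None])[0]
    W = electrode_interpolator(system, electrodes)
    v = W @ V
    return v - v.mean()


def bem_leadfield(
    system: BemSystem,
    electrodes: SensorArray,
    sources: SourceSpace,
    orientation: str,
) -> np.ndarray:
    """(n_electrodes, n_sources) lead field for one Cartesian orientation.

    Uses the transfer-matrix factorisation: the electrode-to-solution rows are
    formed once and applied to every source's infinite-medium potential.
    """
    ori = {"x": 0, "y": 1, "z": 2}[orientation]
    moment = np.zeros(3)
    moment[ori] = 1.0
    W = electrode_interpolator(system, electrodes)
    T = W @ system.solution  # (n_el, n_tot)
    obs = np.concatenate([np.asarray(s.vertices) for s in system.surfaces])
    L = np.empty((len(electrodes), len(sources)))
    mults = system.source_mult
    chunk = 256
    pos = sources.positions
    for lo in range(0, len(pos), chunk):
        v0 = infinite_potential(
            pos[lo : lo + chunk], np.broadcast_to(moment, (min(chunk, len(pos) - lo), 3)), obs
        )
        L[:, lo : lo + chunk] = T @ (v0 * mults[None, :]).T
    L -= L.mean(axis=0, keepdims=True)
    return L
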