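"""Analytic EEG forward solution in a four-layer concentric sphere.

The potential of a current dipole inside nested homogeneous spherical shells
is the classical Legendre series

    V(r_e) = 1/(4 pi s1 R^2) * sum_n T_n (b/R)^(n-1)
             [ n m_r P_n(cos g) + m_t sin(g) P_n'(cos g) ]

with b the dipole radius, R the outer (scalp) radius, g the angle between
dipole and electrode, m_r / m_t the radial and tangential moment components
and s1 the innermost (brain) conductivity.  T_n carries the effect of the
layers; for a homogeneous sphere T_n = (2n+1)/n.  T_n is obtained here by
solving, per harmonic degree, the small linear system expressing potential
and current continuity at the three interfaces plus the insulating outer
boundary — valid for any number of layers and free of closed-form special
cases.

The "sensor-fitted sphere" scheme refits the multilayer sphere to the local
scalp under each individual sensor, then evaluates the series in that
sensor's sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .geometry import SensorArray, ShellSpec, SourceSpace

__all__ = [
    "Dipole",
    "FittedSphere",
    "layer_transfer_coefficients",
    "sphere_potential",
    "fit_sensor_sphere",
    "sensor_fitted_leadfield",
]

DEFAULT_N_TERMS = 200


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (mm) and moment vector (consistent units)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))


@dataclass(frozen=True)
class FittedSphere:
    """Multilayer sphere fitted to the scalp under one sensor."""

    center: np.ndarray
    radii: tuple[float, float, float, float]
    degenerate: bool = False  # patch was near-planar; global fallback used


def layer_transfer_coefficients(shells: ShellSpec, n_terms: int) -> np.ndarray:
    """T_n for n = 1..n_terms (index 0 is n=1).

    Radii are normalised by the outer radius.  For each degree n the unknowns
    are the regular coefficient of the innermost layer and the (regular,
    singular) pair of each outer layer; the unit source is the dipole's
    singular term in the innermost layer.  T_n is the resulting potential
    coefficient evaluated on the outer surface.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    R = np.asarray(shells.radii, dtype=float) / shells.radii[0]
    sig = np.asarray(shells.conductivities, dtype=float)
    rho = R[::-1][:-1]  # interface radii inner→outer: brain, CSF, skull surfaces
    sl = sig[::-1]  # layer conductivities inner→outer
    # layer j occupies (a_j, b_j); per-layer basis (r/b_j)^n and (a_j/r)^(n+1)
    # keeps every matrix entry O(1) at any n (the naive r^±n parameterisation
    # loses ~2n log10(1/rho) digits and corrupts high-contrast models)
    a = np.array([0.0, rho[0], rho[1], rho[2]])
    bnd = np.array([rho[0], rho[1], rho[2], 1.0])
    out = np.empty(n_terms)
    cols_A = [0, 1, 3, 5]
    cols_B = [None, 2, 4, 6]
    for i, n in enumerate(range(1, n_terms + 1)):
        A = np.zeros((7, 7))
        rhs = np.zeros(7)
        for j in range(3):  # interface between layer j and j+1, at r = bnd[j]
            r = bnd[j]
            inner_ratio = (a[j] / r) ** (n + 1) if a[j] > 0 else 0.0
            outer_ratio = (r / bnd[j + 1]) ** n
            row = 2 * j
            # potential continuity (basis values at the interface)
            A[row, cols_A[j]] = 1.0
            if cols_B[j] is not None:
                A[row, cols_B[j]] = inner_ratio
            A[row, cols_A[j + 1]] = -outer_ratio
            A[row, cols_B[j + 1]] = -1.0
            # radial current continuity (times r, keeping entries O(1))
            A[row + 1, cols_A[j]] = sl[j] * n
            if cols_B[j] is not None:
                A[row + 1, cols_B[j]] = -sl[j] * (n + 1) * inner_ratio
            A[row + 1, cols_A[j + 1]] = -sl[j + 1] * n * outer_ratio
            A[row + 1, cols_B[j + 1]] = sl[j + 1] * (n + 1)
            if j == 0:
                # dipole's singular term, rescaled by rho1^(n+1) (undone below)
                rhs[row] = -1.0
                rhs[row + 1] = sl[0] * (n + 1)
        # insulating outer boundary at r = 1 (layer 4: b = 1, a = rho[2])
        A[6, cols_A[3]] = n
        A[6, cols_B[3]] = -(n + 1) * rho[2] ** (n + 1)
        x = np.linalg.solve(A, rhs)
        # potential at r = 1, undoing the source rescale
        out[i] = (x[5] + x[6] * rho[2] ** (n + 1)) * rho[0] ** -(n + 1)
    return out


def _series_potentials(
    shells: ShellSpec,
    center: np.ndarray,
    electrodes: np.ndarray,
    positions: np.ndarray,
    moments: np.ndarray,
    n_terms: int,
    transfer: np.ndarray | None = None,
    max_eccentricity: float = 0.98,
) -> tuple[np.ndarray, int]:
    """Series evaluation for many dipoles and electrodes in one sphere.

    Returns (n_dipoles, n_electrodes) potentials (not referenced) and the
    number of dipoles whose eccentricity had to be clipped.
    """
    if transfer is None:
        transfer = layer_transfer_coefficients(shells, n_terms)
    R = shells.scalp_radius
    r_brain = shells.brain_radius
    pos = np.atleast_2d(positions) - center
    mom = np.atleast_2d(moments)
    el = np.atleast_2d(electrodes) - center

    b = np.linalg.norm(pos, axis=1)
    clipped = int(np.sum(b > max_eccentricity * r_brain))
    b = np.minimum(b, max_eccentricity * r_brain)
    # source direction; arbitrary for a central dipole (only n=1 survives)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(b[:, None] > 1e-12, pos / np.maximum(b, 1e-300)[:, None], [0.0, 0.0, 1.0])
    ehat = el / np.linalg.norm(el, axis=1, keepdims=True)

    cosg = np.clip(rhat @ ehat.T, -1.0, 1.0)  # (nd, ne)
    # tangential unit vector at the source pointing toward each electrode
    t = ehat[None, :, :] - cosg[:, :, None] * rhat[:, None, :]
    sing = np.linalg.norm(t, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        that = np.where(sing[:, :, None] > 1e-12, t / np.maximum(sing, 1e-300)[:, :, None], 0.0)

    m_r = np.einsum("ij,ij->i", mom, rhat)  # radial moment
    m_t = np.einsum("ik,ijk->ij", mom, that)  # tangential toward electrode

    beta = b / R
    V = np.zeros_like(cosg)
    # upward Legendre recurrences: P = P_n, Pm = P_{n-1}, dP = P_n', dPm = P_{n-1}'
    Pm = np.ones_like(cosg)  # P_0
    P = cosg.copy()  # P_1
    dPm = np.zeros_like(cosg)  # P_0'
    dP = np.ones_like(cosg)  # P_1'
    beta_pow = np.ones_like(b)  # beta^(n-1)
    for i, n in enumerate(range(1, n_terms + 1)):
        term = n * m_r[:, None] * P + m_t * sing * dP
        V += transfer[i] * beta_pow[:, None] * term
        # advance n -> n+1
        P_next = ((2 * n + 1) * cosg * P - n * Pm) / (n + 1)
        dP_next = ((2 * n + 1) * (P + cosg * dP) - n * dPm) / (n + 1)
        Pm, P, dPm, dP = P, P_next, dP, dP_next
        beta_pow = beta_pow * beta
    V /= 4.0 * np.pi * shells.conductivities[3] * R**2
    return V, clipped


def sphere_potential(
    dipole: Dipole,
    shells: ShellSpec,
    electrodes: SensorArray | np.ndarray,
    n_terms: int = DEFAULT_N_TERMS,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Average-referenced potentials of one dipole at the given electrodes."""
    el = electrodes.positions if isinstance(electrodes, SensorArray) else np.asarray(electrodes)
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    b = np.linalg.norm(dipole.position - center)
    if b >= shells.brain_radius:
        raise ValueError(
            f"dipole radius {b:.2f} mm is not inside the brain shell "
            f"({shells.brain_radius:.2f} mm)"
        )
    V, _ = _series_potentials(
        shells, center, el, dipole.position[None], dipole.moment[None], n_terms
    )
    v = V[0]
    return v - v.mean()


def fit_sensor_sphere(
    scalp: trimesh.Trimesh,
    sensor: np.ndarray,
    shells: ShellSpec,
    patch_radius: float = 40.0,
) -> FittedSphere:
    """Least-squares sphere to the scalp patch under one sensor.

    The patch is the set of scalp vertices within ``patch_radius`` (Euclidean,
    a proxy for geodesic distance at this scale) of the sensor.  The fitted
    outer radius is reset to the sensor–center distance so the sensor lies
    exactly on the outer surface; inner radii follow the shell proportions.
    A near-planar patch falls back to the global best-fit sphere, flagged.
    """
    sensor = np.asarray(sensor, dtype=float)
    verts = np.asarray(scalp.vertices)
    patch = verts[np.linalg.norm(verts - sensor, axis=1) <= patch_radius]
    if len(patch) < 10:
        raise ValueError(
            f"scalp patch under sensor has only {len(patch)} vertices (< 10)"
        )
    center, ok = _lsq_sphere_center(patch)
    degenerate = not ok
    if degenerate:
        center, _ = _lsq_sphere_center(verts)
    outer = float(np.linalg.norm(sensor - center))
    ratios = np.asarray(shells.radii) / shells.radii[0]
    return FittedSphere(center, tuple(outer * ratios), degenerate)


def _lsq_sphere_center(points: np.ndarray) -> tuple[np.ndarray, bool]:
    """Algebraic least-squares sphere fit; flags ill-conditioned (planar) data."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    bb = np.einsum("ij,ij->i", points, points)
    sol, _, rank, sv = np.linalg.lstsq(A, bb, rcond=None)
    cond_ok = rank == 4 and sv[-1] > 1e-6 * sv[0]
    return sol[:3], bool(cond_ok)


def sensor_fitted_leadfield(
    scalp: trimesh.Trimesh,
    shells: ShellSpec,
    electrodes: SensorArray,
    sources: SourceSpace,
    orientation: str,
    n_terms: int = DEFAULT_N_TERMS,
    patch_radius: float = 40.0,
    max_eccentricity: float = 0.98,
) -> tuple[np.ndarray, int]:
    """Sensor-fitted-sphere lead field, one row per sensor.

    Row s is computed in the multilayer sphere fitted under sensor s; sources
    falling outside a fitted brain shell are evaluated at a clipped
    eccentricity and counted.  Returns (matrix, n_clipped); the matrix is
    average-referenced across sensors.
    """
    from scipy.spatial import cKDTree

    ori = {"x": 0, "y": 1, "z": 2}[orientation]
    moment = np.zeros(3)
    moment[ori] = 1.0
    moments = np.broadcast_to(moment, (len(sources), 3))
    L = np.empty((len(electrodes), len(sources)))
    clipped_total = 0
    # widen the patch on coarse meshes so every fit sees >= 12 vertices
    tree = cKDTree(np.asarray(scalp.vertices))
    d12, _ = tree.query(electrodes.positions, k=min(12, len(scalp.vertices)))
    min_radius = 1.05 * d12[:, -1]
    for s, sensor in enumerate(electrodes.positions):
        fit = fit_sensor_sphere(
            scalp, sensor, shells, max(patch_radius, min_radius[s])
        )
        fshells = ShellSpec(fit.radii, shells.conductivities)
        V, clipped = _series_potentials(
            fshells,
            fit.center,
            sensor[None],
            sources.positions,
            moments,
            n_terms,
            max_eccentricity=max_eccentricity,
        )
        L[s] = V[:, 0]
        clipped_total += clipped
    L -= L.mean(axis=0, keepdims=True)
    return L, clipped_total
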