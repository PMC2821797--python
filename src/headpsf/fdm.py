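"""Voxel finite-difference EEG forward solver on the labeled head volume.

Discretises the current-conservation equation  div(sigma grad V) = -I(r)
with a 7-point stencil in conservative (flux) form: the conductance of each
voxel face is the harmonic mean of the two adjacent voxel conductivities
times the voxel spacing, and faces to non-conducting (air) voxels carry no
flux (homogeneous Neumann boundary).  The resulting operator is symmetric,
singular on the constant vector, and is solved with Jacobi-preconditioned
conjugate gradients; the dipole is a pair of opposite monopoles on the grid
nodes straddling the source along its moment, with the moment magnitude
preserved (I * d = |q|).

Because the operator is symmetric the lead field can be assembled
reciprocally: one solve per sensor (current injected at the sensor node,
returned at a reference sensor node) gives the potentials of every dipole at
that sensor, instead of one solve per source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg

from .geometry import LabeledVoxelGrid, SensorArray, SourceSpace
from .sphere import Dipole

__all__ = ["FdmSystem", "assemble_fdm", "fdm_solve", "fdm_leadfield", "snap_electrodes"]

DEFAULT_TOL = 1e-8
DEFAULT_MAXITER = 10_000


@dataclass
class FdmSystem:
    """Sparse FDM operator over the conductive voxels.

    ``index`` maps each grid voxel to its unknown number (-1 outside the
    conductive domain); ``A`` is the (n_unknowns, n_unknowns) SPD-up-to-
    constant operator in units of S*mm.
    """

    grid: LabeledVoxelGrid
    A: sparse.csr_matrix
    index: np.ndarray
    tol: float = DEFAULT_TOL
    maxiter: int = DEFAULT_MAXITER
    _diag_inv: np.ndarray = field(default=None, repr=False)
    _vox: np.ndarray = field(default=None, repr=False)

    @property
    def n_unknowns(self) -> int:
        return self.A.shape[0]

    def voxel_of_unknown(self) -> np.ndarray:
        """(n_unknowns, 3) integer grid coordinates of each unknown."""
        if self._vox is None:
            order = np.argsort(self.index[self.index >= 0])
            self._vox = np.argwhere(self.index >= 0)[order]
        return self._vox


def assemble_fdm(grid: LabeledVoxelGrid) -> FdmSystem:
    """Build the 7-point conservative-flux operator from the label volume."""
    cond = grid.conductivity
    h = grid.spacing
    conductive = cond > 0
    n = int(conductive.sum())
    if n == 0:
        raise ValueError("no conductive voxels in the grid")

    index = np.full(grid.dims, -1, dtype=np.int64)
    index[conductive] = np.arange(n)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        c_lo = cond[tuple(sl_lo)]
        c_hi = cond[tuple(sl_hi)]
        both = (c_lo > 0) & (c_hi > 0)
        # face conductance: harmonic mean of adjacent conductivities * h
        g = np.zeros_like(c_lo)
        g[both] = 2.0 * c_lo[both] * c_hi[both] / (c_lo[both] + c_hi[both]) * h
        i_lo = index[tuple(sl_lo)][both]
        i_hi = index[tuple(sl_hi)][both]
        gb = g[both]
        rows.append(i_lo)
        cols.append(i_hi)
        vals.append(-gb)
        rows.append(i_hi)
        cols.append(i_lo)
        vals.append(-gb)
        np.add.at(diag, i_lo, gb)
        np.add.at(diag, i_hi, gb)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    n_comp, labels = connected_components(A != 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"conductive domain has {n_comp} disconnected components "
            f"(sizes {sorted(sizes, reverse=True)[:5]}...)"
        )
    return FdmSystem(grid, A, index)


def _dipole_monopoles(
    system: FdmSystem, dipole: Dipole
) -> tuple[np.ndarray, np.ndarray]:
    """Opposite monopole pairs realising the dipole on the grid.

    The moment is decomposed along the lattice axes: each nonzero Cartesian
    component m_a becomes a pair of monopoles +/- I at the neighbours of the
    snapped source node along axis a, with I * 2h = m_a.  A single straddling
    pair would quantise the dipole *direction* to the nearest lattice vector
    (tens of degrees off for oblique moments); the per-axis decomposition
    preserves the moment vector exactly while keeping the position snapped to
    one node.

    Returns (node_indices, currents); currents sum to zero.
    """
    grid = system.grid
    h = grid.spacing
    n0 = _nearest_unknown(system, dipole.position)
    vox0 = system.voxel_of_unknown()[n0]
    center = (vox0 + 0.5) * h + grid.origin
    nodes, currents = [], []
    for axis in range(3):
        m_a = float(dipole.moment[axis])
        if m_a == 0.0:
            continue
        step = np.zeros(3)
        step[axis] = h
        n_plus = _nearest_unknown(system, center + step)
        n_minus = _nearest_unknown(system, center - step)
        if n_plus == n_minus:
            continue  # degenerate at the domain edge; component dropped
        d = np.linalg.norm(
            (system.voxel_of_unknown()[n_plus] - system.voxel_of_unknown()[n_minus]) * h
        )
        current = m_a / d
        nodes.extend([n_plus, n_minus])
        currents.extend([current, -current])
    return np.asarray(nodes, dtype=np.int64), np.asarray(currents)


def _nearest_unknown(system: FdmSystem, point: np.ndarray) -> int:
    """Unknown index of the conductive voxel nearest to a point."""
    grid = system.grid
    ijk = grid.world_to_index(np.atleast_2d(point))[0]
    ijk = np.clip(ijk, 0, np.array(grid.dims) - 1)
    if system.index[tuple(ijk)] >= 0:
        return int(system.index[tuple(ijk)])
    # search outward over a growing cube of neighbours
    for radius in range(1, max(grid.dims)):
        lo = np.maximum(ijk - radius, 0)
        hi = np.minimum(ijk + radius + 1, grid.dims)
        sub = system.index[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        hits = np.argwhere(sub >= 0)
        if len(hits):
            centers = (hits + lo + 0.5) * grid.spacing + grid.origin
            best = hits[np.argmin(np.linalg.norm(centers - point, axis=1))]
            return int(sub[tuple(best)])
    raise ValueError("no conductive voxel found near point")


def _solve(system: FdmSystem, b: np.ndarray) -> np.ndarray:
    """Jacobi-preconditioned CG on the (consistent) singular system."""
    if system._diag_inv is None:
        system._diag_inv = 1.0 / system.A.diagonal()
    dinv = system._diag_inv
    M = sparse.linalg.LinearOperator(
        system.A.shape, matvec=lambda x: dinv * x
    )
    x, info = cg(system.A, b, rtol=system.tol, atol=0.0, maxiter=system.maxiter, M=M)
    if info != 0:
        raise RuntimeError(f"FDM conjugate-gradient solve did not converge (info={info})")
    return x - x.mean()


def fdm_solve(system: FdmSystem, dipole: Dipole) -> np.ndarray:
    """Potential (mean-zero) at every conductive voxel for one dipole."""
    ijk = system.grid.world_to_index(np.atleast_2d(dipole.position))[0]
    if (
        np.any(ijk < 0)
        or np.any(ijk >= system.grid.dims)
        or system.grid.labels[tuple(ijk)] != 4
    ):
        raise ValueError("dipole is not inside the brain compartment")
    nodes, currents = _dipole_monopoles(system, dipole)
    b = np.zeros(system.n_unknowns)
    np.add.at(b, nodes, currents)
    return _solve(system, b)


def snap_electrodes(system: FdmSystem, electrodes: SensorArray) -> np.ndarray:
    """Unknown indices of the conductive voxels nearest each electrode."""
    return np.array(
        [_nearest_unknown(system, p) for p in electrodes.positions], dtype=np.int64
    )


def fdm_leadfield(
    system: FdmSystem,
    electrodes: SensorArray,
    sources: SourceSpace,
    orientation: str,
    mode: str = "reciprocal",
) -> np.ndarray:
    """(n_electrodes, n_sources) lead field, average-referenced.

    ``mode='reciprocal'`` solves one system per sensor (injection at the
    sensor node, return at sensor 0) and evaluates every dipole by the
    potential difference of its two monopole nodes; ``mode='direct'`` solves
    one system per source.  By symmetry of the operator the two agree to
    solver tolerance.
    """
    ori = {"x": 0, "y": 1, "z": 2}[orientation]
    moment = np.zeros(3)
    moment[ori] = 1.0
    el_nodes = snap_electrodes(system, electrodes)
    n_el, n_src = len(electrodes), len(sources)
    L = np.zeros((n_el, n_src))

    if mode == "reciprocal":
        # monopole patterns for all sources (shared across sensors)
        pairs = [
            _dipole_monopoles(system, Dipole(p, moment)) for p in sources.positions
        ]
        ref = el_nodes[0]
        for s in range(1, n_el):
            if el_nodes[s] == ref:
                continue
            b = np.zeros(system.n_unknowns)
            b[el_nodes[s]] += 1.0
            b[ref] -= 1.0
            w = _solve(system, b)
            # reciprocity: V_s(dipole) - V_ref(dipole) = sum_k w(node_k) I_k
            L[s] = [w[nodes] @ currents for nodes, currents in pairs]
        # row 0 (the reference) is 0; average reference across rows
    elif mode == "direct":
        for j, p in enumerate(sources.positions):
            v = fdm_solve(system, Dipole(p, moment))
            L[:, j] = v[el_nodes]
        # subtract the reference-electrode row to match the reciprocal
        # construction before re-referencing
        L -= L[0:1, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    L -= L.mean(axis=0, keepdims=True)
    return L
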