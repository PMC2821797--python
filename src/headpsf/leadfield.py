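"""Lead-field containers: assembly, referencing, storage, error metrics.

A lead field is the (sensors x sources) matrix of scalp potentials produced
by unit dipoles at every source position for one Cartesian orientation; one
matrix exists per (head model, orientation), nine in the default analysis
(3 models x 3 orientations).  Matrices are stored in an HDF5 container with
their provenance (model tag, orientation, geometry checksum, reference
convention).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Leadfield",
    "rereference_average",
    "rdm_mag",
    "save_leadfields",
    "load_leadfields",
    "geometry_checksum",
]

MODELS = ("SPH", "BEM", "FDM")
ORIENTATIONS = ("x", "y", "z")


@dataclass(frozen=True)
class Leadfield:
    """One (sensors x sources) potential matrix with provenance tags."""

    matrix: np.ndarray
    model: str  # SPH | BEM | FDM
    orientation: str  # x | y | z
    geometry_checksum: str = ""
    reference: str = "average"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("leadfield matrix must be 2-D (sensors x sources)")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        object.__setattr__(self, "matrix", m)

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


def geometry_checksum(*arrays: np.ndarray) -> str:
    """Stable hex digest of geometry arrays (vertex/sensor/source positions)."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()[:16]


def rereference_average(lf: Leadfield) -> Leadfield:
    """Remove each column's mean across sensors.  Idempotent."""
    m = lf.matrix - lf.matrix.mean(axis=0, keepdims=True)
    return replace(lf, matrix=m, reference="average")


def rdm_mag(v: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Relative difference measure and magnitude ratio of two potential maps.

    RDM = || v/||v|| - w/||w|| ||  (0 = same shape, sqrt(2) = orthogonal);
    MAG = ||v|| / ||w||.
    """
    v = np.asarray(v, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("rdm_mag is undefined for zero-norm inputs")
    return float(np.linalg.norm(v / nv - w / nw)), float(nv / nw)


def save_leadfields(path: str | Path, fields: list[Leadfield]) -> None:
    """Write lead fields of one model to an HDF5 container (one group per
    orientation: /x/leadfield, ... plus tag attributes)."""
    with h5py.File(path, "w") as f:
        for lf in fields:
            g = f.create_group(lf.orientation)
            g.create_dataset("leadfield", data=lf.matrix)
            g.attrs["model"] = lf.model
            g.attrs["orientation"] = lf.orientation
            g.attrs["geometry_checksum"] = lf.geometry_checksum
            g.attrs["reference"] = lf.reference


def save_leadfield_csv(lf: Leadfield, path: str | Path) -> None:
    """Delimited-text export (sensors as rows) for small matrices."""
    header = f"model={lf.model} orientation={lf.orientation} reference={lf.reference}"
    np.savetxt(path, lf.matrix, delimiter="\t", header=header)


def load_leadfields(path: str | Path) -> list[Leadfield]:
    """Read back every orientation group; round-trips bit-identically."""
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys(), key=lambda k: ORIENTATIONS.index(k)):
            g = f[key]
            out.append(
                Leadfield(
                    matrix=g["leadfield"][()],
                    model=str(g.attrs["model"]),
                    orientation=str(g.attrs["orientation"]),
                    geometry_checksum=str(g.attrs["geometry_checksum"]),
                    reference=str(g.attrs["reference"]),
                )
            )
    return out
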