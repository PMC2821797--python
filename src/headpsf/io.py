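"""File-format helpers: NIfTI label volumes, point lists, PLY surfaces."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .geometry import LabeledVoxelGrid, ShellSpec

__all__ = ["save_label_volume", "load_label_volume", "save_points", "load_points"]


def save_label_volume(grid: LabeledVoxelGrid, path: str | Path) -> None:
    """Write the integer tissue-label volume as NIfTI (mm affine)."""
    affine = np.eye(4)
    affine[:3, :3] *= grid.spacing
    affine[:3, 3] = grid.origin + grid.spacing / 2.0
    img = nib.Nifti1Image(grid.labels.astype(np.int16), affine)
    nib.save(img, str(path))


def load_label_volume(path: str | Path, shells: ShellSpec) -> LabeledVoxelGrid:
    img = nib.load(str(path))
    spacing = float(img.affine[0, 0])
    origin = img.affine[:3, 3] - spacing / 2.0
    labels = np.asarray(img.dataobj).astype(np.int8)
    return LabeledVoxelGrid(labels, spacing, origin, shells)


def save_points(points: np.ndarray, path: str | Path) -> None:
    """Tab-delimited x, y, z in mm, one point per line."""
    np.savetxt(path, np.asarray(points), delimiter="\t", header="mm")


def load_points(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", comments="#")


def load_surfaces(paths: list[str | Path]) -> list[trimesh.Trimesh]:
    """Read 4 PLY surfaces ordered outer→inner."""
    return [trimesh.load(str(p), process=False) for p in paths]
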