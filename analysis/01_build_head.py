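"""Build the synthetic four-shell head and all geometric inputs.

Writes the nested scalp/skull/CSF/brain surfaces (PLY), the labeled voxel
volume (NIfTI), the 62-electrode montage and the 5000-point cortical source
space with its 26 probe sources under results/head/.
"""

from pathlib import Path

import numpy as np

from headpsf.config import RunConfig, save_config
from headpsf.geometry import voxelize
from headpsf.io import save_label_volume, save_points
from headpsf.pipeline import build_geometry

OUT = Path(__file__).resolve().parent.parent / "results" / "head"


def main() -> None:
    cfg = RunConfig()
    shells, meshes, sensors, space = build_geometry(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    for name, mesh in zip(("scalp", "skull", "csf", "brain"), meshes):
        mesh.export(OUT / f"{name}.ply", file_type="ply", encoding="ascii")
    save_label_volume(voxelize(meshes, shells, cfg.fdm_spacing), OUT / "labels.nii.gz")
    save_points(sensors.positions, OUT / "sensors.tsv")
    save_points(space.positions, OUT / "sources.tsv")
    np.savetxt(OUT / "probes.tsv", space.probe_indices, fmt="%d", header="index")
    save_config(cfg, OUT / "config.yaml")
    print(f"shell radii (mm): {shells.radii}")
    print(f"{len(sensors)} electrodes, {len(space)} sources, "
          f"{len(space.probe_indices)} probes -> {OUT}")


if __name__ == "__main__":
    main()
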