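"""Field export: HDF5 arrays and legacy-VTK structured grids.

Writers only — the package never parses these formats.  The VTK output
is the plain ASCII STRUCTURED_POINTS dialect, readable by ParaView and
friends without any library on our side.
"""

from __future__ import annotations

import numpy as np

from .flow import FlowField
from .geometry import LabeledGrid


def save_fields_h5(path, grid: LabeledGrid, flow: FlowField | None = None, species: dict | None = None) -> None:
    """Write the material raster and optional flow/species fields to HDF5.

    ``species`` maps names (e.g. "c_GLC") to (nx, ny) arrays.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["spacing_um"] = grid.spacing
        f.attrs["depth_um"] = grid.depth
        f.attrs["origin_um"] = grid.origin
        f.create_dataset("labels", data=grid.labels)
        f.create_dataset("islet_id", data=grid.islet_id)
        if flow is not None:
            f.create_dataset("pressure_Pa", data=flow.pressure)
            f.create_dataset("face_flux_x_m3s", data=flow.face_flux_x)
            f.create_dataset("face_flux_y_m3s", data=flow.face_flux_y)
            f.create_dataset("speed_ms", data=flow.velocity_magnitude())
            g = f.create_group("port_fluxes_ul_min")
            for name, q in flow.port_fluxes.items():
                g.attrs[name] = q
        for name, arr in (species or {}).items():
            f.create_dataset(name, data=np.asarray(arr))


def save_vtk(path, grid: LabeledGrid, fields: dict) -> None:
    """Write cell fields as an ASCII legacy-VTK structured-points file.

    ``fields`` maps names to (nx, ny) arrays; NaNs are written as zeros
    (walls carry no physical value).
    """
    nx, ny = grid.shape
    with open(path, "w", encoding="utf-8") as f:
        f.write("# vtk DataFile Version 3.0\nislet-VMO fields\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        f.write(f"ORIGIN {grid.origin[0]} {grid.origin[1]} 0\n")
        f.write(f"SPACING {grid.spacing} {grid.spacing} {grid.depth}\n")
        f.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in fields.items():
            a = np.nan_to_num(np.asarray(arr, dtype=float))
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK cell ordering: x fastest
            np.savetxt(f, a.T.reshape(ny, nx), fmt="%.6e")
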