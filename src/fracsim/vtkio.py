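"""Minimal legacy-VTK (ASCII) export of labelled quad meshes."""

from __future__ import annotations

import numpy as np

from .geometry import MeshModel

__all__ = ["write_vtk"]


def write_vtk(path, mesh: MeshModel, cell_data: dict | None = None,
              point_data: dict | None = None, title: str = "fracsim") -> None:
    """Write the mesh with optional per-cell / per-node scalar fields."""
    nodes, elems = mesh.nodes, mesh.elements
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    for x, z in nodes:
        lines.append(f"{x:.10g} {z:.10g} 0")
    lines.append(f"CELLS {len(elems)} {5 * len(elems)}")
    for conn in elems:
        lines.append("4 " + " ".join(str(int(n)) for n in conn))
    lines.append(f"CELL_TYPES {len(elems)}")
    lines.extend(["9"] * len(elems))

    if cell_data:
        lines.append(f"CELL_DATA {len(elems)}")
        for name, values in cell_data.items():
            arr = np.asarray(values)
            if arr.dtype.kind in "OUS":   # categorical labels -> integer codes
                cats, codes = np.unique(arr.astype(str), return_inverse=True)
                lines.append(f"SCALARS {name}_code int 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(str(int(c)) for c in codes)
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{float(v):.10g}" for v in arr)
    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{float(v):.10g}" for v in np.asarray(values))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
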