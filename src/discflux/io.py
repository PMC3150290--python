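"""Result writers: VTK (.vtu ASCII) field snapshots, CSV probe series,
JSON scalar summaries, and a provenance manifest with checksums."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import DiscMesh

_VTU_QUAD_TRI = 22   # VTK quadratic triangle
_VTU_QUAD_EDGE = 21  # VTK quadratic edge (column meshes)


def write_vtu(path, mesh: DiscMesh,
              point_data: Optional[dict] = None,
              cell_data: Optional[dict] = None,
              coords: Optional[np.ndarray] = None) -> None:
    """Minimal ASCII .vtu writer for the quadratic meshes used here."""
    x = mesh.nodes if coords is None else coords
    if x.ndim == 1:
        x = x[:, None]
    pts = np.zeros((len(x), 3))
    pts[:, :x.shape[1]] = x
    conn = mesh.elems_p2
    ctype = _VTU_QUAD_TRI if mesh.kind == "axisym" else _VTU_QUAD_EDGE
    offsets = np.arange(1, len(conn) + 1) * conn.shape[1]

    def arr(a, name, comps=1):
        a = np.asarray(a, dtype=float)
        txt = " ".join(f"{v:.9g}" for v in a.ravel())
        nc = f' NumberOfComponents="{comps}"' if comps > 1 else ""
        return (f'<DataArray type="Float64" Name="{name}"{nc} '
                f'format="ascii">{txt}</DataArray>')

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{len(pts)}" '
             f'NumberOfCells="{len(conn)}">',
             "<Points>", arr(pts, "points", 3), "</Points>",
             "<Cells>",
             '<DataArray type="Int64" Name="connectivity" format="ascii">'
             + " ".join(map(str, conn.ravel())) + "</DataArray>",
             '<DataArray type="Int64" Name="offsets" format="ascii">'
             + " ".join(map(str, offsets)) + "</DataArray>",
             '<DataArray type="UInt8" Name="types" format="ascii">'
             + " ".join([str(ctype)] * len(conn)) + "</DataArray>",
             "</Cells>"]
    if point_data:
        parts.append("<PointData>")
        for name, vals in point_data.items():
            v = np.asarray(vals, dtype=float)
            comps = 1 if v.ndim == 1 else v.shape[1]
            parts.append(arr(np.nan_to_num(v), name, comps))
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, vals in cell_data.items():
            v = np.asarray(vals, dtype=float)
            comps = 1 if v.ndim == 1 else v.shape[1]
            parts.append(arr(v, name, comps))
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_outputs(result, directory, config_text: Optional[str] = None
                  ) -> dict:
    """Write a ScenarioResult: probe CSVs, snapshot VTUs, JSON summary and
    a manifest listing every file with a checksum."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    probes_path = out / "probes.csv"
    result.probes.to_csv(probes_path, index=False)
    written.append(probes_path)
    if len(result.height):
        hpath = out / "height.csv"
        result.height.to_csv(hpath, index=False)
        written.append(hpath)

    for name, snap in result.snapshots.items():
        pd_fields = {k: v for k, v in snap.items()
                     if isinstance(v, np.ndarray)
                     and len(v) == result.mesh.n_nodes}
        vtu = out / f"{name}.vtu"
        write_vtu(vtu, result.mesh, point_data=pd_fields)
        written.append(vtu)

    summary_path = out / "summary.json"
    summary = {k: v for k, v in result.summaries.items()
               if isinstance(v, (int, float, str, bool))}
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(summary_path)

    if config_text is not None:
        cfg = out / "config.yaml"
        cfg.write_text(config_text)
        written.append(cfg)

    manifest = {p.name: _checksum(p) for p in written}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
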