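"""Field and mesh I/O.

Three on-disk layouts are supported:

* **VTK legacy ASCII time series** — a directory with one unstructured-grid
  ``.vtk`` file per snapshot plus a ``series.json`` index carrying the cycle
  period, snapshot times and field kind.  The legacy format is written and
  parsed directly (plain text), covering exactly the subset used here:
  tetrahedral cells, wall triangles, and one point-data vector or scalar.
* **HDF5 bundle** — a single ``.h5`` file with mesh and field datasets.
* **CSV waveforms** — two columns ``time_s,value``.

All files store SI units; values round-trip exactly at double precision
(``%.17g`` formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .fields import FieldError, TimeGrid, VelocityField, WallShearField
from .mesh import Mesh, MeshError

_VTK_TET = 10
_VTK_TRI = 5

FIELD_NAMES = {"velocity": "velocity", "wall_shear": "wall_shear", "scalar": "scalar"}


# ---------------------------------------------------------------- legacy VTK


def _fmt(arr: np.ndarray) -> str:
    return "\n".join(" ".join(f"{x:.17g}" for x in row) for row in np.atleast_2d(arr))


def write_vtk(path, mesh: Mesh, point_data: dict[str, np.ndarray] | None = None,
              comment: str = "haemopost field") -> None:
    """Write one legacy-ASCII unstructured-grid file (tets + wall triangles)."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", comment, "ASCII", "DATASET UNSTRUCTURED_GRID"]
    n = len(mesh.points)
    lines.append(f"POINTS {n} double")
    lines.append(_fmt(mesh.points))
    m, k = len(mesh.tets), len(mesh.wall_tris)
    lines.append(f"CELLS {m + k} {5 * m + 4 * k}")
    if m:
        lines.append(_fmt(np.column_stack([np.full(m, 4, dtype=np.int64), mesh.tets])))
    if k:
        lines.append(_fmt(np.column_stack([np.full(k, 3, dtype=np.int64), mesh.wall_tris])))
    lines.append(f"CELL_TYPES {m + k}")
    lines.append("\n".join([str(_VTK_TET)] * m + [str(_VTK_TRI)] * k))
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.append(_fmt(arr))
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.append(_fmt(arr.reshape(-1, 1)))
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path) -> tuple[Mesh, dict[str, np.ndarray]]:
    """Read a legacy-ASCII unstructured-grid file written by :func:`write_vtk`."""
    tokens = Path(path).read_text().split("\n")
    # strip header lines; work on a token stream from line 4 onward
    flat: list[str] = []
    for line in tokens[3:]:
        flat.extend(line.split())
    if not flat or flat[0] != "DATASET" or flat[1] != "UNSTRUCTURED_GRID":
        raise FieldError(f"{path}: not a legacy VTK unstructured grid")
    i = 2
    points = tets = tris = None
    point_data: dict[str, np.ndarray] = {}
    n_points = 0
    cells_raw = types = None
    while i < len(flat):
        tok = flat[i]
        if tok == "POINTS":
            n_points = int(flat[i + 1])
            vals = np.array(flat[i + 3:i + 3 + 3 * n_points], dtype=np.float64)
            points = vals.reshape(n_points, 3)
            i += 3 + 3 * n_points
        elif tok == "CELLS":
            n_cells, n_ints = int(flat[i + 1]), int(flat[i + 2])
            cells_raw = np.array(flat[i + 3:i + 3 + n_ints], dtype=np.int64)
            i += 3 + n_ints
        elif tok == "CELL_TYPES":
            n_cells = int(flat[i + 1])
            types = np.array(flat[i + 2:i + 2 + n_cells], dtype=np.int64)
            i += 2 + n_cells
        elif tok == "POINT_DATA":
            i += 2
        elif tok == "VECTORS":
            name = flat[i + 1]
            vals = np.array(flat[i + 3:i + 3 + 3 * n_points], dtype=np.float64)
            point_data[name] = vals.reshape(n_points, 3)
            i += 3 + 3 * n_points
        elif tok == "SCALARS":
            name = flat[i + 1]
            ncomp = int(flat[i + 3]) if flat[i + 3].isdigit() else 1
            j = i + 4
            if flat[j] == "LOOKUP_TABLE":
                j += 2
            vals = np.array(flat[j:j + ncomp * n_points], dtype=np.float64)
            point_data[name] = vals if ncomp == 1 else vals.reshape(n_points, ncomp)
            i = j + ncomp * n_points
        else:
            i += 1
    if points is None or cells_raw is None or types is None:
        raise FieldError(f"{path}: incomplete VTK file")
    tet_list, tri_list = [], []
    pos = 0
    for t in types:
        cnt = cells_raw[pos]
        conn = cells_raw[pos + 1:pos + 1 + cnt]
        if t == _VTK_TET:
            tet_list.append(conn)
        elif t == _VTK_TRI:
            tri_list.append(conn)
        else:
            raise MeshError(f"{path}: unsupported cell type {t} (only tetrahedra "
                            "volume cells are handled)")
        pos += 1 + cnt
    tets = np.array(tet_list, dtype=np.int64).reshape(-1, 4)
    tris = np.array(tri_list, dtype=np.int64).reshape(-1, 3)
    return Mesh(points, tets, tris), point_data


# ----------------------------------------------------------- field bundles


def save_field(path, field: VelocityField | WallShearField, fmt: str | None = None) -> None:
    """Save a field as a VTK series directory or an HDF5 bundle.

    ``fmt`` is inferred from the path when omitted: ``.h5`` suffix means
    HDF5, anything else is treated as a series directory.
    """
    path = Path(path)
    if fmt is None:
        fmt = "h5" if path.suffix in {".h5", ".hdf5"} else "vtk"
    if fmt == "h5":
        _save_h5(path, field)
    else:
        _save_vtk_series(path, field)


def load_field(path, kind: str):
    """Load a typed field. ``kind`` is one of {velocity, wall_shear, scalar}."""
    if kind not in FIELD_NAMES:
        raise ValueError(f"unknown field kind {kind!r}")
    path = Path(path)
    if path.is_file() and path.suffix in {".h5", ".hdf5"}:
        return _load_h5(path, kind)
    if path.is_dir():
        return _load_vtk_series(path, kind)
    raise FileNotFoundError(path)


def _save_vtk_series(dirpath: Path, field) -> None:
    dirpath.mkdir(parents=True, exist_ok=True)
    is_vel = isinstance(field, VelocityField)
    kind = "velocity" if is_vel else "wall_shear"
    mesh = field.mesh
    if mesh is None:
        raise FieldError("wall-shear VTK series requires an attached mesh")
    files = []
    for j, t in enumerate(field.grid.times):
        fname = f"snapshot_{j:04d}.vtk"
        if is_vel:
            data = {"velocity": field.values[j]}
        else:
            full = np.zeros((len(mesh.points), 3))
            full[field.wall_node_ids] = field.tau[j]
            data = {"wall_shear": full}
        write_vtk(dirpath / fname, mesh, data)
        files.append(fname)
    meta = {
        "kind": kind,
        "period_s": field.grid.period,
        "times_s": field.grid.times.tolist(),
        "files": files,
    }
    if not is_vel:
        meta["wall_node_ids"] = field.wall_node_ids.tolist()
    (dirpath / "series.json").write_text(json.dumps(meta, indent=1))


def _load_vtk_series(dirpath: Path, kind: str):
    meta_path = dirpath / "series.json"
    if not meta_path.exists():
        raise FieldError(f"{dirpath}: missing series.json time metadata")
    meta = json.loads(meta_path.read_text())
    if "times_s" not in meta or "period_s" not in meta:
        raise FieldError(f"{dirpath}: series.json lacks time metadata")
    times = np.asarray(meta["times_s"], dtype=np.float64)
    if len(times) < 2:
        raise FieldError("a field series needs at least 2 snapshots")
    grid = TimeGrid(float(meta["period_s"]), times)
    mesh = None
    snaps = []
    name = FIELD_NAMES[kind]
    for fname in meta["files"]:
        m, data = read_vtk(dirpath / fname)
        if mesh is None:
            mesh = m
        if name not in data:
            raise FieldError(f"{fname}: field '{name}' not found")
        snaps.append(data[name])
    values = np.stack(snaps)
    if kind == "velocity":
        return VelocityField(mesh, grid, values)
    if kind == "wall_shear":
        ids = np.asarray(meta.get("wall_node_ids", mesh.wall_node_ids), dtype=np.int64)
        return WallShearField(ids, grid, values[:, ids, :], mesh=mesh)
    return mesh, grid, values


def _save_h5(path: Path, field) -> None:
    is_vel = isinstance(field, VelocityField)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "velocity" if is_vel else "wall_shear"
        f.attrs["period_s"] = field.grid.period
        f["times_s"] = field.grid.times
        mesh = field.mesh
        if mesh is not None:
            g = f.create_group("mesh")
            g["points"] = mesh.points
            g["tets"] = mesh.tets
            g["wall_tris"] = mesh.wall_tris
        if is_vel:
            f["values"] = field.values
        else:
            f["values"] = field.tau
            f["wall_node_ids"] = field.wall_node_ids


def _load_h5(path: Path, kind: str):
    with h5py.File(path, "r") as f:
        if "times_s" not in f:
            raise FieldError(f"{path}: missing time metadata")
        times = f["times_s"][()]
        if len(times) < 2:
            raise FieldError("a field series needs at least 2 snapshots")
        grid = TimeGrid(float(f.attrs["period_s"]), times)
        mesh = None
        if "mesh" in f:
            mesh = Mesh(f["mesh/points"][()], f["mesh/tets"][()], f["mesh/wall_tris"][()])
        values = f["values"][()]
        if kind == "velocity":
            return VelocityField(mesh, grid, values)
        if kind == "wall_shear":
            ids = f["wall_node_ids"][()]
            return WallShearField(ids, grid, values, mesh=mesh)
        return mesh, grid, values


# ----------------------------------------------------------------- waveforms


def write_waveform(path, times: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"time_s": times, "value": values}).to_csv(path, index=False, float_format="%.17g")


def read_waveform(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    return df["time_s"].to_numpy(), df["value"].to_numpy()
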