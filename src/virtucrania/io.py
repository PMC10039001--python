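"""File formats: meshes (PLY/OBJ/STL), landmark CSV, pairing JSON.

Landmark CSV layout: header ``name,x,y,z`` with an optional ``estimated``
column; empty coordinate fields mark missing landmarks. The bilateral
pairing table travels as a JSON sidecar:
``{"pairs": [["asterion_L", "asterion_R"], ...], "midline": ["glabella", ...]}``.
All coordinates are millimetres.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .landmarks import InvalidLandmarksError, LandmarkConfiguration, PairingTable
from .meshes import MeshError, TriMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_pairing",
    "write_pairing",
]

_MESH_EXTENSIONS = {".ply", ".obj", ".stl"}


def read_mesh(path: str | Path) -> TriMesh:
    """Read a PLY, OBJ or STL triangular mesh (mm).

    STL carries no shared-vertex topology, so vertices are merged at
    1e-6 mm and the watertight flag recomputed. OBJ's 1-based indices are
    converted to the internal 0-based convention.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _MESH_EXTENSIONS:
        raise MeshError(f"unknown mesh extension {ext!r} (expected PLY/OBJ/STL)")
    try:
        tm = _trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise MeshError(f"cannot read {path}: {exc}") from exc
    merge = ext == ".stl"
    return TriMesh(
        np.asarray(tm.vertices), np.asarray(tm.faces), merge_vertices=merge
    )


def write_mesh(
    mesh: TriMesh,
    path: str | Path,
    per_face_scalars: np.ndarray | None = None,
    binary: bool = False,
) -> None:
    """Write a mesh; optional per-face scalars go to a PLY `quality` property."""
    path = Path(path)
    ext = path.suffix.lower()
    if per_face_scalars is not None:
        if ext != ".ply":
            raise MeshError("per-face scalars are only supported in PLY")
        _write_ply_with_quality(mesh, path, np.asarray(per_face_scalars, dtype=float))
        return
    if ext not in _MESH_EXTENSIONS:
        raise MeshError(f"unknown mesh extension {ext!r}")
    tm = mesh.as_trimesh()
    if ext == ".ply":
        data = tm.export(file_type="ply", encoding="binary" if binary else "ascii")
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
    else:
        tm.export(str(path))


def _write_ply_with_quality(mesh: TriMesh, path: Path, scalars: np.ndarray) -> None:
    faces = mesh.faces
    if len(scalars) != len(faces):
        raise MeshError("one scalar per face required")
    v = mesh.vertices
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(v)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "property float quality",
        "end_header",
    ]
    for p in v:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    for f, q in zip(faces, scalars):
        lines.append(f"3 {f[0]} {f[1]} {f[2]} {q:.9g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_landmarks(config: LandmarkConfiguration, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y", "z", "estimated"])
        for name, xyz, missing, est in zip(
            config.landmark_names,
            config.coords,
            config.missing_mask,
            config.estimated_mask,
        ):
            if missing:
                writer.writerow([name, "", "", "", int(est)])
            else:
                writer.writerow(
                    [name, f"{xyz[0]:.9g}", f"{xyz[1]:.9g}", f"{xyz[2]:.9g}", int(est)]
                )
    if config.pairing is not None:
        write_pairing(config.pairing, path.with_suffix(".pairing.json"))


def read_landmarks(
    path: str | Path, specimen_id: str | None = None
) -> LandmarkConfiguration:
    """Read a landmark CSV; empty coordinate fields become missing values."""
    path = Path(path)
    names: list[str] = []
    coords: list[list[float]] = []
    missing: list[bool] = []
    estimated: list[bool] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "x", "y", "z"} <= set(
            reader.fieldnames
        ):
            raise InvalidLandmarksError(f"{path}: header must contain name,x,y,z")
        for row in reader:
            name = row["name"].strip()
            if name in names:
                raise InvalidLandmarksError(f"{path}: duplicate landmark {name!r}")
            names.append(name)
            vals = [row["x"].strip(), row["y"].strip(), row["z"].strip()]
            if any(v == "" for v in vals):
                coords.append([np.nan] * 3)
                missing.append(True)
            else:
                coords.append([float(v) for v in vals])
                missing.append(False)
            estimated.append(bool(int(row.get("estimated") or 0)))
    pairing_path = path.with_suffix(".pairing.json")
    pairing = read_pairing(pairing_path) if pairing_path.exists() else None
    return LandmarkConfiguration(
        specimen_id=specimen_id or path.stem,
        landmark_names=names,
        coords=np.array(coords),
        missing_mask=np.array(missing),
        pairing=pairing,
        estimated_mask=np.array(estimated),
    )


def write_pairing(pairing: PairingTable, path: str | Path) -> None:
    payload = {
        "pairs": [list(p) for p in pairing.pairs],
        "midline": list(pairing.midline),
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_pairing(path: str | Path) -> PairingTable:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PairingTable(
        pairs=tuple(tuple(p) for p in payload["pairs"]),
        midline=tuple(payload["midline"]),
    )
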