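"""Mesh and contour file I/O plus ground-truth mesh volume.

Meshes are closed triangulated LV endocardial surfaces in millimetres;
their enclosed volume is the ground truth that biplane estimates are judged
against.  PLY (ascii/binary) and OBJ go through :mod:`trimesh`; legacy
ascii VTK polydata is parsed directly (POINTS / POLYGONS sections only).

Contours are stored in a small CSV dialect::

    # view=A4C units=mm
    x1,y1
    x2,y2
    ...

an *open* polyline from one basal corner over the apex to the other basal
corner; the mitral-annulus chord between the endpoints closes the cavity
implicitly, matching clinical tracing practice.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import trimesh

from .geometry import Contour2D, ContourError

__all__ = [
    "read_mesh",
    "write_mesh",
    "mesh_volume",
    "is_closed",
    "read_contour",
    "write_contour",
    "MeshFormatError",
    "NotWatertightError",
    "VIEW_LABELS",
]

MM3_PER_ML = 1000.0
VIEW_LABELS = ("A4C", "A2C", "A3C", "OTHER")


class MeshFormatError(ValueError):
    """Unreadable or unsupported mesh file."""


class NotWatertightError(ValueError):
    """Volume requested for a mesh that is not closed."""


# ---------------------------------------------------------------------------
# meshes


def _read_legacy_vtk(path: Path) -> trimesh.Trimesh:
    """Parse an ascii legacy-VTK polydata file (POINTS + POLYGONS)."""
    tokens = []
    with open(path) as fh:
        header = fh.readline()
        if "vtk" not in header.lower():
            raise MeshFormatError(f"{path}: not a legacy VTK file")
        fh.readline()  # title
        fmt = fh.readline().strip().upper()
        if fmt != "ASCII":
            raise MeshFormatError(f"{path}: only ascii legacy VTK is supported")
        dataset = fh.readline().split()
        if len(dataset) < 2 or dataset[1].upper() != "POLYDATA":
            raise MeshFormatError(f"{path}: DATASET POLYDATA expected")
        tokens = fh.read().split()

    def section(name):
        try:
            i = [t.upper() for t in tokens].index(name)
        except ValueError:
            raise MeshFormatError(f"{path}: missing {name} section") from None
        return i

    ip = section("POINTS")
    npts = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3: ip + 3 + 3 * npts], dtype=float)
    vertices = coords.reshape(npts, 3)

    ig = section("POLYGONS")
    ncells = int(tokens[ig + 1])
    data, j = [], ig + 3
    for _ in range(ncells):
        k = int(tokens[j])
        if k != 3:
            raise MeshFormatError(f"{path}: non-triangular polygon (size {k})")
        data.append([int(tokens[j + 1]), int(tokens[j + 2]), int(tokens[j + 3])])
        j += k + 1
    return trimesh.Trimesh(vertices=vertices, faces=np.asarray(data),
                           process=False)


def _write_legacy_vtk(mesh: trimesh.Trimesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlvvol mesh\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        n = len(mesh.faces)
        fh.write(f"POLYGONS {n} {4 * n}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path) -> trimesh.Trimesh:
    """Load a triangle mesh (PLY, OBJ or legacy ascii VTK), units mm.

    Orientation is normalized so the signed volume of a closed mesh is
    positive.  Open or non-manifold meshes load fine but are flagged:
    :func:`mesh_volume` will refuse them.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"{path}: no such file")
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        mesh = _read_legacy_vtk(path)
    elif suffix in (".ply", ".obj"):
        try:
            loaded = trimesh.load(str(path), force="mesh", process=False)
        except Exception as exc:  # noqa: BLE001 - normalize loader errors
            raise MeshFormatError(f"{path}: unreadable mesh ({exc})") from exc
        if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
            raise MeshFormatError(f"{path}: no triangle data found")
        mesh = loaded
    else:
        raise MeshFormatError(
            f"{path}: unsupported format '{suffix}' (use .ply/.obj/.vtk)")
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write PLY/OBJ via trimesh, or legacy ascii VTK polydata."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        _write_legacy_vtk(mesh, path)
    else:
        mesh.export(str(path))


def is_closed(mesh: trimesh.Trimesh) -> bool:
    """True when every edge is shared by exactly two faces."""
    return bool(mesh.is_watertight)


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume in mL by the divergence theorem.

    Sums signed tetrahedron volumes spanned by each face and the origin;
    orientation is normalized (all faces flipped) if the signed volume is
    negative.  Refuses meshes that are not watertight.
    """
    if not is_closed(mesh):
        raise NotWatertightError("mesh is not watertight; volume undefined")
    return abs(float(mesh.volume)) / MM3_PER_ML


# ---------------------------------------------------------------------------
# contour files

_HEADER_RE = re.compile(r"^#\s*view=(\S+)\s+units=(\S+)\s*$")


def write_contour(contour: Contour2D, path, view_label: str = "OTHER") -> None:
    """Write a contour to the CSV dialect (header + x,y rows, mm)."""
    if view_label not in VIEW_LABELS:
        raise ValueError(f"view_label must be one of {VIEW_LABELS}")
    with open(path, "w") as fh:
        fh.write(f"# view={view_label} units=mm\n")
        for x, y in contour.points:
            fh.write(f"{x:.12g},{y:.12g}\n")


def read_contour(path) -> tuple[Contour2D, str]:
    """Read and validate a contour CSV; returns (contour, view_label).

    Validation rejects fewer than 10 points, NaN coordinates and
    self-intersecting polylines.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        m = _HEADER_RE.match(first.strip())
        if not m:
            raise ContourError(
                f"{path}: missing '# view=<label> units=mm' header")
        label, units = m.group(1), m.group(2)
        if label not in VIEW_LABELS:
            raise ContourError(f"{path}: unknown view label {label!r}")
        if units != "mm":
            raise ContourError(f"{path}: unsupported units {units!r}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ContourError(f"{path}:{lineno}: expected 'x,y'")
            rows.append([float(parts[0]), float(parts[1])])
    contour = Contour2D(np.asarray(rows, dtype=float))  # validates
    return contour, label
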