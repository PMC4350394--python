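"""Reading and writing triangle meshes in OFF, OBJ and PLY.

Hand-written parsers for the three ASCII-friendly exchange formats (plus
little/big-endian binary PLY).  Reads validate indices and report the
offending location; OFF round-trips preserve vertices and faces bit-exactly
(full repr precision).
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import List, Optional

import numpy as np

from .surfaces import SurfaceError, TriSurface


class MeshParseError(SurfaceError):
    """Unparseable mesh file; message names the file and location."""


_FORMATS = ("off", "obj", "ply")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshParseError(f"unsupported mesh format {fmt!r} for {path}")
    return fmt


def read_surface(path, fmt: Optional[str] = None) -> TriSurface:
    """Read a triangle mesh from OFF, OBJ or PLY (format from extension)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "off":
        return _read_off(path)
    if fmt == "obj":
        return _read_obj(path)
    return _read_ply(path)


def write_surface(surface: TriSurface, path, fmt: Optional[str] = None,
                  binary: bool = False,
                  vertex_scalar: Optional[np.ndarray] = None,
                  scalar_name: str = "quality") -> None:
    """Write a mesh; ``vertex_scalar`` adds a per-vertex property (PLY only)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "off":
        _write_off(surface, path)
    elif fmt == "obj":
        _write_obj(surface, path)
    else:
        _write_ply(surface, path, binary=binary, vertex_scalar=vertex_scalar,
                   scalar_name=scalar_name)


def _check_faces(faces: np.ndarray, n_vertices: int, path: Path) -> None:
    if faces.size == 0:
        return
    bad = np.nonzero((faces < 0) | (faces >= n_vertices))[0]
    if len(bad):
        i = int(bad[0] // 3) if faces.ndim == 1 else int(bad[0])
        raise MeshParseError(
            f"{path}: face {i} references vertex index out of range "
            f"(mesh has {n_vertices} vertices)")


# ---------------------------------------------------------------------------
# OFF
# ---------------------------------------------------------------------------

def _read_off(path: Path) -> TriSurface:
    tokens: List[str] = []
    with open(path, "r") as fh:
        first = fh.readline().strip()
        if not first.startswith("OFF"):
            raise MeshParseError(f"{path}: missing OFF header")
        rest = first[3:].strip()
        if rest:                       # counts on the header line
            tokens.extend(rest.split())
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if len(tokens) < 3:
        raise MeshParseError(f"{path}: truncated OFF header")
    try:
        nv, nf = int(tokens[0]), int(tokens[1])
    except ValueError as exc:
        raise MeshParseError(f"{path}: bad OFF counts") from exc
    pos = 3
    if len(tokens) < pos + 3 * nv:
        raise MeshParseError(f"{path}: truncated vertex block")
    verts = np.array(tokens[pos:pos + 3 * nv], dtype=np.float64).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for i in range(nf):
        if pos >= len(tokens):
            raise MeshParseError(f"{path}: truncated at face {i}")
        k = int(tokens[pos])
        if k != 3:
            raise MeshParseError(f"{path}: face {i} has {k} vertices; "
                                 "only triangles are supported")
        faces.append([int(t) for t in tokens[pos + 1:pos + 4]])
        pos += 1 + k
    faces = np.array(faces, dtype=np.int64).reshape(nf, 3)
    _check_faces(faces, nv, path)
    return TriSurface(verts, faces)


def _write_off(surface: TriSurface, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{surface.n_vertices} {surface.n_faces} 0\n")
        for v in surface.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in surface.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# OBJ
# ---------------------------------------------------------------------------

def _read_obj(path: Path) -> TriSurface:
    verts, faces = [], []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split("#", 1)[0].split()
            if not parts:
                continue
            if parts[0] == "v":
                if len(parts) < 4:
                    raise MeshParseError(f"{path}:{lineno}: short vertex line")
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) for p in parts[1:]]
                if len(idx) != 3:
                    raise MeshParseError(
                        f"{path}:{lineno}: only triangular faces supported")
                # OBJ is 1-based; negative indices count from the end
                idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
                faces.append(idx)
    verts = np.array(verts, dtype=np.float64).reshape(-1, 3)
    faces = np.array(faces, dtype=np.int64).reshape(-1, 3)
    _check_faces(faces, len(verts), path)
    return TriSurface(verts, faces)


def _write_obj(surface: TriSurface, path: Path) -> None:
    with open(path, "w") as fh:
        for v in surface.vertices:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in surface.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# PLY (ascii, binary_little_endian, binary_big_endian)
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> TriSurface:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise MeshParseError(f"{path}: missing ply magic")
        fmt = None
        elements = []        # (name, count, [(prop_name, dtype, list_count_dtype)])
        while True:
            line = fh.readline()
            if not line:
                raise MeshParseError(f"{path}: unterminated PLY header")
            parts = line.decode("ascii", "replace").split()
            if not parts or parts[0] == "comment":
                continue
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                elements.append((parts[1], int(parts[2]), []))
            elif parts[0] == "property":
                if not elements:
                    raise MeshParseError(f"{path}: property before element")
                if parts[1] == "list":
                    elements[-1][2].append((parts[4], parts[3], parts[2]))
                else:
                    elements[-1][2].append((parts[2], parts[1], None))
            elif parts[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian", "binary_big_endian"):
            raise MeshParseError(f"{path}: unknown PLY format {fmt!r}")
        if fmt == "ascii":
            data = fh.read().decode("ascii", "replace").split()
            return _parse_ply_elements_ascii(path, elements, data)
        endian = "<" if fmt == "binary_little_endian" else ">"
        return _parse_ply_elements_binary(path, elements, fh, endian)


def _finish_ply(path: Path, verts, faces) -> TriSurface:
    if verts is None:
        raise MeshParseError(f"{path}: no vertex element")
    faces = (np.array(faces, dtype=np.int64).reshape(-1, 3)
             if faces is not None else np.zeros((0, 3), dtype=np.int64))
    _check_faces(faces, len(verts), path)
    return TriSurface(np.asarray(verts, dtype=np.float64), faces)


def _parse_ply_elements_ascii(path, elements, data) -> TriSurface:
    pos = 0
    verts = faces = None
    for name, count, props in elements:
        if name == "vertex":
            names = [p[0] for p in props]
            rows = np.empty((count, 3))
            per = len(props)
            try:
                ix, iy, iz = names.index("x"), names.index("y"), names.index("z")
            except ValueError as exc:
                raise MeshParseError(f"{path}: vertex element lacks x/y/z") from exc
            block = data[pos:pos + count * per]
            if len(block) < count * per:
                raise MeshParseError(f"{path}: truncated vertex data")
            arr = np.array(block, dtype=np.float64).reshape(count, per)
            rows[:, 0], rows[:, 1], rows[:, 2] = arr[:, ix], arr[:, iy], arr[:, iz]
            verts = rows
            pos += count * per
        elif name == "face":
            faces = []
            for i in range(count):
                if pos >= len(data):
                    raise MeshParseError(f"{path}: truncated at face {i}")
                k = int(data[pos])
                if k != 3:
                    raise MeshParseError(
                        f"{path}: face {i} has {k} vertices; triangles only")
                faces.append([int(x) for x in data[pos + 1:pos + 4]])
                pos += 1 + k
        else:                                     # skip unknown element
            for _ in range(count):
                for _, _, list_dt in props:
                    if list_dt is not None:
                        k = int(data[pos]); pos += 1 + k
                    else:
                        pos += 1
    return _finish_ply(path, verts, faces)


def _parse_ply_elements_binary(path, elements, fh, endian) -> TriSurface:
    verts = faces = None
    for name, count, props in elements:
        if name == "vertex" and all(p[2] is None for p in props):
            dtype = np.dtype([(p[0], endian + _PLY_TYPES[p[1]]) for p in props])
            raw = fh.read(dtype.itemsize * count)
            if len(raw) < dtype.itemsize * count:
                raise MeshParseError(f"{path}: truncated vertex data")
            arr = np.frombuffer(raw, dtype=dtype)
            try:
                verts = np.column_stack([arr["x"], arr["y"], arr["z"]]
                                        ).astype(np.float64)
            except KeyError as exc:
                raise MeshParseError(f"{path}: vertex element lacks x/y/z") from exc
        elif name == "face":
            faces = []
            for i in range(count):
                row = []
                for _, item_t, list_t in props:
                    cdt = np.dtype(endian + _PLY_TYPES[list_t])
                    raw = fh.read(cdt.itemsize)
                    if len(raw) < cdt.itemsize:
                        raise MeshParseError(f"{path}: truncated at face {i}")
                    k = int(np.frombuffer(raw, cdt)[0])
                    idt = np.dtype(endian + _PLY_TYPES[item_t])
                    vals = np.frombuffer(fh.read(idt.itemsize * k), idt)
                    row.append(vals)
                idx = row[0]
                if len(idx) != 3:
                    raise MeshParseError(
                        f"{path}: face {i} has {len(idx)} vertices; triangles only")
                faces.append([int(x) for x in idx])
        else:
            for _ in range(count):
                for _, item_t, list_t in props:
                    if list_t is not None:
                        cdt = np.dtype(endian + _PLY_TYPES[list_t])
                        k = int(np.frombuffer(fh.read(cdt.itemsize), cdt)[0])
                        fh.read(np.dtype(_PLY_TYPES[item_t]).itemsize * k)
                    else:
                        fh.read(np.dtype(_PLY_TYPES[item_t]).itemsize)
    return _finish_ply(path, verts, faces)


def _write_ply(surface: TriSurface, path: Path, binary: bool,
               vertex_scalar: Optional[np.ndarray], scalar_name: str) -> None:
    nv, nf = surface.n_vertices, surface.n_faces
    has_scalar = vertex_scalar is not None
    if has_scalar and len(vertex_scalar) != nv:
        raise SurfaceError("vertex_scalar length must match vertex count")
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {nv}",
              "property double x", "property double y", "property double z"]
    if has_scalar:
        header.append(f"property double {scalar_name}")
    header += [f"element face {nf}",
               "property list uchar int vertex_indices", "end_header"]
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            cols = [surface.vertices]
            if has_scalar:
                cols.append(np.asarray(vertex_scalar, float).reshape(-1, 1))
            fh.write(np.hstack(cols).astype("<f8").tobytes())
            for f in surface.faces:
                fh.write(struct.pack("<BIII", 3, *[int(i) for i in f]))
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for i, v in enumerate(surface.vertices):
                row = f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}"
                if has_scalar:
                    row += f" {float(vertex_scalar[i])!r}"
                fh.write(row + "\n")
            for f in surface.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
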