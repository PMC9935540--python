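"""Mesh file I/O: Abaqus INP (C3D4 subset), Gmsh MSH v2.2 (tet subset),
and surface formats (STL/PLY/OFF) through trimesh.

On-disk INP and MSH node/element ids are 1-based; in memory everything is
0-based.  INP ``*NSET`` blocks populate ``TetMesh.node_sets``; a facet set
of the same name is derived as all boundary facets whose three nodes lie
in the set (the convention the writer inverts).
"""

from __future__ import annotations

import logging
import os
import warnings

import numpy as np

from .mesh import MeshError, TetMesh, boundary_facets_of, tet_volumes

log = logging.getLogger(__name__)

__all__ = ["read_mesh", "write_mesh", "FormatError"]


class FormatError(MeshError):
    """Raised when a file cannot be parsed as a supported mesh dialect."""


_SURFACE_EXT = {".stl", ".ply", ".off"}

# Gmsh v2.2 element type codes for the volumetric types we reject by name.
_MSH_TYPE_NAMES = {5: "hexahedron", 6: "prism", 7: "pyramid", 11: "quadratic tet"}


def read_mesh(path: str, format_hint: str | None = None) -> TetMesh:
    """Read a tetrahedral or surface mesh.

    Supported dialects: Abaqus INP with C3D4 elements, Gmsh MSH v2.2 with
    type-4 (tet) elements, and STL/PLY/OFF surfaces (which yield a
    surface-only mesh with empty ``tets``).
    """
    fmt = (format_hint or os.path.splitext(path)[1].lstrip(".")).lower()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "inp":
        mesh = _read_inp(path)
    elif fmt == "msh":
        mesh = _read_msh(path)
    elif "." + fmt in _SURFACE_EXT:
        mesh = _read_surface(path)
    else:
        raise FormatError(f"unsupported mesh format {fmt!r} for {path}")
    mesh.provenance = mesh.provenance or f"read from {path}"
    if not mesh.is_surface_only():
        mesh.validate()
    return mesh


def write_mesh(mesh: TetMesh, path: str, format_hint: str | None = None) -> None:
    fmt = (format_hint or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt == "inp":
        _write_inp(mesh, path)
    elif fmt == "msh":
        _write_msh(mesh, path)
    elif "." + fmt in _SURFACE_EXT:
        _write_surface(mesh, path, fmt)
    else:
        raise FormatError(f"unsupported mesh format {fmt!r} for {path}")


# ---------------------------------------------------------------------------
# Abaqus INP subset


def _finalize_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Reject degenerate tets; repair inverted ones by a vertex swap."""
    if len(tets) == 0:
        return tets
    vols = tet_volumes(nodes, tets)
    scale = np.abs(nodes).max() or 1.0
    degenerate = np.abs(vols) <= 1e-12 * scale**3
    if np.any(degenerate):
        raise MeshError(
            f"{int(degenerate.sum())} zero-volume tetrahedra; refusing to repair"
        )
    inverted = vols < 0
    if np.any(inverted):
        log.warning("repaired %d inverted tetrahedra by vertex swap", int(inverted.sum()))
        tets = tets.copy()
        tets[inverted] = tets[inverted][:, [0, 2, 1, 3]]
    return tets


def _read_inp(path: str) -> TetMesh:
    node_ids: list[int] = []
    coords: list[list[float]] = []
    elems: list[list[int]] = []
    nsets: dict[str, list[int]] = {}
    section = None
    current_set: list[int] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                head = [p.strip() for p in line.split(",")]
                keyword = head[0].upper()
                params = {
                    k.strip().upper(): v.strip()
                    for k, _, v in (p.partition("=") for p in head[1:])
                }
                if keyword == "*NODE":
                    section = "node"
                elif keyword == "*ELEMENT":
                    etype = params.get("TYPE", "").upper()
                    if etype != "C3D4":
                        raise FormatError(
                            f"unsupported element type {etype or '<missing>'}; "
                            "only C3D4 tetrahedra are supported"
                        )
                    section = "element"
                elif keyword == "*NSET":
                    name = params.get("NSET", "").lower()
                    if not name:
                        raise FormatError("*NSET without NSET= name")
                    current_set = nsets.setdefault(name, [])
                    section = "nset"
                else:
                    section = None
                continue
            parts = [p for p in (q.strip() for q in line.split(",")) if p]
            if section == "node":
                node_ids.append(int(parts[0]))
                coords.append([float(x) for x in parts[1:4]])
            elif section == "element":
                if len(parts) != 5:
                    raise FormatError(f"C3D4 element line with {len(parts)} fields")
                elems.append([int(x) for x in parts])
            elif section == "nset" and current_set is not None:
                current_set.extend(int(x) for x in parts)

    if not node_ids:
        raise FormatError(f"no *NODE block found in {path}")
    remap = {nid: i for i, nid in enumerate(node_ids)}
    nodes = np.asarray(coords, dtype=np.float64)
    tets = np.asarray(
        [[remap[n] for n in e[1:]] for e in elems], dtype=np.int64
    ).reshape(-1, 4)
    tets = _finalize_tets(nodes, tets)
    boundary = boundary_facets_of(tets)
    node_sets = {
        name: np.asarray(sorted(remap[i] for i in ids), dtype=np.int64)
        for name, ids in nsets.items()
    }
    facet_sets = _derive_facet_sets(boundary, node_sets)
    return TetMesh(nodes, tets, boundary, node_sets, facet_sets, provenance=path)


def _derive_facet_sets(
    boundary: np.ndarray, node_sets: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    facet_sets = {}
    for name, ids in node_sets.items():
        member = np.zeros(0, dtype=bool)
        if len(boundary):
            inset = np.isin(boundary, ids)
            member = inset.all(axis=1)
        idx = np.nonzero(member)[0]
        if len(idx):
            facet_sets[name] = idx
    return facet_sets


def _write_inp(mesh: TetMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.node_coords, start=1):
            fh.write(f"{i}, {float(x)!r}, {float(y)!r}, {float(z)!r}\n")
        if mesh.n_tets:
            fh.write("*ELEMENT, TYPE=C3D4\n")
            for i, t in enumerate(mesh.tets + 1, start=1):
                fh.write(f"{i}, {t[0]}, {t[1]}, {t[2]}, {t[3]}\n")
        written: dict[str, np.ndarray] = {}
        for name, ids in mesh.node_sets.items():
            written[name] = np.asarray(ids)
        for name, fidx in mesh.facet_sets.items():
            if name not in written:
                written[name] = np.unique(mesh.boundary_facets[fidx])
        for name, ids in written.items():
            fh.write(f"*NSET, NSET={name}\n")
            ids1 = np.sort(np.asarray(ids)) + 1
            for start in range(0, len(ids1), 10):
                fh.write(", ".join(str(i) for i in ids1[start : start + 10]) + "\n")


# ---------------------------------------------------------------------------
# Gmsh MSH v2.2 subset


def _read_msh(path: str) -> TetMesh:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    try:
        i = lines.index("$Nodes")
        n = int(lines[i + 1])
        node_ids, coords = [], []
        for ln in lines[i + 2 : i + 2 + n]:
            parts = ln.split()
            node_ids.append(int(parts[0]))
            coords.append([float(x) for x in parts[1:4]])
        j = lines.index("$Elements")
        m = int(lines[j + 1])
        elem_lines = lines[j + 2 : j + 2 + m]
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed MSH v2.2 file {path}: {exc}") from exc
    remap = {nid: k for k, nid in enumerate(node_ids)}
    tets = []
    for ln in elem_lines:
        parts = [int(x) for x in ln.split()]
        etype, ntags = parts[1], parts[2]
        conn = parts[3 + ntags :]
        if etype == 4:
            tets.append([remap[c] for c in conn])
        elif etype in _MSH_TYPE_NAMES:
            raise FormatError(
                f"unsupported element type {_MSH_TYPE_NAMES[etype]} (code {etype})"
            )
        # points/lines/triangles silently ignored
    nodes = np.asarray(coords, dtype=np.float64)
    tets_arr = _finalize_tets(nodes, np.asarray(tets, dtype=np.int64).reshape(-1, 4))
    return TetMesh(nodes, tets_arr, boundary_facets_of(tets_arr), provenance=path)


def _write_msh(mesh: TetMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
        fh.write(f"{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.node_coords, start=1):
            fh.write(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}\n")
        fh.write("$EndNodes\n$Elements\n")
        fh.write(f"{mesh.n_tets}\n")
        for i, t in enumerate(mesh.tets + 1, start=1):
            fh.write(f"{i} 4 2 0 0 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write("$EndElements\n")


# ---------------------------------------------------------------------------
# Surface formats via trimesh


def _read_surface(path: str) -> TetMesh:
    import trimesh

    tm = trimesh.load(path, force="mesh", process=False)
    tm.merge_vertices()  # STL stores vertices per facet
    nodes = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if faces.shape[1] != 3:
        raise FormatError("surface mesh is not triangular")
    mesh = TetMesh(nodes, np.empty((0, 4), dtype=np.int64), faces, provenance=path)
    if not mesh.is_closed():
        warnings.warn(f"surface mesh {path} is not watertight", stacklevel=2)
    return mesh


def _write_surface(mesh: TetMesh, path: str, fmt: str) -> None:
    import trimesh

    tm = trimesh.Trimesh(
        vertices=mesh.node_coords, faces=mesh.boundary_facets, process=False
    )
    tm.export(path, file_type=fmt)
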