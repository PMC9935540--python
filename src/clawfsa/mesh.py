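"""Tetrahedral and surface claw meshes: containers, measurement, scaling.

The local claw frame is fixed throughout the package: +x proximodistal
(distal positive), +z dorsoventral (dorsal positive), +y mediolateral.
Units are mm; derived areas are mm^2, volumes mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TetMesh",
    "ClawMeasurements",
    "MeshError",
    "measure_claw",
    "scale_to_surface_area",
    "boundary_facets_of",
    "tet_volumes",
    "facet_areas",
    "facet_normals",
]


class MeshError(ValueError):
    """Raised for invalid, degenerate or inconsistent mesh data."""


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra under the stored node ordering."""
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def facet_areas(nodes: np.ndarray, facets: np.ndarray) -> np.ndarray:
    a, b, c = (nodes[facets[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def facet_normals(nodes: np.ndarray, facets: np.ndarray) -> np.ndarray:
    """Unit normals following the facet winding (outward for boundary facets)."""
    a, b, c = (nodes[facets[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0.0] = 1.0
    return n / norm


def boundary_facets_of(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary facets of a tet mesh.

    A facet is on the boundary iff it belongs to exactly one tet. For a
    positively oriented tet (a, b, c, d) the four outward-wound faces are
    (a, c, b), (a, b, d), (b, c, d), (a, d, c).
    """
    if len(tets) == 0:
        return np.empty((0, 3), dtype=np.int64)
    faces = np.concatenate(
        [
            tets[:, [0, 2, 1]],
            tets[:, [0, 1, 3]],
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    return np.ascontiguousarray(faces[counts[inverse] == 1])


@dataclass
class TetMesh:
    """A claw mesh: nodes, tets, oriented boundary and named regions.

    ``node_sets`` index nodes (e.g. "articular", "tip"); ``facet_sets``
    index rows of ``boundary_facets`` (e.g. "ventral").  ``node_u`` is an
    optional per-node axial parametric coordinate in [0, 1] (0 proximal,
    1 distal) carried by generated claws and used to resolve the tip.
    """

    node_coords: np.ndarray
    tets: np.ndarray
    boundary_facets: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_u: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=np.float64).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.boundary_facets = np.asarray(
            self.boundary_facets, dtype=np.int64
        ).reshape(-1, 3)
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}
        self.facet_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.facet_sets.items()}
        if self.node_u is not None:
            self.node_u = np.asarray(self.node_u, dtype=np.float64)

    # -- basic quantities ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        return tet_volumes(self.node_coords, self.tets)

    def surface_area(self) -> float:
        return float(facet_areas(self.node_coords, self.boundary_facets).sum())

    def volume_divergence(self) -> float:
        """Enclosed volume via the divergence theorem over oriented facets."""
        a, b, c = (self.node_coords[self.boundary_facets[:, i]] for i in range(3))
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def is_surface_only(self) -> bool:
        return self.n_tets == 0

    def is_closed(self) -> bool:
        """Every boundary edge shared by exactly two boundary facets."""
        if len(self.boundary_facets) == 0:
            return False
        edges = np.concatenate(
            [self.boundary_facets[:, [0, 1]], self.boundary_facets[:, [1, 2]],
             self.boundary_facets[:, [2, 0]]]
        )
        key = np.sort(edges, axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    # -- invariants ---------------------------------------------------------

    def validate(self, require_articular: bool = False) -> None:
        """Check the structural invariants; raise :class:`MeshError` on failure."""
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= self.n_nodes):
            raise MeshError("tet connectivity references nonexistent nodes")
        if self.boundary_facets.size and (
            self.boundary_facets.min() < 0 or self.boundary_facets.max() >= self.n_nodes
        ):
            raise MeshError("boundary facets reference nonexistent nodes")
        if self.n_tets:
            vols = self.tet_volumes()
            if np.any(vols <= 0.0):
                bad = int(np.argmin(vols))
                raise MeshError(
                    f"tet {bad} has non-positive signed volume {vols[bad]:.3e}"
                )
            derived = boundary_facets_of(self.tets)
            if not _same_facet_set(derived, self.boundary_facets):
                raise MeshError("stored boundary facets do not tile the tet-mesh boundary")
        for name, idx in self.node_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise MeshError(f"node set {name!r} references nonexistent nodes")
        for name, idx in self.facet_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.boundary_facets)):
                raise MeshError(f"facet set {name!r} references nonexistent facets")
        if require_articular and len(self.node_sets.get("articular", ())) == 0:
            raise MeshError('node set "articular" is empty; required before an FE solve')

    def copy(self) -> "TetMesh":
        return replace(
            self,
            node_coords=self.node_coords.copy(),
            tets=self.tets.copy(),
            boundary_facets=self.boundary_facets.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            facet_sets={k: v.copy() for k, v in self.facet_sets.items()},
            node_u=None if self.node_u is None else self.node_u.copy(),
        )


def _same_facet_set(a: np.ndarray, b: np.ndarray) -> bool:
    if len(a) != len(b):
        return False
    ka = np.sort(np.sort(a, axis=1), axis=0)
    kb = np.sort(np.sort(b, axis=1), axis=0)
    return bool(np.array_equal(ka, kb))


@dataclass(frozen=True)
class ClawMeasurements:
    """Linear claw measurements and their ratios.

    L, D, W are extents along the mesh's principal axes: L along the first
    principal axis of the node scatter, D along the remaining axis closest
    to local +z (dorsoventral), W along the last.  For curved claws L is a
    chord-like extent, not arc length.
    """

    length_mm: float
    depth_mm: float
    width_mm: float
    ratio_LW: float
    ratio_LD: float
    ratio_DW: float
    surface_area_mm2: float
    volume_mm3: float | None

    @classmethod
    def from_ldw(
        cls, L: float, D: float, W: float, area: float, volume: float | None
    ) -> "ClawMeasurements":
        if min(L, D, W) <= 0 or area <= 0:
            raise MeshError("claw measurements must be strictly positive")
        return cls(L, D, W, L / W, L / D, D / W, area, volume)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "length_mm": self.length_mm,
            "depth_mm": self.depth_mm,
            "width_mm": self.width_mm,
            "ratio_LW": self.ratio_LW,
            "ratio_LD": self.ratio_LD,
            "ratio_DW": self.ratio_DW,
            "surface_area_mm2": self.surface_area_mm2,
            "volume_mm3": self.volume_mm3,
        }


def principal_axes(points: np.ndarray) -> np.ndarray:
    """Principal axes of a point scatter, rows ordered by decreasing variance.

    Signs are fixed deterministically: each axis is flipped so that its
    component of largest magnitude is positive.
    """
    centered = points - points.mean(axis=0)
    cov = centered.T @ cov_weight(centered)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return axes


def cov_weight(centered: np.ndarray) -> np.ndarray:
    return centered / max(len(centered) - 1, 1)


def measure_claw(mesh: TetMesh, base_fraction: float = 0.1) -> ClawMeasurements:
    """Measure length, depth, width, ratios, surface area and volume.

    L is the extent along the first principal axis of the node scatter (a
    chord-like extent for curved claws).  D and W are measured at the claw
    base, in the basal cross-section's own plane, following standard claw
    morphometrics (ungual depth and width at the articular facet); this
    keeps the ratios immune to centerline-curvature sagitta, which would
    otherwise inflate the depth of strongly curved claws.  The basal
    region is the "articular" node set when present, else the end slab
    spanning ``base_fraction`` of the axial span at whichever end has the
    larger cross-section (claws taper distally).  D is the in-plane axis
    closest to local +z (dorsoventral); ties break toward +z.

    Volume uses the divergence theorem over the oriented boundary; for an
    open surface mesh the volume is reported as ``None`` with a warning.
    """
    pts = mesh.node_coords
    if len(pts) < 4:
        raise MeshError("mesh has too few nodes to measure")
    axes = principal_axes(pts)
    t = pts @ axes[0]
    tmin, tmax = float(t.min()), float(t.max())
    L = tmax - tmin

    articular = mesh.node_sets.get("articular")
    if articular is not None and len(articular) >= 3:
        cap = pts[articular]
    else:
        span = base_fraction * L
        best_cap, best_score = None, -1.0
        for slab_mask in (t <= tmin + span, t >= tmax - span):
            slab = pts[slab_mask]
            ext = np.ptp(slab @ axes[1:].T, axis=0)
            if ext[0] * ext[1] > best_score:
                best_cap, best_score = slab, float(ext[0] * ext[1])
        cap = best_cap
    # in-plane axes of the basal cross-section: its two largest principal axes
    cap_axes = principal_axes(cap)[:2]
    extents = np.ptp(cap @ cap_axes.T, axis=0)
    # D is the in-plane axis closest to local +z; ties broken toward +z.
    z_align = np.abs(cap_axes[:, 2])
    if np.isclose(z_align[0], z_align[1]):
        d_idx = 0 if cap_axes[0, 2] >= cap_axes[1, 2] else 1
    else:
        d_idx = int(np.argmax(z_align))
    w_idx = 1 - d_idx
    D, W = float(extents[d_idx]), float(extents[w_idx])

    area = mesh.surface_area()
    if mesh.is_closed():
        volume: float | None = abs(mesh.volume_divergence())
    else:
        warnings.warn(
            "open surface: claw volume unavailable, ratios still computed",
            stacklevel=2,
        )
        volume = None
    return ClawMeasurements.from_ldw(L, D, W, area, volume)


def scale_to_surface_area(mesh: TetMesh, target_area_mm2: float) -> TetMesh:
    """Uniformly scale the mesh about its centroid to a target surface area.

    The scale factor is s = sqrt(target / current); volumes scale by s^3.
    """
    if target_area_mm2 <= 0:
        raise ValueError("target surface area must be positive")
    current = mesh.surface_area()
    if current <= 0:
        raise MeshError("mesh surface area is not positive; cannot scale")
    s = float(np.sqrt(target_area_mm2 / current))
    centroid = mesh.node_coords.mean(axis=0)
    out = mesh.copy()
    out.node_coords = centroid + s * (mesh.node_coords - centroid)
    return out
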