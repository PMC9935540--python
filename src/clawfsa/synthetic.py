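"""Synthetic claw geometries and stress fields with known ground truth.

The claw generator sweeps a solid elliptical cross-section along a circular
arc, tapering toward the tip, and tetrahedralizes the resulting structured
hexahedral lattice.  Stress fields are drawn i.i.d. per element from a
chosen distribution family so that distributional ground truth (e.g. the
volume-weighted mean) is exact; spatially realistic fields come from the FE
solver instead.

Cross-sections are meshed by mapping a square grid onto the ellipse with
the standard square-to-disk map x = p*sqrt(1-q^2/2), y = q*sqrt(1-p^2/2),
whose boundary points lie exactly on the ellipse.  Hexahedra are split into
six tetrahedra with the uniform Freudenthal (Kuhn) template, which is
conforming on structured grids; the tip is closed by a pyramid fan to an
apex node on the centerline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping

import numpy as np

from .fe import SCENARIOS, StressField
from .mesh import MeshError, TetMesh, boundary_facets_of, tet_volumes

__all__ = [
    "ClawParams",
    "StressSimParams",
    "GradientSpec",
    "Cohort",
    "generate_claw_mesh",
    "generate_stress_field",
    "make_benchmark_cohort",
    "box_mesh",
    "GenerationError",
]


class GenerationError(ValueError):
    """Raised when generator parameters produce an invalid geometry."""


# six-tet Freudenthal split of the unit cube: corner paths (0,0,0)->(1,1,1)
_KUHN_PATHS: list[list[tuple[int, int, int]]] = []
for _perm in permutations(range(3)):
    _cur = [0, 0, 0]
    _corners = [tuple(_cur)]
    for _ax in _perm:
        _cur[_ax] = 1
        _corners.append(tuple(_cur))
    _KUHN_PATHS.append(_corners)


def _split_hex_lattice(index_of, shape) -> np.ndarray:
    """Tets of a structured hex lattice of `shape` cells.

    ``index_of(a, b, c)`` maps lattice node coordinates to global node ids.
    """
    na, nb, nc = shape
    tets = []
    for a in range(na):
        for b in range(nb):
            for c in range(nc):
                for corners in _KUHN_PATHS:
                    tets.append(
                        [index_of(a + da, b + db, c + dc) for (da, db, dc) in corners]
                    )
    return np.asarray(tets, dtype=np.int64)


def _orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vols = tet_volumes(nodes, tets)
    scale = float(np.abs(nodes).max() or 1.0)
    if np.any(np.abs(vols) <= 1e-14 * scale**3):
        raise GenerationError("generated lattice contains degenerate tetrahedra")
    flipped = vols < 0
    if np.any(flipped):
        tets = tets.copy()
        tets[flipped] = tets[flipped][:, [0, 2, 1, 3]]
    return tets


def box_mesh(
    lx: float,
    ly: float,
    lz: float,
    nx: int,
    ny: int,
    nz: int,
    split: str = "kuhn6",
) -> TetMesh:
    """Axis-aligned box [0,lx]x[0,ly]x[0,lz] as a tetrahedralized hex lattice.

    ``split="kuhn6"`` uses the uniform Freudenthal 6-tet template (cheap,
    directionally biased); ``split="sym24"`` adds face- and body-center
    nodes and splits each hex into 24 symmetric tets, which is markedly
    softer in bending and is used by the cantilever validation benchmark.
    """
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(0.0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    corner_nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def index_of(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    if split == "kuhn6":
        nodes = corner_nodes
        tets = _split_hex_lattice(index_of, (nx, ny, nz))
    elif split == "sym24":
        nodes, tets = _sym24_lattice(corner_nodes, index_of, (nx, ny, nz))
    else:
        raise ValueError(f"unknown hex split {split!r}; use 'kuhn6' or 'sym24'")
    tets = _orient_tets(nodes, tets)
    return TetMesh(nodes, tets, boundary_facets_of(tets), provenance=f"box_mesh({split})")


_HEX_CORNERS = [
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
]
_HEX_FACES = [
    (0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
    (3, 2, 6, 7), (0, 3, 7, 4), (1, 2, 6, 5),
]


def _sym24_lattice(corner_nodes, index_of, shape):
    """24 tets per hex via shared face centers and a body center."""
    na, nb, nc = shape
    extra: dict[tuple, int] = {}
    extra_pts: list[np.ndarray] = []

    def center(ids):
        key = tuple(sorted(ids))
        if key not in extra:
            extra[key] = len(corner_nodes) + len(extra)
            extra_pts.append(corner_nodes[list(key)].mean(axis=0))
        return extra[key]

    tets = []
    for a in range(na):
        for b in range(nb):
            for c in range(nc):
                ids = [index_of(a + da, b + db, c + dc) for da, db, dc in _HEX_CORNERS]
                cc = center(ids)
                for f in _HEX_FACES:
                    fids = [ids[v] for v in f]
                    fc = center(fids)
                    for e in range(4):
                        tets.append([fids[e], fids[(e + 1) % 4], fc, cc])
    nodes = np.concatenate([corner_nodes, np.asarray(extra_pts)])
    return nodes, np.asarray(tets, dtype=np.int64)


# ---------------------------------------------------------------------------
# Parametric claw


@dataclass(frozen=True)
class ClawParams:
    """Parameters of a synthetic claw.

    ``length_mm`` is the centerline arc length.  When ``centerline_arc_deg``
    > 0 and ``centerline_radius_mm`` is given, the length is derived as
    radius x arc instead.  ``circumferential_segments`` is the cross-section
    grid resolution per square side (the section boundary then has 4x that
    many segments).  The cross-section tapers as (1-u)^taper_exponent and
    closes to an apex at the tip.
    """

    length_mm: float = 50.0
    centerline_arc_deg: float = 60.0
    centerline_radius_mm: float | None = None
    base_depth_mm: float = 12.0
    base_width_mm: float = 8.0
    taper_exponent: float = 1.0
    axial_segments: int = 16
    circumferential_segments: int = 8
    seed: int = 0
    noise_amplitude_mm: float = 0.0

    def validate(self) -> None:
        if self.axial_segments < 4 or self.circumferential_segments < 4:
            raise GenerationError("axial and circumferential segments must be >= 4")
        if min(self.length_mm, self.base_depth_mm, self.base_width_mm) <= 0:
            raise GenerationError("claw dimensions must be positive")
        if self.taper_exponent <= 0:
            raise GenerationError("taper_exponent must be positive")
        if not (0.0 <= self.centerline_arc_deg < 180.0):
            raise GenerationError("centerline arc must lie in [0, 180) degrees")
        if self.noise_amplitude_mm < 0:
            raise GenerationError("noise amplitude must be non-negative")

    @property
    def arc_rad(self) -> float:
        return float(np.radians(self.centerline_arc_deg))

    @property
    def radius_mm(self) -> float | None:
        if self.arc_rad == 0.0:
            return None
        if self.centerline_radius_mm is not None:
            return float(self.centerline_radius_mm)
        return self.length_mm / self.arc_rad

    @property
    def arc_length_mm(self) -> float:
        r = self.radius_mm
        return self.length_mm if r is None else r * self.arc_rad


def _centerline_frame(params: ClawParams, u: np.ndarray):
    """Centerline point, tangent and dorsal normal at axial coordinate u.

    The claw curves ventrally: the centerline is a circular arc in the x-z
    plane starting at the origin with tangent +x, center of curvature at
    (0, 0, -R).  The dorsal normal points away from the center of curvature.
    """
    u = np.atleast_1d(np.asarray(u, dtype=np.float64))
    r = params.radius_mm
    if r is None:
        c = np.column_stack([u * params.arc_length_mm, 0 * u, 0 * u])
        t = np.tile([1.0, 0.0, 0.0], (len(u), 1))
        n = np.tile([0.0, 0.0, 1.0], (len(u), 1))
        return c, t, n
    phi = u * params.arc_rad
    c = np.column_stack([r * np.sin(phi), 0 * u, r * (np.cos(phi) - 1.0)])
    t = np.column_stack([np.cos(phi), 0 * phi, -np.sin(phi)])
    n = np.column_stack([np.sin(phi), 0 * phi, np.cos(phi)])
    return c, t, n


def generate_claw_mesh(params: ClawParams) -> TetMesh:
    """Generate a watertight tetrahedral claw mesh from sweep parameters.

    Region sets follow the package conventions: ``articular`` = nodes of
    the proximal cap section, ``ventral`` = boundary facets whose outward
    normal points against the local dorsal direction, ``tip`` = nodes with
    axial parameter u >= 0.95.  The axial parameter is retained on
    ``node_u``.
    """
    params.validate()
    r = params.radius_mm
    if r is not None and params.base_depth_mm / 2.0 >= 0.95 * r:
        raise GenerationError(
            f"arc too tight: base half-depth {params.base_depth_mm / 2.0:.3g} mm "
            f"must be < 0.95 x centerline radius {r:.3g} mm"
        )
    na, nc = params.axial_segments, params.circumferential_segments
    side = np.linspace(-1.0, 1.0, nc + 1)
    P, Q = np.meshgrid(side, side, indexing="ij")
    SX = (P * np.sqrt(1.0 - Q**2 / 2.0)).ravel()
    SY = (Q * np.sqrt(1.0 - P**2 / 2.0)).ravel()
    rng = np.random.default_rng(params.seed)

    u_sections = np.arange(na) / na
    c, _, n_dorsal = _centerline_frame(params, u_sections)
    e_w = np.array([0.0, 1.0, 0.0])

    nodes = []
    node_u = []
    for k, u in enumerate(u_sections):
        scale = (1.0 - u) ** params.taper_exponent
        w = params.base_width_mm / 2.0 * scale
        d = params.base_depth_mm / 2.0 * scale
        if params.noise_amplitude_mm > 0.0:
            w = max(w + rng.uniform(-1, 1) * params.noise_amplitude_mm, 0.1 * w)
            d = max(d + rng.uniform(-1, 1) * params.noise_amplitude_mm, 0.1 * d)
        sec = c[k] + np.outer(SX * w, e_w) + np.outer(SY * d, n_dorsal[k])
        nodes.append(sec)
        node_u.append(np.full(len(sec), u))
    apex, _, _ = _centerline_frame(params, np.array([1.0]))
    nodes.append(apex)
    node_u.append(np.array([1.0]))
    nodes = np.concatenate(nodes)
    node_u = np.concatenate(node_u)

    nps = (nc + 1) ** 2  # nodes per section

    def index_of(k, i, j):
        return k * nps + i * (nc + 1) + j

    tets = _split_hex_lattice(
        lambda a, b, c_: index_of(a, b, c_), (na - 1, nc, nc)
    )
    # tip cone: pyramid fan from the last section's quads to the apex node
    apex_id = len(nodes) - 1
    cone = []
    k = na - 1
    for i in range(nc):
        for j in range(nc):
            a = index_of(k, i, j)
            b = index_of(k, i + 1, j)
            cc = index_of(k, i + 1, j + 1)
            d = index_of(k, i, j + 1)
            cone.append([a, b, cc, apex_id])
            cone.append([a, cc, d, apex_id])
    tets = np.concatenate([tets, np.asarray(cone, dtype=np.int64)])
    tets = _orient_tets(nodes, tets)
    boundary = boundary_facets_of(tets)

    articular = np.arange(nps, dtype=np.int64)
    tip_nodes = np.nonzero(node_u >= 0.95)[0].astype(np.int64)
    facet_u = node_u[boundary].mean(axis=1)
    _, _, facet_dorsal = _centerline_frame(params, np.clip(facet_u, 0.0, 1.0))
    from .mesh import facet_normals

    normals = facet_normals(nodes, boundary)
    is_cap = np.all(node_u[boundary] == 0.0, axis=1)
    ventral = np.nonzero(
        (np.einsum("ij,ij->i", normals, facet_dorsal) < -1e-9) & ~is_cap
    )[0].astype(np.int64)

    mesh = TetMesh(
        nodes,
        tets,
        boundary,
        node_sets={"articular": articular, "tip": tip_nodes},
        facet_sets={"ventral": ventral},
        node_u=node_u,
        provenance=f"generate_claw_mesh(seed={params.seed})",
    )
    mesh.validate(require_articular=True)
    return mesh


# ---------------------------------------------------------------------------
# Stress-field simulation


@dataclass(frozen=True)
class StressSimParams:
    """Distribution family and per-scenario parameters for simulated fields.

    ``scenario_params`` maps scenario name to the family parameters:
    lognormal -> (mu, sigma) of the underlying normal; gamma -> (shape,
    scale); constant -> (value, ignored).
    """

    family: str = "lognormal"
    scenario_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {s: (1.0, 0.5) for s in SCENARIOS}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("lognormal", "gamma", "constant"):
            raise ValueError(f"unknown stress distribution family {self.family!r}")
        for s, (a, b) in self.scenario_params.items():
            if self.family in ("lognormal", "gamma") and b <= 0:
                raise ValueError(f"scale/sigma for scenario {s!r} must be positive")

    def expected_mean(self, scenario: str) -> float:
        """Exact mean stress of the family for a scenario (ground truth)."""
        a, b = self.scenario_params[scenario]
        if self.family == "lognormal":
            return float(np.exp(a + b**2 / 2.0))
        if self.family == "gamma":
            return float(a * b)
        return float(a)


def generate_stress_field(
    mesh: TetMesh, params: StressSimParams, scenario: str, specimen_id: str = "synthetic"
) -> StressField:
    """Draw an i.i.d. per-element von Mises field on a mesh, seeded."""
    params.validate()
    if scenario not in params.scenario_params:
        raise ValueError(f"no distribution parameters for scenario {scenario!r}")
    vols = mesh.tet_volumes()
    if np.any(vols <= 0):
        raise MeshError("mesh has non-positive tet volumes")
    rng = np.random.default_rng([params.seed, SCENARIOS.index(scenario)])
    a, b = params.scenario_params[scenario]
    n = len(vols)
    if params.family == "lognormal":
        vm = rng.lognormal(mean=a, sigma=b, size=n)
    elif params.family == "gamma":
        vm = rng.gamma(shape=a, scale=b, size=n)
    else:
        vm = np.full(n, float(a))
    return StressField(
        element_vm_mpa=vm,
        element_volume_mm3=vols,
        scenario=scenario,
        specimen_id=specimen_id,
    )


# ---------------------------------------------------------------------------
# Benchmark cohorts


@dataclass(frozen=True)
class GradientSpec:
    """Ground-truth gradients a benchmark cohort spans.

    Specimens are ordered along the gradients: depth/width ratio, arc, and
    base stress scale all vary linearly from the first to the last specimen
    (so base stress is monotone in D/W by construction when both ranges are
    non-constant).  Scenario mean stresses are base x multiplier, realised
    as lognormal fields with the given sigma.
    """

    dw_range: tuple[float, float] = (1.0, 2.5)
    arc_range_deg: tuple[float, float] = (30.0, 90.0)
    base_stress_range_mpa: tuple[float, float] = (8.0, 8.0)
    scenario_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "scratch_digging": 1.0,
            "hook_and_pull": 1.0,
            "piercing": 1.0,
        }
    )
    sigma: float = 0.5
    base_width_mm: float = 8.0
    length_mm: float = 50.0
    axial_segments: int = 12
    circumferential_segments: int = 6


@dataclass
class Cohort:
    """A generated cohort: per-specimen meshes, fields and the manifest."""

    specimen_ids: list[str]
    meshes: dict[str, TetMesh]
    fields: dict[tuple[str, str], StressField]
    manifest: dict

    def resample_fields(self, seed: int, sigma: float = 0.5) -> dict[tuple[str, str], StressField]:
        """Fresh i.i.d. stress fields from the manifest's ground-truth means.

        Used by recovery experiments that replicate the stochastic part of
        the pipeline on fixed geometry.
        """
        out: dict[tuple[str, str], StressField] = {}
        for i, sid in enumerate(self.specimen_ids):
            truth = self.manifest["specimens"][sid]["scenario_mean_stress_mpa"]
            sp = StressSimParams(
                family="lognormal",
                scenario_params={
                    s: (float(np.log(m) - sigma**2 / 2.0), sigma)
                    for s, m in truth.items()
                },
                seed=int(np.random.default_rng([seed, i, 11]).integers(2**31)),
            )
            for s in SCENARIOS:
                out[(sid, s)] = generate_stress_field(self.meshes[sid], sp, s, sid)
        return out


def make_benchmark_cohort(
    n_specimens: int, gradient: GradientSpec | None = None, seed: int = 0
) -> Cohort:
    """Generate a claw cohort spanning stated shape and stress gradients.

    The manifest records all ground truth (claw parameters, exact scenario
    mean stresses) for recovery tests.
    """
    if n_specimens < 3:
        raise ValueError("a cohort needs at least 3 specimens")
    g = gradient or GradientSpec()
    frac = (
        np.zeros(1) if n_specimens == 1 else np.linspace(0.0, 1.0, n_specimens)
    )
    ids = [f"claw{i:02d}" for i in range(n_specimens)]
    meshes: dict[str, TetMesh] = {}
    fields: dict[tuple[str, str], StressField] = {}
    manifest: dict = {"seed": seed, "n_specimens": n_specimens, "specimens": {}}
    for i, sid in enumerate(ids):
        f = float(frac[i])
        dw = g.dw_range[0] + f * (g.dw_range[1] - g.dw_range[0])
        arc = g.arc_range_deg[0] + f * (g.arc_range_deg[1] - g.arc_range_deg[0])
        base = g.base_stress_range_mpa[0] + f * (
            g.base_stress_range_mpa[1] - g.base_stress_range_mpa[0]
        )
        cp = ClawParams(
            length_mm=g.length_mm,
            centerline_arc_deg=arc,
            base_depth_mm=g.base_width_mm * dw,
            base_width_mm=g.base_width_mm,
            axial_segments=g.axial_segments,
            circumferential_segments=g.circumferential_segments,
            seed=int(np.random.default_rng([seed, i]).integers(2**31)),
        )
        meshes[sid] = generate_claw_mesh(cp)
        scen_params = {}
        truth_means = {}
        for s in SCENARIOS:
            mean = base * float(g.scenario_multipliers.get(s, 1.0))
            mu = float(np.log(mean) - g.sigma**2 / 2.0)
            scen_params[s] = (mu, g.sigma)
            truth_means[s] = mean
        sp = StressSimParams(
            family="lognormal",
            scenario_params=scen_params,
            seed=int(np.random.default_rng([seed, i, 7]).integers(2**31)),
        )
        for s in SCENARIOS:
            fields[(sid, s)] = generate_stress_field(meshes[sid], sp, s, sid)
        manifest["specimens"][sid] = {
            "dw": dw,
            "arc_deg": arc,
            "base_stress_mpa": base,
            "scenario_mean_stress_mpa": truth_means,
            "claw_params": {
                "length_mm": cp.length_mm,
                "centerline_arc_deg": cp.centerline_arc_deg,
                "base_depth_mm": cp.base_depth_mm,
                "base_width_mm": cp.base_width_mm,
                "seed": cp.seed,
            },
        }
    manifest["scenario_multipliers"] = dict(g.scenario_multipliers)
    return Cohort(ids, meshes, fields, manifest)
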