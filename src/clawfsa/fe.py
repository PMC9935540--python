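"""Linear elastic small-strain FE on tetrahedral meshes.

Constant-strain 4-node tetrahedra, isotropic homogeneous material, direct
sparse factorization.  Units: mm / N / MPa (Young's modulus entered in GPa
is converted x1000).  Three standardized claw load scenarios are provided:

* ``scratch_digging`` — total force on the ventral facets of the ungual
  tip, along inward (dorsal-pointing) facet normals (substrate reaction);
* ``hook_and_pull`` — total force spread over all ventral facets in
  proportion to facet area, inward normals;
* ``piercing`` — total force on the tip nodes directed proximally along
  the distal tangent of the claw axis.

In every scenario the articular nodes are fixed in all translations and
the resultant applied force has exactly the requested magnitude
(200 N by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import MeshError, TetMesh, facet_areas, facet_normals

log = logging.getLogger(__name__)

__all__ = [
    "SCENARIOS",
    "MaterialSpec",
    "LoadScenario",
    "StressField",
    "FESolution",
    "ConfigurationError",
    "SolverError",
    "assign_scenario_loads",
    "solve",
    "solve_linear_elastic",
    "von_mises",
    "uniform_traction_loads",
    "read_stress_export",
    "write_stress_export",
]

SCENARIOS = ("scratch_digging", "hook_and_pull", "piercing")

_SCENARIO_ALIASES = {
    "dig": "scratch_digging",
    "pull": "hook_and_pull",
    "pierce": "piercing",
}


def canonical_scenario(name: str) -> str:
    name = name.strip().lower().replace("-", "_").replace(" ", "_")
    name = _SCENARIO_ALIASES.get(name, name)
    if name not in SCENARIOS:
        raise ValueError(f"unknown load scenario {name!r}; expected one of {SCENARIOS}")
    return name


class ConfigurationError(ValueError):
    """A required region set is missing or empty."""


class SolverError(RuntimeError):
    """The linear system could not be solved (insufficient constraints?)."""


@dataclass(frozen=True)
class MaterialSpec:
    """Isotropic linear elastic material (cortical bone by default)."""

    youngs_modulus_gpa: float = 20.49
    poisson_ratio: float = 0.40

    def __post_init__(self) -> None:
        if self.youngs_modulus_gpa <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")

    @property
    def youngs_modulus_mpa(self) -> float:
        return self.youngs_modulus_gpa * 1000.0

    def stiffness_matrix(self) -> np.ndarray:
        """6x6 isotropic elasticity matrix in Voigt order (xx,yy,zz,xy,yz,zx)."""
        e, nu = self.youngs_modulus_mpa, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        d = np.zeros((6, 6))
        d[:3, :3] = lam
        d[np.arange(3), np.arange(3)] += 2 * mu
        d[np.arange(3, 6), np.arange(3, 6)] = mu
        return d


@dataclass(frozen=True)
class LoadScenario:
    """One of the three standardized claw load scenarios.

    ``tip_fraction`` is the distal share of the axial parametric
    coordinate counted as "the tip" (default 5%).
    """

    kind: str
    total_force_n: float = 200.0
    tip_fraction: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", canonical_scenario(self.kind))
        if self.total_force_n <= 0:
            raise ValueError("total force must be positive")
        if not (0.0 < self.tip_fraction < 1.0):
            raise ValueError("tip_fraction must lie in (0, 1)")


@dataclass
class StressField:
    """Per-element von Mises stress with per-element volumes (MPa, mm^3)."""

    element_vm_mpa: np.ndarray
    element_volume_mm3: np.ndarray
    scenario: str = ""
    specimen_id: str = ""
    trimmed_volume_mm3: float = 0.0

    def __post_init__(self) -> None:
        self.element_vm_mpa = np.asarray(self.element_vm_mpa, dtype=np.float64).ravel()
        self.element_volume_mm3 = np.asarray(
            self.element_volume_mm3, dtype=np.float64
        ).ravel()
        if len(self.element_vm_mpa) != len(self.element_volume_mm3):
            raise ValueError("stress and volume arrays have mismatched lengths")
        if np.any(self.element_volume_mm3 <= 0):
            raise ValueError("element volumes must be strictly positive")
        if np.any(self.element_vm_mpa < 0):
            raise ValueError("von Mises stress cannot be negative")

    def __len__(self) -> int:
        return len(self.element_vm_mpa)

    @property
    def total_volume_mm3(self) -> float:
        return float(self.element_volume_mm3.sum())

    @property
    def pretrim_volume_mm3(self) -> float:
        return self.total_volume_mm3 + self.trimmed_volume_mm3


def von_mises(stress_tensor: np.ndarray) -> np.ndarray | float:
    """Von Mises equivalent stress of symmetric 3x3 tensor(s).

    Accepts shape (..., 3, 3); rotation invariant, zero for hydrostatic
    states, equal to |sigma| for uniaxial stress.
    """
    s = np.asarray(stress_tensor, dtype=np.float64)
    if s.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) stress tensor")
    d = (
        (s[..., 0, 0] - s[..., 1, 1]) ** 2
        + (s[..., 1, 1] - s[..., 2, 2]) ** 2
        + (s[..., 2, 2] - s[..., 0, 0]) ** 2
    )
    shear = s[..., 0, 1] ** 2 + s[..., 1, 2] ** 2 + s[..., 0, 2] ** 2
    out = np.sqrt(0.5 * d + 3.0 * shear)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Scenario loads


def _tip_facet_mask(mesh: TetMesh, threshold: float) -> np.ndarray:
    """Boolean mask over boundary facets reaching into the distal tip region.

    A facet counts as tip when it touches the region (any node with
    u >= threshold), so the loaded patch is non-empty even on meshes too
    coarse to have whole facets beyond the threshold.
    """
    if mesh.node_u is not None:
        return np.any(mesh.node_u[mesh.boundary_facets] >= threshold, axis=1)
    if "tip" in mesh.facet_sets:
        mask = np.zeros(len(mesh.boundary_facets), dtype=bool)
        mask[mesh.facet_sets["tip"]] = True
        return mask
    if "tip" in mesh.node_sets:
        return np.any(
            np.isin(mesh.boundary_facets, mesh.node_sets["tip"]), axis=1
        )
    raise ConfigurationError(
        'cannot resolve the tip: mesh has neither node_u nor a "tip" region set'
    )


def _tip_nodes(mesh: TetMesh, threshold: float) -> np.ndarray:
    if mesh.node_u is not None:
        return np.nonzero(mesh.node_u >= threshold)[0]
    if "tip" in mesh.node_sets and len(mesh.node_sets["tip"]):
        return mesh.node_sets["tip"]
    raise ConfigurationError(
        'cannot resolve the tip: mesh has neither node_u nor a "tip" node set'
    )


def _distal_tangent(mesh: TetMesh, threshold: float) -> np.ndarray:
    """Unit tangent of the claw axis at the tip, pointing distally."""
    pts = mesh.node_coords
    if mesh.node_u is not None:
        u = mesh.node_u
        tip = pts[u >= threshold].mean(axis=0)
        band = (u >= max(threshold - 0.15, 0.0)) & (u < threshold)
        if band.any():
            t = tip - pts[band].mean(axis=0)
            return t / np.linalg.norm(t)
    # fall back to the first principal axis, oriented distally (+x positive)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = vt[0]
    if t[0] < 0:
        t = -t
    return t / np.linalg.norm(t)


def _facet_forces_inward(
    mesh: TetMesh, facet_idx: np.ndarray, total_force: float
) -> np.ndarray:
    """Nodal forces from area-weighted inward-normal facet tractions.

    Per-facet vectors are area x inward unit normal, globally rescaled so
    the resultant magnitude equals ``total_force`` exactly; each facet's
    force is shared equally by its three nodes.
    """
    facets = mesh.boundary_facets[facet_idx]
    areas = facet_areas(mesh.node_coords, facets)
    inward = -facet_normals(mesh.node_coords, facets)
    raw = areas[:, None] * inward
    resultant = raw.sum(axis=0)
    mag = np.linalg.norm(resultant)
    if mag <= 0:
        raise ConfigurationError(
            "loaded facets have a zero resultant (opposing normals cancel); "
            "cannot normalise the applied force"
        )
    per_facet = raw * (total_force / mag)
    forces = np.zeros_like(mesh.node_coords)
    for corner in range(3):
        np.add.at(forces, facets[:, corner], per_facet / 3.0)
    return forces


def assign_scenario_loads(
    mesh: TetMesh, scenario: LoadScenario
) -> tuple[np.ndarray, np.ndarray]:
    """Nodal force vectors and fixed node set for a standardized scenario.

    Returns ``(forces, fixed_nodes)`` where forces is (n_nodes, 3) in N and
    fixed_nodes are the articular nodes (all translations constrained).
    """
    articular = mesh.node_sets.get("articular")
    if articular is None or len(articular) == 0:
        raise ConfigurationError('region set "articular" is missing or empty')

    kind = scenario.kind
    if kind in ("scratch_digging", "hook_and_pull"):
        ventral = mesh.facet_sets.get("ventral")
        if ventral is None or len(ventral) == 0:
            raise ConfigurationError('region set "ventral" is missing or empty')
        if kind == "scratch_digging":
            tip_mask = _tip_facet_mask(mesh, 1.0 - scenario.tip_fraction)
            sel = ventral[tip_mask[ventral]]
            if len(sel) == 0:
                raise ConfigurationError(
                    "no ventral facets inside the tip region; "
                    "check the tip fraction or region sets"
                )
        else:
            sel = ventral
        forces = _facet_forces_inward(mesh, sel, scenario.total_force_n)
    else:  # piercing
        tip = _tip_nodes(mesh, 1.0 - scenario.tip_fraction)
        if len(tip) == 0:
            raise ConfigurationError('region set "tip" is missing or empty')
        t = _distal_tangent(mesh, 1.0 - scenario.tip_fraction)
        forces = np.zeros_like(mesh.node_coords)
        forces[tip] = -t * (scenario.total_force_n / len(tip))
    return forces, np.asarray(articular, dtype=np.int64)


def uniform_traction_loads(
    mesh: TetMesh, facet_idx: np.ndarray, traction: np.ndarray
) -> np.ndarray:
    """Consistent nodal forces for a uniform traction (N/mm^2) on facets."""
    facets = mesh.boundary_facets[np.asarray(facet_idx, dtype=np.int64)]
    areas = facet_areas(mesh.node_coords, facets)
    per_facet = areas[:, None] * np.asarray(traction, dtype=np.float64)
    forces = np.zeros_like(mesh.node_coords)
    for corner in range(3):
        np.add.at(forces, facets[:, corner], per_facet / 3.0)
    return forces


# ---------------------------------------------------------------------------
# Solver


@dataclass
class FESolution:
    """Full FE solution: displacements plus per-element stress."""

    displacements_mm: np.ndarray
    element_stress_mpa: np.ndarray  # (n_elem, 3, 3)
    element_vm_mpa: np.ndarray
    element_volume_mm3: np.ndarray

    def stress_field(self, scenario: str = "", specimen_id: str = "") -> StressField:
        return StressField(
            self.element_vm_mpa, self.element_volume_mm3, scenario, specimen_id
        )


def _element_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (n_elem, 4, 3) and tet volumes."""
    x = mesh.node_coords[mesh.tets]  # (m, 4, 3)
    j = x[:, 1:] - x[:, :1]  # rows are edge vectors
    vol = np.linalg.det(j) / 6.0
    if np.any(vol <= 0):
        raise MeshError("mesh contains non-positively oriented tets; repair first")
    jinv = np.linalg.inv(j)  # (m, 3, 3)
    # grad N_{k+1} = column k of J^-1 ; grad N_0 = -sum
    g = np.transpose(jinv, (0, 2, 1))  # (m, 3(k), 3(xyz))
    g0 = -g.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g], axis=1), vol


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (n_elem, 6, 12), Voigt (xx,yy,zz,xy,yz,zx)."""
    m = grads.shape[0]
    b = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        b[:, 0, c] = gx
        b[:, 1, c + 1] = gy
        b[:, 2, c + 2] = gz
        b[:, 3, c] = gy
        b[:, 3, c + 1] = gx
        b[:, 4, c + 1] = gz
        b[:, 4, c + 2] = gy
        b[:, 5, c] = gz
        b[:, 5, c + 2] = gx
    return b


def _fixed_dof_mask(mesh: TetMesh, fixed) -> np.ndarray:
    """Accept node indices (all components fixed) or an (n, 3) boolean mask."""
    fixed = np.asarray(fixed)
    mask = np.zeros((mesh.n_nodes, 3), dtype=bool)
    if fixed.dtype == bool:
        mask[:] = fixed.reshape(mesh.n_nodes, 3)
    else:
        mask[fixed.astype(np.int64)] = True
    return mask.ravel()


def solve(
    mesh: TetMesh, material: MaterialSpec, loads: np.ndarray, fixed
) -> FESolution:
    """Solve K u = f with constant-strain tets and return the full solution.

    ``loads`` is (n_nodes, 3) nodal forces in N; ``fixed`` is either an
    array of node indices (all translations fixed) or an (n_nodes, 3)
    boolean mask of constrained components (fixed at zero).
    """
    if mesh.n_tets == 0:
        raise MeshError("surface-only mesh cannot be solved; tetrahedra required")
    grads, vol = _element_gradients(mesh)
    b = _b_matrices(grads)
    d = material.stiffness_matrix()
    ke = np.einsum("eia,ij,ejb,e->eab", b, d, b, vol, optimize=True)

    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n_dof = 3 * mesh.n_nodes
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsc()

    fixed_mask = _fixed_dof_mask(mesh, fixed)
    if not fixed_mask.any():
        raise SolverError("no constrained dofs; the system has rigid-body modes")
    free = ~fixed_mask
    f = np.asarray(loads, dtype=np.float64).ravel()
    try:
        lu = spla.splu(k[free][:, free])
        u_free = lu.solve(f[free])
    except RuntimeError as exc:
        raise SolverError(
            "singular stiffness system; check that the articular set "
            f"constrains all rigid-body modes ({exc})"
        ) from exc
    if not np.all(np.isfinite(u_free)):
        raise SolverError(
            "non-finite displacements; check the articular constraint set"
        )
    u = np.zeros(n_dof)
    u[free] = u_free

    ue = u[dofs]  # (m, 12)
    strain = np.einsum("eij,ej->ei", b, ue)
    stress_voigt = strain @ d.T
    m = len(vol)
    tensors = np.empty((m, 3, 3))
    sxx, syy, szz, sxy, syz, szx = stress_voigt.T
    tensors[:, 0, 0] = sxx
    tensors[:, 1, 1] = syy
    tensors[:, 2, 2] = szz
    tensors[:, 0, 1] = tensors[:, 1, 0] = sxy
    tensors[:, 1, 2] = tensors[:, 2, 1] = syz
    tensors[:, 0, 2] = tensors[:, 2, 0] = szx
    vm = von_mises(tensors)
    return FESolution(u.reshape(-1, 3), tensors, np.asarray(vm), vol)


def solve_linear_elastic(
    mesh: TetMesh,
    material: MaterialSpec,
    loads: np.ndarray,
    fixed,
    scenario: str = "",
    specimen_id: str = "",
) -> StressField:
    """Linear elastic solve returning the per-element von Mises field."""
    return solve(mesh, material, loads, fixed).stress_field(scenario, specimen_id)


def solve_scenario(
    mesh: TetMesh,
    scenario: LoadScenario,
    material: MaterialSpec | None = None,
    specimen_id: str = "",
) -> StressField:
    """Convenience: assign a standardized scenario's loads and solve."""
    material = material or MaterialSpec()
    forces, fixed = assign_scenario_loads(mesh, scenario)
    return solve_linear_elastic(
        mesh, material, forces, fixed, scenario.kind, specimen_id
    )


# ---------------------------------------------------------------------------
# Stress CSV interchange (element_id, von_mises_mpa, volume_mm3)


def read_stress_export(path: str) -> StressField:
    """Read a per-element von Mises export from any FEA program.

    Rows with non-positive volume are rejected; the rejection count is
    logged.
    """
    import pandas as pd

    table = pd.read_csv(path)
    required = {"element_id", "von_mises_mpa", "volume_mm3"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(
            f"stress export {path} is missing column(s): {', '.join(sorted(missing))}"
        )
    bad = table["volume_mm3"] <= 0
    if bad.any():
        log.warning("rejected %d rows with non-positive volume", int(bad.sum()))
        table = table[~bad]
    return StressField(
        table["von_mises_mpa"].to_numpy(),
        table["volume_mm3"].to_numpy(),
    )


def write_stress_export(field: StressField, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("element_id,von_mises_mpa,volume_mm3\n")
        for i, (vm, vol) in enumerate(
            zip(field.element_vm_mpa, field.element_volume_mm3), start=1
        ):
            fh.write(f"{i},{vm:.12g},{vol:.12g}\n")
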