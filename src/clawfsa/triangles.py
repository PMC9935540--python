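"""Functional triangles: per-specimen geometry in the functional space.

One specimen run under the three load scenarios gives three points in the
(PC1, PC2) functional space — a functional triangle.  Its area measures
functional divergence (large = variable performance across functions),
its centroid the average performance, and its three directed sides compare
scenarios pairwise: a side is positive when its terminal scenario sits in
a higher stress field than its initial scenario (higher stress = less
suited), where "higher stress field" is the volume-weighted mean von Mises
stress of the underlying simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fe import SCENARIOS, canonical_scenario
from .intervals import FunctionalSpaceModel

__all__ = [
    "SignedSide",
    "FunctionalTriangle",
    "SIDE_DEFINITIONS",
    "build_functional_triangle",
    "triangles_from_model",
    "classify_quadrant",
    "triangle_report",
]

# (name, initial scenario, terminal scenario, report column)
SIDE_DEFINITIONS = (
    ("hook-and-pull to piercing", "hook_and_pull", "piercing", "side_pullpierce"),
    ("scratch-digging to piercing", "scratch_digging", "piercing", "side_digpierce"),
    ("scratch-digging to hook-and-pull", "scratch_digging", "hook_and_pull", "side_digpull"),
)


@dataclass(frozen=True)
class SignedSide:
    """A directed triangle side with the stress-comparison sign."""

    name: str
    length: float
    sign: int
    signed_value: float

    @classmethod
    def from_vertices(
        cls,
        name: str,
        start: np.ndarray,
        end: np.ndarray,
        stress_start: float,
        stress_end: float,
        stress_tol: float = 1e-9,
    ) -> "SignedSide":
        length = float(np.linalg.norm(np.asarray(end) - np.asarray(start)))
        delta = stress_end - stress_start
        sign = 0 if abs(delta) <= stress_tol else (1 if delta > 0 else -1)
        return cls(name, length, sign, sign * length)


@dataclass(frozen=True)
class FunctionalTriangle:
    """Three scenario points of one specimen with divergence metrics."""

    specimen_id: str
    vertices: Mapping[str, tuple[float, float]]
    vertex_mean_stress: Mapping[str, float]
    centroid: tuple[float, float]
    area: float
    sides: tuple[SignedSide, SignedSide, SignedSide]

    @property
    def mean_vertex_stress(self) -> float:
        return float(np.mean(list(self.vertex_mean_stress.values())))

    def side(self, name: str) -> SignedSide:
        for s in self.sides:
            if s.name == name:
                return s
        raise KeyError(f"no side named {name!r}")


def build_functional_triangle(
    specimen_id: str,
    scenario_points: Mapping[str, tuple[float, float]]
    | Iterable[tuple[str, tuple[float, float]]],
    mean_stresses: Mapping[str, float],
    stress_tol: float = 1e-9,
) -> FunctionalTriangle:
    """Build a functional triangle from one specimen's three scenario scores.

    ``scenario_points`` maps each of the three scenarios to its (pc1, pc2)
    coordinates; ``mean_stresses`` to the simulation's volume-weighted mean
    von Mises stress in MPa.  Area by the shoelace formula, centroid as the
    vertex mean; side signs follow the higher-terminal-stress rule.
    """
    if not isinstance(scenario_points, Mapping):
        pts: dict[str, tuple[float, float]] = {}
        for name, xy in scenario_points:
            key = canonical_scenario(name)
            if key in pts:
                raise ValueError(f"duplicated scenario {key!r}")
            pts[key] = xy
        scenario_points = pts
    points = {canonical_scenario(k): np.asarray(v, float) for k, v in scenario_points.items()}
    stresses = {canonical_scenario(k): float(v) for k, v in mean_stresses.items()}
    for s in SCENARIOS:
        if s not in points:
            raise ValueError(f"missing scenario {s!r} for specimen {specimen_id!r}")
        if s not in stresses:
            raise ValueError(f"missing mean stress for scenario {s!r}")
    if len(points) != 3:
        raise ValueError("expected exactly the three load scenarios")

    (x1, y1), (x2, y2), (x3, y3) = (points[s] for s in SCENARIOS)
    area = 0.5 * abs(x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    centroid = (float((x1 + x2 + x3) / 3.0), float((y1 + y2 + y3) / 3.0))
    sides = tuple(
        SignedSide.from_vertices(
            name, points[a], points[b], stresses[a], stresses[b], stress_tol
        )
        for name, a, b, _ in SIDE_DEFINITIONS
    )
    return FunctionalTriangle(
        specimen_id=specimen_id,
        vertices={s: (float(points[s][0]), float(points[s][1])) for s in SCENARIOS},
        vertex_mean_stress=stresses,
        centroid=centroid,
        area=float(area),
        sides=sides,  # type: ignore[arg-type]
    )


def triangles_from_model(
    model: FunctionalSpaceModel, stress_tol: float = 1e-9
) -> list[FunctionalTriangle]:
    """One functional triangle per specimen from a joint ordination."""
    out = []
    for sid, grp in model.scores.groupby("specimen_id", sort=True):
        pts = {
            row["scenario"]: (float(row["pc1"]), float(row["pc2"]))
            for _, row in grp.iterrows()
        }
        stresses = {
            row["scenario"]: float(row["mean_stress_mpa"]) for _, row in grp.iterrows()
        }
        if len(grp) != 3:
            raise ValueError(
                f"specimen {sid!r} has {len(grp)} simulations; exactly 3 required"
            )
        out.append(build_functional_triangle(str(sid), pts, stresses, stress_tol))
    return out


def classify_quadrant(point: tuple[float, float]) -> str:
    """Quadrant label I-IV of a functional-space point.

    I = (+,+), II = (-,+), III = (-,-), IV = (+,-); the low-stress corner
    of an oriented ordination is II.  Points on an axis take the adjacent
    quadrant by the half-open rule: 0 counts as positive.
    """
    x, y = point
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("quadrant classification needs finite coordinates")
    if x >= 0:
        return "I" if y >= 0 else "IV"
    return "II" if y >= 0 else "III"


def triangle_report(triangles: Iterable[FunctionalTriangle]) -> pd.DataFrame:
    """Tabular per-specimen summary, deterministically ordered by id."""
    triangles = list(triangles)
    if not triangles:
        raise ValueError("no triangles to report")
    rows = []
    for t in triangles:
        row = {
            "specimen_id": t.specimen_id,
            "area": t.area,
            "centroid_pc1": t.centroid[0],
            "centroid_pc2": t.centroid[1],
            "quadrant": classify_quadrant(t.centroid),
            "mean_vertex_stress_mpa": t.mean_vertex_stress,
        }
        for name, _, _, col in SIDE_DEFINITIONS:
            row[col] = t.side(name).signed_value
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values("specimen_id", kind="stable")
        .reset_index(drop=True)
    )
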