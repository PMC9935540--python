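"""End-to-end convenience: stress fields -> functional space -> triangles."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fe import StressField
from .intervals import (
    FunctionalSpaceModel,
    IntervalConfig,
    batch_interval_vectors,
    ordinate,
    vectors_to_frame,
)
from .triangles import FunctionalTriangle, triangle_report, triangles_from_model

__all__ = ["FSAResult", "analyze_fields"]


@dataclass
class FSAResult:
    """Everything one functional-space analysis produces."""

    interval_frame: pd.DataFrame
    model: FunctionalSpaceModel
    triangles: list[FunctionalTriangle]
    report: pd.DataFrame


def analyze_fields(
    fields: list[StressField], config: IntervalConfig | None = None
) -> FSAResult:
    """Run the intervals method, joint ordination and triangle construction.

    Every specimen must contribute exactly the three standardized
    scenarios; fields are trimmed and binned over a shared global bound.
    """
    config = config or IntervalConfig()
    vectors = batch_interval_vectors(fields, config)
    model = ordinate(vectors, config)
    tris = triangles_from_model(model)
    return FSAResult(
        interval_frame=vectors_to_frame(vectors),
        model=model,
        triangles=tris,
        report=triangle_report(tris),
    )
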