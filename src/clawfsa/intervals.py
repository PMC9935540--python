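"""The intervals method: stress fields -> interval vectors -> functional space.

A stress field is summarised as the percentage of model volume falling in
each of ``n_intervals`` equal stress ranges over a shared [lower, upper]
bound (50 intervals by default).  Before binning, the highest-stress
elements are trimmed by volume (default 2%, allowed up to 5%) to avoid
extreme-value effects from constraint anchor points.  Vectors from a batch
are then log-transformed (log(p + c), zero-volume intervals are common),
standardized column-wise (correlation PCA) and ordinated jointly by PCA
into the functional space.  Component signs are fixed deterministically:
PC1 correlates non-negatively with the volume-weighted mean stress of the
simulations (so the high-stress quadrants are reproducible across runs),
and every other component has its largest-magnitude loading positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fe import StressField

__all__ = [
    "IntervalConfig",
    "IntervalVector",
    "FunctionalSpaceModel",
    "trim_upper_tail",
    "compute_interval_vector",
    "batch_interval_vectors",
    "ordinate",
    "mean_stress_summary",
    "vectors_to_frame",
    "frame_to_vectors",
]


@dataclass(frozen=True)
class IntervalConfig:
    """Binning and transform settings for the intervals method.

    ``upper_bound_mpa=None`` means the pooled post-trim maximum across the
    batch (a shared global bound is required for cross-model
    comparability).  ``log_offset`` is in percentage points.
    """

    n_intervals: int = 50
    trim_fraction: float = 0.02
    lower_bound_mpa: float = 0.0
    upper_bound_mpa: float | None = None
    log_offset: float = 0.01

    def __post_init__(self) -> None:
        if self.n_intervals < 2:
            raise ValueError("need at least 2 intervals")
        if not (0.0 <= self.trim_fraction <= 0.05):
            raise ValueError("trim fraction must lie in [0, 0.05]")
        if self.upper_bound_mpa is not None and (
            self.upper_bound_mpa <= self.lower_bound_mpa
        ):
            raise ValueError("upper bound must exceed lower bound")
        if self.log_offset <= 0:
            raise ValueError("log offset must be positive")


@dataclass
class IntervalVector:
    """Volume-percentage-per-stress-interval fingerprint of one simulation.

    Percentages are relative to the original (pre-trim) model volume, so
    ``sum(percentages) + trimmed_volume_pct == 100``.
    """

    percentages: np.ndarray
    edges: np.ndarray
    specimen_id: str = ""
    scenario: str = ""
    trimmed_volume_pct: float = 0.0
    mean_stress_mpa: float | None = None

    def __post_init__(self) -> None:
        self.percentages = np.asarray(self.percentages, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.float64)
        if len(self.edges) != len(self.percentages) + 1:
            raise ValueError("edges must have one more entry than percentages")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(self.percentages < -1e-12):
            raise ValueError("percentages must be non-negative")


def mean_stress_summary(fld: StressField) -> float:
    """Volume-weighted arithmetic mean of element von Mises stress (MPa)."""
    if len(fld) == 0:
        raise ValueError("empty stress field")
    return float(
        np.average(fld.element_vm_mpa, weights=fld.element_volume_mm3)
    )


def trim_upper_tail(fld: StressField, fraction: float) -> StressField:
    """Remove whole elements from the top of the stress range, by volume.

    Elements are removed in descending stress order, greedily, while the
    cumulative removed volume stays <= fraction x total volume (never
    exceeding it).  The removed volume is recorded on the returned field.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("trim fraction must lie in [0, 1)")
    if fraction == 0.0 or len(fld) == 0:
        return replace(fld)
    order = np.argsort(-fld.element_vm_mpa, kind="stable")
    budget = fraction * fld.total_volume_mm3
    cum = np.cumsum(fld.element_volume_mm3[order])
    n_removed = int(np.searchsorted(cum, budget, side="right"))
    removed = order[:n_removed]
    keep = np.ones(len(fld), dtype=bool)
    keep[removed] = False
    return StressField(
        fld.element_vm_mpa[keep],
        fld.element_volume_mm3[keep],
        fld.scenario,
        fld.specimen_id,
        trimmed_volume_mm3=fld.trimmed_volume_mm3
        + float(fld.element_volume_mm3[removed].sum()),
    )


def compute_interval_vector(
    fld: StressField, config: IntervalConfig
) -> IntervalVector:
    """Bin a (possibly pre-trimmed) field into equal stress intervals.

    Interval i accumulates the volume of elements with stress in
    [edge_i, edge_{i+1}); the last interval is closed.  Stresses above the
    upper bound (possible when a global bound is imposed) are accumulated
    into the last interval with a warning.  Percentages are relative to
    the pre-trim total volume.
    """
    if len(fld) == 0:
        raise ValueError("cannot bin an empty stress field")
    lower = config.lower_bound_mpa
    upper = (
        config.upper_bound_mpa
        if config.upper_bound_mpa is not None
        else float(fld.element_vm_mpa.max())
    )
    if upper <= lower:
        upper = lower + 1.0  # all-constant field at the lower bound
    edges = np.linspace(lower, upper, config.n_intervals + 1)
    vm = fld.element_vm_mpa
    over = vm > upper
    if over.any():
        warnings.warn(
            f"{int(over.sum())} elements exceed the upper bound "
            f"{upper:g} MPa; accumulated into the last interval",
            stacklevel=2,
        )
        vm = np.minimum(vm, upper)
    hist, _ = np.histogram(vm, bins=edges, weights=fld.element_volume_mm3)
    total = fld.pretrim_volume_mm3
    return IntervalVector(
        percentages=100.0 * hist / total,
        edges=edges,
        specimen_id=fld.specimen_id,
        scenario=fld.scenario,
        trimmed_volume_pct=100.0 * fld.trimmed_volume_mm3 / total,
        mean_stress_mpa=mean_stress_summary(fld) if fld.trimmed_volume_mm3 == 0 else None,
    )


def batch_interval_vectors(
    fields: list[StressField], config: IntervalConfig | None = None
) -> list[IntervalVector]:
    """Trim and bin a batch of fields over a shared global stress bound.

    Each field is trimmed by ``config.trim_fraction``; unless an explicit
    upper bound is configured, the pooled post-trim maximum across the
    batch becomes the common upper edge.  The volume-weighted mean stress
    of the ORIGINAL (untrimmed) field is attached to each vector for PC1
    orientation and side-sign rules downstream.
    """
    config = config or IntervalConfig()
    trimmed = [trim_upper_tail(f, config.trim_fraction) for f in fields]
    if config.upper_bound_mpa is None:
        pooled_max = max(float(t.element_vm_mpa.max()) for t in trimmed)
        config = replace(config, upper_bound_mpa=max(pooled_max, config.lower_bound_mpa + 1e-12))
    vectors = []
    for original, t in zip(fields, trimmed):
        v = compute_interval_vector(t, config)
        v.mean_stress_mpa = mean_stress_summary(original)
        vectors.append(v)
    return vectors


def vectors_to_frame(vectors: list[IntervalVector]) -> pd.DataFrame:
    """One row per simulation; columns labelled by interval upper edges."""
    if not vectors:
        raise ValueError("no interval vectors")
    edges = vectors[0].edges
    cols = [f"le_{e:.6g}MPa" for e in edges[1:]]
    rows = []
    for v in vectors:
        row = {
            "specimen_id": v.specimen_id,
            "scenario": v.scenario,
            "trimmed_volume_pct": v.trimmed_volume_pct,
            "mean_stress_mpa": v.mean_stress_mpa,
        }
        row.update(dict(zip(cols, v.percentages)))
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["edges"] = edges.tolist()
    return frame


def frame_to_vectors(frame: pd.DataFrame, edges: np.ndarray | None = None) -> list[IntervalVector]:
    """Inverse of :func:`vectors_to_frame` (edges from attrs or argument)."""
    cols = [c for c in frame.columns if c.startswith("le_")]
    if edges is None:
        stored = frame.attrs.get("edges")
        if stored is None:
            uppers = [float(c[3:-3]) for c in cols]  # strip "le_" and "MPa"
            first_width = uppers[1] - uppers[0] if len(uppers) > 1 else uppers[0]
            edges = np.concatenate([[uppers[0] - first_width], uppers])
        else:
            edges = np.asarray(stored)
    out = []
    for _, row in frame.iterrows():
        out.append(
            IntervalVector(
                percentages=row[cols].to_numpy(dtype=float),
                edges=np.asarray(edges, dtype=float),
                specimen_id=str(row.get("specimen_id", "")),
                scenario=str(row.get("scenario", "")),
                trimmed_volume_pct=float(row.get("trimmed_volume_pct", 0.0)),
                mean_stress_mpa=(
                    None
                    if pd.isna(row.get("mean_stress_mpa"))
                    else float(row["mean_stress_mpa"])
                ),
            )
        )
    return out


@dataclass
class FunctionalSpaceModel:
    """Joint PCA ordination of interval vectors: the functional space.

    ``scores`` has one row per simulation with specimen_id, scenario,
    mean_stress_mpa and pc1..pcK columns.  Transform parameters (per-column
    means/scales on the log scale, the log offset, kept columns and the
    shared edges) are retained so the ordination is fully reproducible.
    """

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_kept_columns, n_components)
    kept_columns: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    log_offset: float
    edges: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def score_matrix(self) -> np.ndarray:
        pcs = [c for c in self.scores.columns if c.startswith("pc")]
        return self.scores[pcs].to_numpy(dtype=float)


def ordinate(
    vectors: list[IntervalVector],
    config: IntervalConfig | None = None,
    n_components: int | None = None,
) -> FunctionalSpaceModel:
    """Ordinate a batch of interval vectors jointly by correlation PCA.

    Pipeline: log(p + c) per cell -> drop zero-variance columns ->
    standardize to unit variance -> PCA.  All simulations are ordinated
    jointly.  Requires >= 3 vectors (three scenarios make one triangle)
    with identical edges; mismatched edges mean the fields were binned
    without a shared bound — re-bin with :func:`batch_interval_vectors`.
    """
    if len(vectors) < 3:
        raise ValueError(
            "ordination needs at least 3 interval vectors (one per scenario)"
        )
    edges0 = vectors[0].edges
    for v in vectors[1:]:
        if len(v.edges) != len(edges0) or not np.allclose(v.edges, edges0, atol=1e-12):
            raise ValueError(
                "interval vectors have mismatched edges; re-bin the batch with "
                "a shared global bound (batch_interval_vectors)"
            )
    mean_stress = np.array(
        [np.nan if v.mean_stress_mpa is None else v.mean_stress_mpa for v in vectors]
    )
    if np.isnan(mean_stress).any():
        raise ValueError(
            "every interval vector needs mean_stress_mpa for PC1 orientation"
        )
    config = config or IntervalConfig()
    p = np.vstack([v.percentages for v in vectors])
    x = np.log(p + config.log_offset)

    spread = x.max(axis=0) - x.min(axis=0)
    kept = np.nonzero(spread > 0.0)[0]
    if len(kept) == 0:
        raise ValueError("all interval columns are constant; nothing to ordinate")
    x = x[:, kept]
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    z = (x - means) / scales

    from sklearn.decomposition import PCA

    max_comp = min(z.shape[0] - 1, z.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T.copy()  # (n_cols, k)

    # deterministic signs: PC1 non-negatively correlated with mean stress,
    # other components' largest-|loading| positive
    for comp in range(k):
        if comp == 0:
            sd = scores[:, 0].std()
            r = (
                0.0
                if sd == 0 or mean_stress.std() == 0
                else float(np.corrcoef(scores[:, 0], mean_stress)[0, 1])
            )
            flip = r < 0
        else:
            j = int(np.argmax(np.abs(loadings[:, comp])))
            flip = loadings[j, comp] < 0
        if flip:
            scores[:, comp] = -scores[:, comp]
            loadings[:, comp] = -loadings[:, comp]

    frame = pd.DataFrame(
        {
            "specimen_id": [v.specimen_id for v in vectors],
            "scenario": [v.scenario for v in vectors],
            "mean_stress_mpa": mean_stress,
        }
    )
    for comp in range(k):
        frame[f"pc{comp + 1}"] = scores[:, comp]
    return FunctionalSpaceModel(
        scores=frame,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        kept_columns=kept,
        column_means=means,
        column_scales=scales,
        log_offset=config.log_offset,
        edges=edges0.copy(),
    )
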