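"""Total-evidence layer: shape ratios, morphospace projection, regressions.

Relates the functional summaries (triangle centroid, area, signed sides,
mean stress) to claw shape (L/W, L/D, D/W ratios) and size (ungual volume,
body mass).  Study claws are projected as supplementary points into a
morphospace PCA fitted on a reference claw-ratio table only, so reference
scores are unchanged by the projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "MorphospaceModel",
    "RATIO_COLUMNS",
    "regress_ols",
    "morphospace_project",
    "divergence_metrics",
]

RATIO_COLUMNS = ("ratio_LW", "ratio_LD", "ratio_DW")

# accept the field's slash spellings in reference tables
_RATIO_ALIASES = {
    "l/w": "ratio_LW",
    "l/d": "ratio_LD",
    "d/w": "ratio_DW",
    "lw": "ratio_LW",
    "ld": "ratio_LD",
    "dw": "ratio_DW",
}


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares y = slope*x + intercept.

    R^2 is the squared Pearson correlation; the p-value is the two-sided
    slope t-test with n-2 degrees of freedom (undefined for n = 2).
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    x_label: str
    y_label: str

    def predict(self, x):
        return self.slope * np.asarray(x, float) + self.intercept


def regress_ols(
    x,
    y,
    log_x: bool = False,
    log_y: bool = False,
    log_base: float = 10.0,
    x_label: str = "x",
    y_label: str = "y",
) -> RegressionResult:
    """OLS regression with optional log transforms and pairwise NA dropping."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal lengths")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    for flag, arr, lbl in ((log_x, x, x_label), (log_y, y, y_label)):
        if flag and np.any(arr <= 0):
            raise ValueError(f"log transform of {lbl!r} requires positive values")
    if log_x:
        x = np.log(x) / np.log(log_base)
        x_label = f"log{log_base:g}({x_label})"
    if log_y:
        y = np.log(y) / np.log(log_base)
        y_label = f"log{log_base:g}({y_label})"
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope is undefined")
    res = stats.linregress(x, y)
    p = float(res.pvalue) if n > 2 else float("nan")
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=p,
        n=n,
        x_label=x_label,
        y_label=y_label,
    )


@dataclass
class MorphospaceModel:
    """PCA morphospace fitted on log reference ratios; records projected in.

    ``reference_scores`` are the reference rows' own coordinates (unchanged
    by projecting study records); ``record_scores`` the supplementary study
    points.
    """

    reference_scores: pd.DataFrame
    record_scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (n_components, 3) rows = axes in log-ratio space
    mean_log_ratios: np.ndarray
    log_base: float

    def project(self, ratios: pd.DataFrame) -> np.ndarray:
        x = _log_ratio_matrix(ratios, self.log_base)
        return (x - self.mean_log_ratios) @ self.components.T


def _normalise_ratio_columns(table: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in table.columns:
        key = str(col).strip().lower().replace(" ", "")
        if key in _RATIO_ALIASES:
            renames[col] = _RATIO_ALIASES[key]
    return table.rename(columns=renames)


def _log_ratio_matrix(table: pd.DataFrame, log_base: float) -> np.ndarray:
    table = _normalise_ratio_columns(table)
    missing = [c for c in RATIO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"ratio column(s) missing: {', '.join(missing)} "
            "(accepted spellings include L/W, L/D, D/W)"
        )
    x = table[list(RATIO_COLUMNS)].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("claw ratios must be finite and strictly positive")
    return np.log(x) / np.log(log_base)


def morphospace_project(
    records: pd.DataFrame,
    reference_table: pd.DataFrame,
    n_components: int = 2,
    log_base: float = 10.0,
) -> MorphospaceModel:
    """Project study claws into a reference-ratio morphospace.

    The PCA (covariance, on log ratios) is fitted on the reference table
    only; study records enter as supplementary points.  Component signs are
    fixed by making each axis' largest-magnitude loading positive.  Note
    log L/W = log L/D + log D/W, so the third axis carries ~zero variance.
    """
    if len(reference_table) < 3:
        raise ValueError("reference table needs at least 3 rows")
    x_ref = _log_ratio_matrix(reference_table, log_base)
    from sklearn.decomposition import PCA

    k = min(n_components, 3, len(reference_table) - 1)
    pca = PCA(n_components=k, svd_solver="full")
    ref_scores = pca.fit_transform(x_ref)
    components = pca.components_.copy()
    for comp in range(k):
        j = int(np.argmax(np.abs(components[comp])))
        if components[comp, j] < 0:
            components[comp] = -components[comp]
            ref_scores[:, comp] = -ref_scores[:, comp]

    def score_frame(scores: np.ndarray, source: pd.DataFrame) -> pd.DataFrame:
        frame = pd.DataFrame(
            scores, columns=[f"mp{c + 1}" for c in range(k)], index=source.index
        )
        for id_col in ("specimen_id", "species", "taxon"):
            if id_col in source.columns:
                frame.insert(0, id_col, source[id_col].to_numpy())
                break
        return frame

    rec_scores = (_log_ratio_matrix(records, log_base) - pca.mean_) @ components.T
    return MorphospaceModel(
        reference_scores=score_frame(ref_scores, reference_table),
        record_scores=score_frame(rec_scores, records),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        components=components,
        mean_log_ratios=pca.mean_.copy(),
        log_base=log_base,
    )


def divergence_metrics(
    records: pd.DataFrame,
    baseline_id: str,
    side_column: str = "side_digpierce",
) -> pd.DataFrame:
    """Per-record morphological and functional divergence scalars.

    ``records`` must carry morphospace coordinates (mp1, mp2) and triangle
    summaries (area plus the chosen signed-side column).  Morphological
    divergence is the Euclidean distance from the baseline record in the
    (mp1, mp2) plane; functional divergence is intrinsic to each record and
    emitted both as the triangle area and as the named signed side.
    """
    for col in ("specimen_id", "mp1", "mp2", "area", side_column):
        if col not in records.columns:
            raise ValueError(f"records are missing required column {col!r}")
    ids = records["specimen_id"].astype(str)
    if not ids.is_unique:
        raise ValueError("specimen ids must be unique")
    base = records[ids == str(baseline_id)]
    if len(base) != 1:
        raise ValueError(f"unknown baseline specimen {baseline_id!r}")
    b = base[["mp1", "mp2"]].to_numpy(dtype=float)[0]
    coords = records[["mp1", "mp2"]].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "specimen_id": ids.to_numpy(),
            "morphological_divergence": np.linalg.norm(coords - b, axis=1),
            "functional_divergence_area": records["area"].to_numpy(dtype=float),
            "functional_divergence_side": records[side_column].to_numpy(dtype=float),
        }
    )
    out.attrs["baseline_id"] = str(baseline_id)
    out.attrs["side_column"] = side_column
    return out
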