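"""Per-segment morphometric feature tables from repeated raw observations.

Raw observations come from vessel cross sections in registered light-
microscopy slices: for each cross section the lumen diameter ``A`` and the
outer diameter ``B`` (lumen plus both media walls; the adventitia is
excluded) are measured in micrometres, and where the staining allows, the
number of smooth-muscle cell layers is counted.  The wall thickness of one
observation is (B - A) / 2.

A segment is typically observed in several slices; observations are
averaged per segment into a single :data:`MeasurementTable` row.  Wall
thickness is computed per observation and then averaged (not recomputed
from averaged diameters); layer counts are averaged over the observations
where a count exists and left missing otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawObservation",
    "MeasurementError",
    "wall_thickness",
    "aggregate_observations",
    "feature_matrix",
    "observations_to_frame",
    "FEATURE_COLUMNS",
]

#: canonical MeasurementTable columns
TABLE_COLUMNS = [
    "segment_id",
    "lumen_diameter",
    "wall_thickness",
    "layer_count",
    "n_observations",
]

#: mapping from short feature names to MeasurementTable columns
FEATURE_COLUMNS = {
    "lumen": "lumen_diameter",
    "wall": "wall_thickness",
    "layers": "layer_count",
}


class MeasurementError(ValueError):
    """Raised for physically impossible raw observations."""


@dataclass(frozen=True)
class RawObservation:
    """One cross-section measurement of one segment in one slice."""

    segment_id: int
    slice_id: int
    lumen_diameter: float  # A, um
    outer_diameter: float  # B = lumen + both media walls, um
    layer_count: int | None = None

    def __post_init__(self) -> None:
        if self.lumen_diameter < 0:
            raise MeasurementError(
                f"segment {self.segment_id} slice {self.slice_id}: negative lumen"
            )
        if self.outer_diameter < self.lumen_diameter:
            raise MeasurementError(
                f"segment {self.segment_id} slice {self.slice_id}: outer diameter "
                f"B={self.outer_diameter} < lumen A={self.lumen_diameter}"
            )
        if self.layer_count is not None and self.layer_count < 0:
            raise MeasurementError(
                f"segment {self.segment_id} slice {self.slice_id}: negative layer count"
            )

    @property
    def wall(self) -> float:
        return wall_thickness(self.lumen_diameter, self.outer_diameter)


def wall_thickness(A, B):
    """Wall thickness from lumen diameter ``A`` and outer diameter ``B``.

    The outer diameter spans media, intima, lumen, intima and media, so the
    single-wall thickness is (B - A) / 2.  Vectorized over array input.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(B < A) or np.any(A < 0):
        bad = np.argwhere((B < A) | (A < 0)).ravel()
        raise MeasurementError(
            f"invalid diameter pair(s) at observation index {bad.tolist()[:5]}: "
            "need B >= A >= 0"
        )
    out = (B - A) / 2.0
    return float(out) if out.ndim == 0 else out


def observations_to_frame(
    observations: Iterable[RawObservation] | pd.DataFrame,
) -> pd.DataFrame:
    """Normalize observations to a DataFrame with columns
    segment_id, slice_id, A_um, B_um, layers."""
    if isinstance(observations, pd.DataFrame):
        df = observations.copy()
        missing = {"segment_id", "A_um", "B_um"} - set(df.columns)
        if missing:
            raise ValueError(f"observation table lacks columns {sorted(missing)}")
        if "slice_id" not in df.columns:
            df["slice_id"] = 0
        if "layers" not in df.columns:
            df["layers"] = np.nan
        return df[["segment_id", "slice_id", "A_um", "B_um", "layers"]]
    rows = [
        {
            "segment_id": o.segment_id,
            "slice_id": o.slice_id,
            "A_um": o.lumen_diameter,
            "B_um": o.outer_diameter,
            "layers": np.nan if o.layer_count is None else float(o.layer_count),
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=["segment_id", "slice_id", "A_um", "B_um", "layers"])


def aggregate_observations(
    observations: Iterable[RawObservation] | pd.DataFrame,
) -> pd.DataFrame:
    """Average repeated observations per segment into a MeasurementTable.

    Per segment: lumen = mean(A); wall = mean of per-observation
    (B - A) / 2; layer_count = mean over observations with a count (NaN if
    none); n_observations = number of observations of that segment.  The
    result has one row per segment_id, sorted by segment_id, and is
    invariant to the observation order.
    """
    df = observations_to_frame(observations)
    if df.empty:
        raise ValueError("no observations to aggregate")
    # validates B >= A >= 0 as a side effect
    df = df.assign(wall=wall_thickness(df["A_um"], df["B_um"]))
    grouped = df.groupby("segment_id", sort=True)
    table = pd.DataFrame(
        {
            "segment_id": np.array(sorted(df["segment_id"].unique())),
            "lumen_diameter": grouped["A_um"].mean().to_numpy(),
            "wall_thickness": grouped["wall"].mean().to_numpy(),
            "layer_count": grouped["layers"].mean().to_numpy(),
            "n_observations": grouped.size().to_numpy(),
        }
    )
    return table


def feature_matrix(
    table: pd.DataFrame, features: Sequence[str] = ("lumen", "wall")
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (segment_ids, n x d matrix) for the requested features.

    Rows are kept only for segments with *all* requested features present;
    row order is stable by segment_id and column order follows ``features``
    (default: lumen, wall).
    """
    cols = []
    for f in features:
        if f not in FEATURE_COLUMNS:
            raise ValueError(f"unknown feature {f!r}; expected one of {list(FEATURE_COLUMNS)}")
        cols.append(FEATURE_COLUMNS[f])
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    sub = table[["segment_id", *cols]].dropna(subset=cols).sort_values("segment_id")
    if sub.empty:
        raise ValueError(f"no segment has all of the requested features {list(features)}")
    return sub["segment_id"].to_numpy(), sub[cols].to_numpy(dtype=float)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a raw observation CSV (segment_id,slice_id,A_um,B_um,layers)."""
    return observations_to_frame(pd.read_csv(path, float_precision="round_trip"))


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    return df[TABLE_COLUMNS]
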