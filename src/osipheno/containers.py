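"""Shared in-memory containers and their delimited-text dialects."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sampling grid: every 6 h for 5 days, 20 points (0, 6, ..., 114 h)
DEFAULT_GRID_HOURS = tuple(range(0, 120, 6))


@dataclass
class TrajectoryMatrix:
    """Per-patient OSI series on a fixed 6-hourly grid.

    Attributes
    ----------
    patient_ids : (n,) integer array
    grid_hours : (T,) strictly increasing sampling times in hours
    osi : (n, T) float array; NaN where unobserved
    mask : (n, T) bool array, True where observed
    """

    patient_ids: np.ndarray
    grid_hours: np.ndarray
    osi: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        self.grid_hours = np.asarray(self.grid_hours, dtype=float)
        self.osi = np.asarray(self.osi, dtype=float)
        if self.mask is None:
            self.mask = ~np.isnan(self.osi)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.osi.shape != self.mask.shape:
            raise ValueError("osi and mask shapes differ")
        if self.osi.shape != (len(self.patient_ids), len(self.grid_hours)):
            raise ValueError("osi shape inconsistent with ids/grid")
        if np.any(np.diff(self.grid_hours) <= 0):
            raise ValueError("grid_hours must be strictly increasing")
        obs = self.osi[self.mask]
        if obs.size and (not np.all(np.isfinite(obs)) or np.any(obs <= 0)):
            raise ValueError("observed OSI values must be finite and positive")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def grid_days(self) -> np.ndarray:
        return self.grid_hours / 24.0

    def complete_grid(self) -> np.ndarray:
        """Boolean per patient: every gridpoint observed."""
        return self.mask.all(axis=1)

    def copy(self) -> "TrajectoryMatrix":
        return TrajectoryMatrix(
            self.patient_ids.copy(), self.grid_hours.copy(), self.osi.copy(), self.mask.copy()
        )

    def to_long(self, drop_missing: bool = True) -> pd.DataFrame:
        """Long format (patient_id, time_h, osi); unobserved cells dropped by default."""
        n, t = self.osi.shape
        df = pd.DataFrame(
            {
                "patient_id": np.repeat(self.patient_ids, t),
                "time_h": np.tile(self.grid_hours, n),
                "osi": self.osi.ravel(),
            }
        )
        if drop_missing:
            df = df[self.mask.ravel()]
        return df.reset_index(drop=True)

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, grid_hours=DEFAULT_GRID_HOURS, value_col: str = "osi"
    ) -> "TrajectoryMatrix":
        grid = np.asarray(grid_hours, dtype=float)
        ids = np.sort(df["patient_id"].unique())
        wide = df.pivot_table(index="patient_id", columns="time_h", values=value_col, aggfunc="first")
        wide = wide.reindex(index=ids, columns=grid)
        return cls(ids, grid, wide.to_numpy())


def subset_rows(tm: TrajectoryMatrix, keep: np.ndarray) -> TrajectoryMatrix:
    """Row subset by boolean mask or index array, preserving order."""
    return TrajectoryMatrix(
        tm.patient_ids[keep], tm.grid_hours.copy(), tm.osi[keep], tm.mask[keep]
    )
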