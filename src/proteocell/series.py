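"""Timestamped measurement series used by every fitting stage.

A :class:`MeasurementSeries` holds either fluid-phase protein concentrations
(ug/mL) or areal attached-cell counts (cells/cm^2), with optional replicate
standard deviations.  Synthetic series generated in-package additionally
carry the noiseless ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

VALID_LABELS = ("adsorption", "desorption", "cell_culture")


@dataclass
class MeasurementSeries:
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray  # ug/mL or cells/cm^2, >= 0
    sd: Optional[np.ndarray] = None
    label: str = "adsorption"
    truth: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1D arrays of equal length")
        if self.times.size < 1:
            raise ValueError("a measurement series needs at least one point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("measurement values must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise ValueError("sd must match times in shape")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times, "value": self.values})
        if self.sd is not None:
            df["sd"] = self.sd
        df["label"] = self.label
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "MeasurementSeries":
        """Read a series from a tidy CSV with columns time_h, value[, sd, label]."""
        df = pd.read_csv(path)
        if label is not None and "label" in df.columns:
            df = df[df["label"] == label]
        lab = label or (str(df["label"].iloc[0]) if "label" in df.columns else "adsorption")
        df = df.sort_values("time_h")
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df["time_h"].to_numpy(), df["value"].to_numpy(), sd=sd, label=lab)
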