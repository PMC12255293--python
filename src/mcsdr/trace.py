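"""Time-series container for simulated concentrations and fluorescence signals."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Trace", "write_traces_csv", "read_traces_csv"]


@dataclass
class Trace:
    """A strictly increasing time grid with per-time values and metadata.

    ``meta`` records the provenance a downstream fit or metric needs:
    concentrations, variant label, model, seed, unit ("M" or "au").
    """

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.times.size

    @property
    def endpoint(self) -> float:
        return float(self.values[-1])

    def with_values(self, values: np.ndarray, **meta) -> "Trace":
        return Trace(self.times.copy(), np.asarray(values, dtype=float), {**self.meta, **meta})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "value": self.values,
                "unit": self.meta.get("unit", ""),
                "variant": self.meta.get("variant", ""),
                "replicate": self.meta.get("replicate", 0),
                "label": self.meta.get("label", ""),
            }
        )


def write_traces_csv(traces: Iterable[Trace], path: str | Path) -> None:
    pd.concat([t.to_frame() for t in traces], ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[Trace]:
    """Group rows by (variant, replicate, label) back into Trace objects."""
    df = pd.read_csv(path, keep_default_na=False)
    traces = []
    for (variant, replicate, label), grp in df.groupby(["variant", "replicate", "label"], sort=False):
        grp = grp.sort_values("time_s")
        unit = str(grp["unit"].iloc[0]) if "unit" in grp else ""
        traces.append(
            Trace(
                grp["time_s"].to_numpy(),
                grp["value"].to_numpy(),
                {"variant": variant, "replicate": replicate, "label": label, "unit": unit},
            )
        )
    return traces
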