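"""Per-subject multivariate ROI time-series container and tabular I/O.

A subject is a T x R matrix of BOLD time courses, one column per region of
interest, sampled every ``tr_seconds`` seconds (the scanner repetition time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical 8-node default-mode-network region labels: posterior cingulate,
#: medial prefrontal, bilateral inferior parietal, bilateral inferior
#: temporal, bilateral hippocampal formation.
DEFAULT_NODE_LABELS: tuple[str, ...] = (
    "PCC", "MPFC", "lIPC", "rIPC", "lITC", "rITC", "lHC", "rHC",
)

#: Nodes with the widest causal interactions; IPC is bilateral so it
#: contributes two labels.
DEFAULT_HUB_LABELS: tuple[str, ...] = ("PCC", "MPFC", "lIPC", "rIPC")


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """T x R matrix of ROI time courses for one subject.

    Parameters
    ----------
    values : ndarray, shape (T, R)
        One row per time point, one column per region.
    node_labels : tuple of str
        Region names, one per column; must be unique.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    """

    values: np.ndarray
    node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D (T x R) array")
        t, r = vals.shape
        if t < 1 or r < 1:
            raise ValueError("values must have at least one row and column")
        if len(self.node_labels) != r:
            raise ValueError(
                f"{len(self.node_labels)} labels for {r} columns"
            )
        if len(set(self.node_labels)) != r:
            raise ValueError("node labels must be unique")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values contain non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        """Return the time course of one region by label."""
        try:
            idx = self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None
        return self.values[:, idx]

    def with_values(self, values: np.ndarray) -> "TimeSeriesMatrix":
        """Copy of this matrix with replaced values (labels/TR kept)."""
        return replace(self, values=values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.node_labels))

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        """Write as plain tabular text, header = node labels."""
        # %.17g keeps IEEE doubles exact through the text round trip
        self.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, tr_seconds: float = 2.0
    ) -> "TimeSeriesMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            node_labels=tuple(str(c) for c in frame.columns),
            tr_seconds=tr_seconds,
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, tr_seconds: float = 2.0, sep: str | None = None
    ) -> "TimeSeriesMatrix":
        """Read a TSV/CSV time-series table (separator sniffed if not given)."""
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        frame = pd.read_csv(path, sep=sep)
        return cls.from_frame(frame, tr_seconds=tr_seconds)
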