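"""Per-subject trial data containers.

Missing values are encoded as NaN in the float arrays (``None`` in
record form).  The continuous component ``y`` is on the analysis scale;
the binary component ``b`` is 1 when its criterion is met.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SubjectRecord", "TrialData"]


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    z: int  # arm indicator, 0 = control, 1 = treatment
    y: Optional[float]  # continuous component, None = missing
    b: Optional[int]  # binary component (1 = criterion met), None = missing


@dataclass
class TrialData:
    """Column-oriented trial dataset (ids, arm, continuous, binary).

    ``y`` and ``b`` are float arrays with NaN marking missing components.
    """

    ids: np.ndarray
    z: np.ndarray
    y: np.ndarray
    b: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.z = np.asarray(self.z, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.ids)
        if not (len(self.z) == len(self.y) == len(self.b) == n):
            raise ValueError("ids, z, y, b must have equal length")
        if n and not np.isin(self.z, (0, 1)).all():
            bad = np.unique(self.z[~np.isin(self.z, (0, 1))])
            raise ValueError(f"arm indicator must be 0 or 1, got {bad.tolist()}")
        ob = ~np.isnan(self.b)
        if ob.any() and not np.isin(self.b[ob], (0.0, 1.0)).all():
            raise ValueError("binary component must be 0, 1 or missing")

    @property
    def n(self) -> int:
        return len(self.ids)

    def n_arm(self, arm: int) -> int:
        return int(np.sum(self.z == arm))

    @classmethod
    def from_records(cls, records, meta: dict | None = None) -> "TrialData":
        recs = list(records)
        return cls(
            ids=[r.id for r in recs],
            z=[r.z for r in recs],
            y=[np.nan if r.y is None else r.y for r in recs],
            b=[np.nan if r.b is None else r.b for r in recs],
            meta=meta or {},
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: dict | None = None) -> "TrialData":
        return cls(
            ids=df["id"].to_numpy(dtype=object),
            z=df["arm"].to_numpy(),
            y=df["y"].to_numpy(dtype=float),
            b=df["b"].to_numpy(dtype=float),
            meta=meta or {},
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "arm": self.z, "y": self.y, "b": self.b}
        )

    def records(self) -> list[SubjectRecord]:
        out = []
        for i in range(self.n):
            y = None if np.isnan(self.y[i]) else float(self.y[i])
            b = None if np.isnan(self.b[i]) else int(self.b[i])
            out.append(SubjectRecord(str(self.ids[i]), int(self.z[i]), y, b))
        return out

    def subset(self, mask) -> "TrialData":
        mask = np.asarray(mask)
        return TrialData(
            self.ids[mask], self.z[mask], self.y[mask], self.b[mask], dict(self.meta)
        )
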