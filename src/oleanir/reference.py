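"""Reference (wet-chemistry) antioxidant values: the y-block.

One :class:`ReferenceValues` holds the per-sample antioxidant capacity,
in mM Trolox equivalents, measured by a single assay (DPPH, ABTS or
ORAC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ASSAYS = ("DPPH", "ABTS", "ORAC")

__all__ = ["ReferenceValues", "ASSAYS"]


@dataclass
class ReferenceValues:
    """Per-sample antioxidant capacity (mM Trolox) for one assay."""

    assay: str
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference values must be finite")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(self.values.size)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.size:
            raise ValueError("one sample_id required per value")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def subset(self, indices) -> "ReferenceValues":
        idx = np.asarray(indices, dtype=int)
        return ReferenceValues(
            assay=self.assay,
            values=self.values[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            name=self.assay,
        )

    @classmethod
    def from_series(cls, s: pd.Series, assay: str | None = None) -> "ReferenceValues":
        return cls(
            assay=assay or str(s.name),
            values=s.to_numpy(dtype=float),
            sample_ids=[str(i) for i in s.index],
        )
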