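"""Container for NIR spectra sets.

A :class:`SpectraSet` is the X-block of every chemometric step in this
package: a matrix of absorbance values (samples x wavelengths) together
with a strictly descending wavenumber axis in cm^-1, matching the
convention of FT-NIR instruments that scan from high to low wavenumber
(750-2500 nm, i.e. 13,333-4000 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectraSet"]


@dataclass
class SpectraSet:
    """NIR absorbance spectra for a set of samples.

    Parameters
    ----------
    wavenumbers
        Strictly descending axis in cm^-1.
    absorbance
        Matrix of shape ``(n_samples, n_wavenumbers)``; no missing values.
    sample_ids
        Unique sample identifiers, one per row.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"axis has {self.wavenumbers.size} wavenumbers"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) < 0):
            raise ValueError("wavenumber axis must be strictly descending")
        if not np.all(np.isfinite(self.absorbance)):
            rows, cols = np.nonzero(~np.isfinite(self.absorbance))
            raise ValueError(
                f"non-finite absorbance at row {rows[0]}, column {cols[0]}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(self.n_samples)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("one sample_id required per spectrum row")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    def grid_step(self, rtol: float = 1e-6) -> float:
        """Uniform (negative) step of the axis; error if non-uniform."""
        steps = np.diff(self.wavenumbers)
        if steps.size == 0:
            raise ValueError("axis has a single point; no step defined")
        if not np.allclose(steps, steps[0], rtol=rtol, atol=abs(steps[0]) * rtol):
            raise ValueError("wavenumber grid is not uniform")
        return float(steps[0])

    def copy_with(self, absorbance: np.ndarray) -> "SpectraSet":
        """New set with the same axis and ids but replaced absorbance."""
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=np.asarray(absorbance, dtype=float).copy(),
            sample_ids=list(self.sample_ids),
        )

    def subset(self, indices) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.absorbance,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.wavenumbers,
        )
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectraSet":
        return cls(
            wavenumbers=np.asarray(df.columns, dtype=float),
            absorbance=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraSet):
            return NotImplemented
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
            and self.sample_ids == other.sample_ids
        )
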