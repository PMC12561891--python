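"""Pearson correlation of phenolic compounds with assay values.

Builds the compound x assay correlation grid with two-level
significance marking: ** for p < 0.01, * for 0.01 <= p < 0.05, blank
otherwise. Significance uses the standard t-test for a Pearson
correlation (t with n-2 degrees of freedom, two-sided). No
multiple-testing correction is applied by default; a Bonferroni option
is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson_r", "stars", "CorrelationTable", "correlation_table"]


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-test p-value."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ValueError("inputs differ in length")
    if xv.size < 3:
        raise ValueError("need at least 3 pairs")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


def stars(p_value: float) -> str:
    """Two-level significance marker: ** p<0.01, * p<0.05, else blank."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p-value must be in [0, 1]")
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationTable:
    """Compound x assay grid of r, p and significance stars."""

    r: pd.DataFrame  # compounds x assays
    p: pd.DataFrame
    stars: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """r values with significance stars appended, as printed tables do."""
        out = self.r.round(3).astype(str)
        return out + self.stars

    def to_csv(self, path) -> None:
        long = (
            self.r.stack().rename("r").to_frame()
            .join(self.p.stack().rename("p_value"))
            .join(self.stars.stack().rename("stars"))
            .reset_index(names=["compound", "assay"])
        )
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorrelationTable":
        long = pd.read_csv(path, keep_default_na=False)
        long["stars"] = long["stars"].astype(str)
        r = long.pivot(index="compound", columns="assay", values="r")
        p = long.pivot(index="compound", columns="assay", values="p_value")
        s = long.pivot(index="compound", columns="assay", values="stars")
        order = long["compound"].drop_duplicates().tolist()
        cols = long["assay"].drop_duplicates().tolist()
        return cls(r=r.loc[order, cols].astype(float),
                   p=p.loc[order, cols].astype(float),
                   stars=s.loc[order, cols])


def correlation_table(
    profiles: pd.DataFrame,
    assay_values: dict,
    *,
    bonferroni: bool = False,
) -> CorrelationTable:
    """Correlate every compound column with every assay's values.

    ``assay_values`` maps assay name to a ReferenceValues (or a Series
    indexed by sample_id). Sample ids must align across all tables.
    ``bonferroni=True`` multiplies p-values by the number of cells
    before starring.
    """
    profile_ids = [str(i) for i in profiles.index]
    series = {}
    for assay, ref in assay_values.items():
        s = ref.to_series() if hasattr(ref, "to_series") else pd.Series(ref)
        ids = [str(i) for i in s.index]
        if ids != profile_ids:
            missing = sorted(set(profile_ids) ^ set(ids))
            raise ValueError(
                f"sample ids for assay {assay} do not match profiles; "
                f"offenders: {missing[:5]}"
            )
        series[assay] = s.to_numpy(dtype=float)
    assays = pd.Index(list(series), name="assay")
    compounds = pd.Index(list(profiles.columns), name="compound")
    r = pd.DataFrame(index=compounds, columns=assays, dtype=float)
    p = pd.DataFrame(index=compounds, columns=assays, dtype=float)
    n_cells = len(compounds) * len(assays)
    for compound in compounds:
        for assay in assays:
            rv, pv = pearson_r(profiles[compound].to_numpy(dtype=float),
                               series[assay])
            if bonferroni:
                pv = min(1.0, pv * n_cells)
            r.loc[compound, assay] = rv
            p.loc[compound, assay] = pv
    s = p.map(stars)
    return CorrelationTable(r=r, p=p, stars=s)
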