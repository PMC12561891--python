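#!/usr/bin/env python
"""Correlate phenolic compound concentrations with assay values.

Builds the compound x assay Pearson correlation grid with two-level
significance stars (** p<0.01, * p<0.05) and writes both the long-form
table and the formatted grid to results/tables/.

Requires 01_simulate_dataset.py first.
"""

from pathlib import Path

from oleanir import io as oio
from oleanir.correlate import correlation_table
from oleanir.reference import ASSAYS

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = oio.read_profiles_csv(DATA / "profiles.csv")
    refs = {a: oio.read_reference_csv(DATA / f"references_{a}.csv")
            for a in ASSAYS}
    table = correlation_table(profiles, refs)
    table.to_csv(OUT / "correlations.csv")
    formatted = table.formatted()
    formatted.to_csv(OUT / "correlations_formatted.csv")
    print(formatted.to_string())


if __name__ == "__main__":
    main()
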