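#!/usr/bin/env python
"""Observed-vs-predicted diagnostics for the winning pretreatments.

For each assay's best pretreatment (from grid_winners.csv) re-runs the
evaluation, fits the observed-vs-predicted line on the prediction set
and writes per-sample predictions plus a slope/intercept/R-squared
summary to results/tables/.

Requires 01_simulate_dataset.py and 02_pretreatment_grid.py first.
"""

from pathlib import Path

import pandas as pd

from oleanir import io as oio
from oleanir.evaluate import evaluate_model, observed_predicted_fit
from oleanir.pls import fit_pls, predict
from oleanir.preprocess import apply_pretreatment
from oleanir.split import split_sets

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spectra = oio.read_spectra_csv(DATA / "spectra.csv")
    winners = pd.read_csv(OUT / "grid_winners.csv")

    rows = []
    for _, w in winners.iterrows():
        assay, code = w["assay"], w["pretreatment"]
        ref = oio.read_reference_csv(DATA / f"references_{assay}.csv")
        report = evaluate_model(spectra, ref, code, max_lv=20)

        pretreated = apply_pretreatment(spectra, code)
        split = split_sets(pretreated, 0.7)
        model = fit_pls(pretreated.subset(split.cv_indices),
                        ref.subset(split.cv_indices), report.selected_lv)
        pred_set = pretreated.subset(split.prediction_indices)
        observed = ref.subset(split.prediction_indices)
        predicted = predict(model, pred_set)

        per_sample = pd.DataFrame({
            "sample_id": pred_set.sample_ids,
            "observed": observed.values,
            "predicted": predicted,
        })
        per_sample.to_csv(OUT / f"predictions_{assay}.csv", index=False)

        fit = observed_predicted_fit(observed.values, predicted)
        rows.append({
            "assay": assay, "pretreatment": code,
            "latent_variables": report.selected_lv,
            "slope": round(fit.slope, 3),
            "intercept": round(fit.intercept, 3),
            "r_squared": round(fit.r_squared, 3),
            "n_prediction": len(per_sample),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "prediction_fits.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
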