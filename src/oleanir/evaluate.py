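"""Model evaluation: RMSE, RPD, report assembly and pretreatment ranking.

RMSE = sqrt(sum((f - y)^2) / n) over a data set; RPD = SD / RMSE where
SD is the (n-1) standard deviation of that set's reference values.
RPD is interpreted on the conventional bands: >= 3 suitable for quality
control, 2-3 for screening, < 2 not recommended for quantification.

R-squared throughout is the squared Pearson correlation of predicted vs
observed (the scatter-plot definition); the 1 - SSE/SST variant is also
carried in the reports for reference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PretreatmentSpec, apply_pretreatment, parse_pretreatment_code
from .pls import cross_validate, fit_pls, predict
from .reference import ReferenceValues
from .spectra import SpectraSet
from .split import SplitResult, split_sets

__all__ = [
    "rmse",
    "rpd",
    "interpret_rpd",
    "SetMetrics",
    "EvaluationReport",
    "evaluate_model",
    "grid_search",
    "observed_predicted_fit",
    "ObservedPredictedFit",
    "reports_to_dataframe",
    "DEFAULT_GRID_CODES",
]

# The six distinct pretreatment pipelines of the study grid.
DEFAULT_GRID_CODES = (
    "MSC-1.19.5",
    "SNV-2.13.9",
    "MSC-2.19.5",
    "SNV-2.19.5",
    "SNV-2.5.19",
    "MSC-2.5.19",
)


def rmse(predicted, observed) -> float:
    """Root mean square error sqrt(sum((f - y)^2) / n)."""
    f = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if f.size == 0:
        raise ValueError("empty input")
    if f.size != y.size:
        raise ValueError("predicted and observed differ in length")
    return float(np.sqrt(np.mean((f - y) ** 2)))


def rpd(reference_sd: float, rmse_value: float) -> float:
    """Residual predictive deviation SD/RMSE.

    A zero RMSE yields +inf with a warning (perfect fit), not an error.
    """
    if rmse_value < 0:
        raise ValueError("rmse must be >= 0")
    if rmse_value == 0:
        warnings.warn("RMSE is zero; RPD is infinite", RuntimeWarning,
                      stacklevel=2)
        return float("inf")
    return float(reference_sd / rmse_value)


def interpret_rpd(value: float) -> str:
    """Conventional RPD interpretation bands."""
    if not value > 0:
        raise ValueError("RPD must be positive")
    if value >= 3.0:
        return "quality control"
    if value >= 2.0:
        return "screening"
    return "not recommended"


def _pearson_r2(predicted, observed) -> float:
    f = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if f.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(f, y)[0, 1] ** 2)


def _sse_r2(predicted, observed) -> float:
    f = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 0.0
    return 1.0 - float(np.sum((f - y) ** 2)) / sst


@dataclass
class SetMetrics:
    """Per-set evaluation entries (calibration, cv or prediction)."""

    n: int
    r_squared: float
    r_squared_sse: float
    rmse: float
    sd: float
    rpd: float
    rpd_category: str


def _set_metrics(predicted, observed) -> SetMetrics:
    y = np.asarray(observed, dtype=float).ravel()
    err = rmse(predicted, y)
    sd = float(y.std(ddof=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rpd_value = rpd(sd, err)
    return SetMetrics(
        n=y.size,
        r_squared=_pearson_r2(predicted, y),
        r_squared_sse=_sse_r2(predicted, y),
        rmse=err,
        sd=sd,
        rpd=rpd_value,
        rpd_category=interpret_rpd(rpd_value) if rpd_value > 0 else "undefined",
    )


@dataclass
class EvaluationReport:
    """Full evaluation of one pretreatment for one assay."""

    assay: str
    pretreatment: str
    selected_lv: int
    calibration: SetMetrics
    cv: SetMetrics
    prediction: SetMetrics
    paper_mode: bool = False
    training_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        d = dict(d)
        for key in ("calibration", "cv", "prediction"):
            d[key] = SetMetrics(**d[key])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def evaluate_model(
    spectra: SpectraSet,
    reference: ReferenceValues,
    pretreatment: PretreatmentSpec | str | None = None,
    *,
    split: SplitResult | None = None,
    fraction: float = 0.7,
    cv_scheme="loo",
    max_lv: int = 20,
    paper_mode: bool = False,
) -> EvaluationReport:
    """Evaluate one pretreatment end to end.

    Pipeline: pretreat -> Kennard-Stone split on the pretreated spectra
    (unless a split is supplied) -> cross-validated latent-variable
    selection on Set 1 -> per-set metrics. Calibration metrics always
    come from the model fitted on all samples (Set 1+2). In the default
    mode the model scored on Set 2 is refitted on Set 1 only, so the
    prediction set is never seen in training; ``paper_mode=True``
    scores Set 2 with the Set 1+2 calibration model instead,
    reproducing the protocol in which the prediction set is a subset of
    the calibration data. ``training_ids`` records the training samples
    of the model that produced the prediction metrics.
    """
    if spectra.sample_ids != reference.sample_ids:
        raise ValueError("spectra and reference sample_ids are misaligned")
    code = "RAW"
    if pretreatment is not None:
        if isinstance(pretreatment, str):
            pretreatment = parse_pretreatment_code(pretreatment)
        try:
            code = pretreatment.code
        except ValueError:
            code = "CUSTOM"
        spectra = apply_pretreatment(spectra, pretreatment)
    if split is None:
        split = split_sets(spectra, fraction)

    X1, y1 = spectra.subset(split.cv_indices), reference.subset(split.cv_indices)
    X2, y2 = (spectra.subset(split.prediction_indices),
              reference.subset(split.prediction_indices))

    curve = cross_validate(X1, y1, max_lv=max_lv, scheme=cv_scheme)
    lv = curve.selected_lv
    cv_metrics = _set_metrics(curve.predictions[:, lv - 1], y1.values)

    cal_model = fit_pls(spectra, reference, lv)
    cal_metrics = _set_metrics(predict(cal_model, spectra), reference.values)
    pred_model = cal_model if paper_mode else fit_pls(X1, y1, lv)
    pred_metrics = _set_metrics(predict(pred_model, X2), y2.values)

    return EvaluationReport(
        assay=reference.assay,
        pretreatment=code,
        selected_lv=lv,
        calibration=cal_metrics,
        cv=cv_metrics,
        prediction=pred_metrics,
        paper_mode=paper_mode,
        training_ids=list(pred_model.training_ids),
    )


def grid_search(
    spectra: SpectraSet,
    reference: ReferenceValues,
    codes=None,
    *,
    split: SplitResult | None = None,
    fraction: float = 0.7,
    cv_scheme="loo",
    max_lv: int = 20,
    paper_mode: bool = False,
) -> list[EvaluationReport]:
    """Evaluate a list of pretreatment codes and rank them.

    Ranking is by prediction RPD (descending), then prediction
    R-squared (descending), then RMSEP (ascending). With ``split=None``
    each code gets its own Kennard-Stone split on its pretreated
    spectra.
    """
    codes = list(codes) if codes is not None else list(DEFAULT_GRID_CODES)
    if not codes:
        raise ValueError("need at least one pretreatment code")
    reports, errors = [], []
    for code in codes:
        try:
            reports.append(evaluate_model(
                spectra, reference, code, split=split, fraction=fraction,
                cv_scheme=cv_scheme, max_lv=max_lv, paper_mode=paper_mode,
            ))
        except Exception as exc:  # aggregate; re-raise if nothing worked
            errors.append(f"{code}: {exc}")
    if not reports:
        raise RuntimeError("all pretreatment codes failed: " + "; ".join(errors))
    reports.sort(key=lambda r: (-r.prediction.rpd, -r.prediction.r_squared,
                                r.prediction.rmse))
    return reports


@dataclass
class ObservedPredictedFit:
    """OLS line of predicted vs observed values (scatter diagnostics)."""

    slope: float
    intercept: float
    r_squared: float


def observed_predicted_fit(observed, predicted) -> ObservedPredictedFit:
    """Regress predicted on observed: slope, intercept, R-squared.

    A perfect model gives slope 1, intercept 0, R-squared 1.
    """
    y = np.asarray(observed, dtype=float).ravel()
    f = np.asarray(predicted, dtype=float).ravel()
    if y.size != f.size or y.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if y.std() == 0:
        raise ValueError("observed values have zero variance")
    slope, intercept = np.polyfit(y, f, 1)
    return ObservedPredictedFit(slope=float(slope), intercept=float(intercept),
                                r_squared=_pearson_r2(f, y))


def reports_to_dataframe(reports) -> pd.DataFrame:
    """Flatten evaluation reports into a study-style results table."""
    rows = []
    for r in reports:
        for set_name, m in (("Set 1+2", r.calibration),
                            ("Set 1", r.cv), ("Set 2", r.prediction)):
            rows.append({
                "assay": r.assay,
                "pretreatment": r.pretreatment,
                "data_set": set_name,
                "n": m.n,
                "selected_lv": r.selected_lv,
                "r_squared": m.r_squared,
                "rmse": m.rmse,
                "rpd": m.rpd,
                "rpd_category": m.rpd_category,
            })
    return pd.DataFrame(rows)
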