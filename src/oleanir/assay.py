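"""Quantification math of the antioxidant assays.

Covers the two area-under-curve statistics used to summarise a
radical-decay kinetic read (the full normalised sum and the simplified
start/end ratio), the Trolox standard curve (ordinary least squares),
and conversion of a sample response to mM Trolox equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import KineticCurve

__all__ = [
    "StandardCurve",
    "TroloxEquivalent",
    "auc_full",
    "auc_simplified",
    "fit_standard_curve",
    "to_trolox_equivalent",
]


def _signal(curve) -> np.ndarray:
    """Accept a KineticCurve or any 1-D sequence of readings."""
    values = np.asarray(getattr(curve, "signal", curve), dtype=float).ravel()
    if values.size == 0:
        raise ValueError("curve has no readings")
    return values


def auc_full(curve: KineticCurve) -> float:
    """Normalised area under the decay curve: sum_i F_i / F_1.

    Includes the leading F_1/F_1 = 1 term, so a constant signal over n
    readings gives exactly n.
    """
    signal = _signal(curve)
    f1 = signal[0]
    if f1 == 0:
        raise ZeroDivisionError("first reading F1 is zero")
    return float(np.sum(signal / f1))


def auc_simplified(curve: KineticCurve, direction: str = "start_over_end") -> float:
    """Simplified AUC using only the first and last readings.

    ``start_over_end`` (the default) returns F_1/F_n; ``end_over_start``
    returns F_n/F_1. Both readings of the ratio are exposed because the
    simplified statistic is defined only up to this orientation.
    """
    signal = _signal(curve)
    f1, fn = signal[0], signal[-1]
    if direction == "start_over_end":
        if fn == 0:
            raise ZeroDivisionError("final reading Fn is zero")
        return float(f1 / fn)
    if direction == "end_over_start":
        if f1 == 0:
            raise ZeroDivisionError("first reading F1 is zero")
        return float(fn / f1)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class StandardCurve:
    """Fitted Trolox standard curve: response = slope*conc + intercept."""

    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    units: str = "mM"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.units not in ("mM", "uM"):
            raise ValueError(f"unknown concentration units {self.units!r}")


def fit_standard_curve(
    concentrations, responses, units: str = "mM"
) -> StandardCurve:
    """Ordinary least squares line through standard points.

    ``units`` is the concentration unit of the points ("mM" for the
    DPPH/ABTS curves, "uM" for the ORAC fluorescein curve).
    """
    conc = np.asarray(concentrations, dtype=float).ravel()
    resp = np.asarray(responses, dtype=float).ravel()
    if conc.size != resp.size:
        raise ValueError("concentrations and responses differ in length")
    if conc.size < 2:
        raise ValueError("need at least two standard points")
    if np.ptp(conc) == 0:
        raise ValueError("all standard concentrations identical: singular fit")
    slope, intercept = np.polyfit(conc, resp, 1)
    fitted = slope * conc + intercept
    sse = float(np.sum((resp - fitted) ** 2))
    sst = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    return StandardCurve(conc, resp, float(slope), float(intercept), r2, units)


@dataclass
class TroloxEquivalent:
    """Antioxidant capacity expressed relative to the Trolox standard."""

    value: float  # mM Trolox
    assay: str
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("value must be finite")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")


def to_trolox_equivalent(
    response: float,
    curve: StandardCurve,
    dilution_factor: float = 1.0,
    assay: str = "DPPH",
    blank_response: float | None = None,
) -> TroloxEquivalent:
    """Invert the standard curve and apply the extract dilution.

    ((response - intercept) / slope) * dilution_factor, converted to mM
    if the curve was fitted in µM. ``blank_response`` is subtracted from
    the response first when provided (net-response quantification);
    default is no blank correction.
    """
    scale = max(1.0, abs(curve.intercept), float(np.abs(curve.responses).max()))
    if abs(curve.slope) < 1e-12 * scale:
        raise ZeroDivisionError("standard curve slope is (numerically) zero")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    r = response if blank_response is None else response - blank_response
    conc = (r - curve.intercept) / curve.slope * dilution_factor
    if curve.units == "uM":
        conc /= 1000.0
    return TroloxEquivalent(value=float(conc), assay=assay,
                            dilution_factor=dilution_factor)
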