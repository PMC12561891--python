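"""Spectral pretreatments and the pretreatment pipeline code parser.

Implements the five pretreatments used in NIR chemometric practice for
this kind of data — Savitzky-Golay smoothing (SGS), first and second
Savitzky-Golay derivatives, multiplicative scatter correction (MSC) and
standard normal variate (SNV) — plus the compact "SCATTER-a.b.c"
pipeline notation, where ``a`` is the derivative order, ``b`` the
derivative window (points) and ``c`` the smoothing window (points).

A coded pipeline is applied in the order derivative -> smoothing ->
scatter correction; ``scatter_first=True`` swaps scatter correction to
the front for sensitivity analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

__all__ = [
    "PretreatmentSpec",
    "parse_pretreatment_code",
    "savitzky_golay",
    "snv",
    "msc",
    "apply_pretreatment",
    "IDENTITY",
]

DEFAULT_POLYORDER = 2

_CODE_RE = re.compile(r"^(MSC|SNV)-(\d+)\.(\d+)\.(\d+)$")


@dataclass(frozen=True)
class PretreatmentSpec:
    """Parsed pretreatment pipeline.

    ``deriv_order`` 0 means no derivative stage (and no smoothing
    unless a smoothing window is given); scatter may be "MSC", "SNV" or
    "NONE".
    """

    scatter: str = "NONE"
    deriv_order: int = 0
    deriv_window: int | None = None
    smooth_window: int | None = None
    polyorder: int = DEFAULT_POLYORDER

    def __post_init__(self) -> None:
        if self.scatter not in ("MSC", "SNV", "NONE"):
            raise ValueError(f"unknown scatter correction {self.scatter!r}")
        if self.deriv_order not in (0, 1, 2):
            raise ValueError("deriv_order must be 0, 1 or 2")
        for name, w in (("deriv_window", self.deriv_window),
                        ("smooth_window", self.smooth_window)):
            if w is not None and (w < 3 or w % 2 == 0):
                raise ValueError(f"{name} must be odd and >= 3, got {w}")
            if w is not None and w < self.polyorder + 1:
                raise ValueError(f"{name} must be >= polyorder + 1")
        if self.deriv_order > 0 and self.deriv_window is None:
            raise ValueError("derivative stage requires deriv_window")
        if self.deriv_order > self.polyorder:
            raise ValueError("deriv_order must be <= polyorder")

    @property
    def code(self) -> str:
        """Compact code, defined for coded (scatter + derivative) specs."""
        if self.scatter == "NONE" or self.deriv_order == 0:
            raise ValueError("only SCATTER-a.b.c pipelines have a code")
        return (f"{self.scatter}-{self.deriv_order}"
                f".{self.deriv_window}.{self.smooth_window}")


IDENTITY = PretreatmentSpec()


def parse_pretreatment_code(code: str) -> PretreatmentSpec:
    """Parse a "SCATTER-a.b.c" code (e.g. "SNV-2.19.5").

    a = derivative order (1 or 2), b = derivative window points,
    c = smoothing window points. Raises ValueError with the offending
    position for malformed codes.
    """
    m = _CODE_RE.match(code.strip())
    if not m:
        raise ValueError(
            f"malformed pretreatment code {code!r}: expected "
            "'MSC-a.b.c' or 'SNV-a.b.c' (at position 0)"
        )
    scatter, a, b, c = m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4))
    if a not in (1, 2):
        raise ValueError(
            f"derivative order must be 1 or 2 in {code!r} (at position {m.start(2)})"
        )
    for val, pos, name in ((b, m.start(3), "derivative window"),
                           (c, m.start(4), "smoothing window")):
        if val < 3 or val % 2 == 0:
            raise ValueError(
                f"{name} must be odd and >= 3 in {code!r} (at position {pos})"
            )
    return PretreatmentSpec(scatter=scatter, deriv_order=a,
                            deriv_window=b, smooth_window=c)


def savitzky_golay(
    spectra: SpectraSet,
    window: int,
    polyorder: int = DEFAULT_POLYORDER,
    deriv_order: int = 0,
) -> SpectraSet:
    """Savitzky-Golay smoothing / derivative along the wavenumber axis.

    Derivatives are with respect to wavenumber (per cm^-1), using the
    uniform grid step; the axis being stored descending is accounted
    for. Edges are handled by evaluating the edge-fitted polynomial, so
    the output has the same length as the input.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv_order > polyorder:
        raise ValueError("deriv_order must be <= polyorder")
    step = spectra.grid_step()  # raises on non-uniform grid; negative here
    out = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv_order, delta=abs(step), axis=1, mode="interp",
    )
    if step < 0 and deriv_order % 2 == 1:
        out = -out
    return spectra.copy_with(out)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre and scale each spectrum (row).

    Output rows have mean 0 and sample standard deviation 1 (n-1
    denominator).
    """
    x = spectra.absorbance
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        raise ValueError(
            f"constant spectrum for sample {spectra.sample_ids[flat[0]]!r}: "
            "SNV undefined"
        )
    return spectra.copy_with((x - mean) / sd)


def msc(
    spectra: SpectraSet,
    reference: np.ndarray | None = None,
    b_tol: float = 1e-12,
) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference (x ~ a + b*ref, OLS)
    and corrected to (x - a)/b, removing per-sample additive and
    multiplicative scatter. The reference defaults to the mean spectrum
    of the input set.
    """
    x = spectra.absorbance
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != spectra.n_wavenumbers:
        raise ValueError("reference length does not match the wavenumber axis")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("reference spectrum is constant: MSC undefined")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    small = np.nonzero(np.abs(b) < b_tol)[0]
    if small.size:
        raise ValueError(
            f"multiplicative coefficient ~0 for sample "
            f"{spectra.sample_ids[small[0]]!r}: MSC undefined"
        )
    a = x.mean(axis=1) - b * ref.mean()
    return spectra.copy_with((x - a[:, None]) / b[:, None])


def apply_pretreatment(
    spectra: SpectraSet,
    spec: PretreatmentSpec | str,
    *,
    scatter_first: bool = False,
    msc_reference: np.ndarray | None = None,
) -> SpectraSet:
    """Run a full pretreatment pipeline on a spectra set.

    Stage order is derivative (SG, window b) -> smoothing (SG, window
    c, derivative 0) -> scatter correction; ``scatter_first`` moves the
    scatter correction to the front. Errors from a stage are re-raised
    with the stage name attached.
    """
    if isinstance(spec, str):
        spec = parse_pretreatment_code(spec)

    def _scatter(s: SpectraSet) -> SpectraSet:
        if spec.scatter == "SNV":
            return snv(s)
        if spec.scatter == "MSC":
            return msc(s, reference=msc_reference)
        return s

    stages: list[tuple[str, object]] = []
    if scatter_first and spec.scatter != "NONE":
        stages.append(("scatter", _scatter))
    if spec.deriv_order > 0:
        stages.append(("derivative", lambda s: savitzky_golay(
            s, spec.deriv_window, spec.polyorder, spec.deriv_order)))
    if spec.smooth_window is not None:
        stages.append(("smoothing", lambda s: savitzky_golay(
            s, spec.smooth_window, spec.polyorder, 0)))
    if not scatter_first and spec.scatter != "NONE":
        stages.append(("scatter", _scatter))

    out = spectra
    for name, fn in stages:
        try:
            out = fn(out)
        except Exception as exc:
            raise type(exc)(f"pretreatment stage '{name}': {exc}") from exc
    return out
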