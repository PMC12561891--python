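"""Synthetic olive-leaf dataset generator.

Emulates the statistical structure of a 120-sample olive-leaf powder
study: per-sample phenolic profiles (oleuropein dominant), antioxidant
reference values in mM Trolox for the DPPH, ABTS and ORAC assays,
FT-NIR absorbance spectra over 13,333-4000 cm^-1 built from Gaussian
absorption bands that are linear (Beer-Lambert style) in the phenolic
concentrations, and radical-decay kinetic curves for the assay math.

The generative model, in order:

1. Phenolic concentrations (mg/g dry leaf) drawn per compound from
   independent log-normal distributions.
2. Assay reference values as an affine function of the concentrations
   plus Gaussian measurement noise, optionally clipped to the assay's
   observed range. Default weights reproduce the sign pattern seen in
   olive-leaf correlation studies: oleuropein and hydroxytyrosol load
   positively on DPPH and ORAC, verbascoside and hydroxytyrosol
   hexoside on ABTS, apigenin-7-glucoside weakly negatively on ABTS.
3. Spectra as sums of Gaussian bands centred on the seven assigned
   olive-leaf NIR bands (C-H first overtones at 5785 and 5677 cm^-1,
   C=O second overtone at 5222, O-H at 4861 and 4404, C-H combination
   at 4337, CH2 bending at 4262), degraded by per-sample multiplicative
   and additive scatter, a sloping baseline and white noise.
4. Kinetic curves as exponential signal decay whose rate is slowed by
   antioxidant (Trolox-equivalent) concentration.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reference import ASSAYS, ReferenceValues
from .spectra import SpectraSet

__all__ = [
    "COMPOUNDS",
    "Band",
    "BandLibrary",
    "AssayDesign",
    "GeneratorConfig",
    "KineticCurve",
    "KineticParams",
    "generate_profiles",
    "assay_weights",
    "generate_reference_values",
    "clean_spectra",
    "generate_spectra",
    "generate_kinetic_curve",
    "generate_dataset",
    "default_band_library",
    "matrix_spectrum",
    "MATRIX_BANDS",
]

COMPOUNDS = (
    "oleuropein",
    "hydroxytyrosol",
    "hydroxytyrosol_hexoside",
    "verbascoside",
    "apigenin_7_glucoside",
)

# (mean mg/g dry leaf, coefficient of variation) per compound. Oleuropein is
# the predominant phenolic of olive leaf (up to tens of mg/g dry weight);
# the minor phenolics sit one order of magnitude lower.
DEFAULT_COMPOUND_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "oleuropein": (30.0, 0.35),
    "hydroxytyrosol": (3.5, 0.40),
    "hydroxytyrosol_hexoside": (2.0, 0.40),
    "verbascoside": (2.5, 0.45),
    "apigenin_7_glucoside": (0.8, 0.40),
}


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``loadings`` maps compound name to absorbance per mg/g at the band
    centre.
    """

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    loadings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band at {self.center} cm^-1 has non-positive width")


BandLibrary = list[Band]

# The seven assigned olive-leaf NIR bands. Loadings are chosen so the
# compound -> spectrum map has full column rank (each compound has a
# distinct band signature) while keeping the dominant assignments:
# secoiridoid C=O at 5222 (oleuropein), O-H bands at 4861/4404
# (hydroxytyrosol, verbascoside, glycosides), C-H overtones shared.
_DEFAULT_BANDS: tuple[tuple[float, dict[str, float]], ...] = (
    (5785.0, {"oleuropein": 0.012, "hydroxytyrosol": 0.010,
              "hydroxytyrosol_hexoside": 0.008, "verbascoside": 0.006,
              "apigenin_7_glucoside": 0.010}),
    (5677.0, {"oleuropein": 0.010, "hydroxytyrosol": 0.006,
              "hydroxytyrosol_hexoside": 0.006, "verbascoside": 0.004,
              "apigenin_7_glucoside": 0.012}),
    (5222.0, {"oleuropein": 0.015, "hydroxytyrosol_hexoside": 0.002}),
    (4861.0, {"oleuropein": 0.004, "hydroxytyrosol": 0.014,
              "hydroxytyrosol_hexoside": 0.008, "verbascoside": 0.012,
              "apigenin_7_glucoside": 0.010}),
    (4404.0, {"oleuropein": 0.003, "hydroxytyrosol": 0.006,
              "hydroxytyrosol_hexoside": 0.006, "verbascoside": 0.016}),
    (4337.0, {"oleuropein": 0.008, "hydroxytyrosol": 0.004,
              "hydroxytyrosol_hexoside": 0.004, "verbascoside": 0.004,
              "apigenin_7_glucoside": 0.008}),
    (4262.0, {"oleuropein": 0.006, "hydroxytyrosol": 0.002,
              "hydroxytyrosol_hexoside": 0.005, "verbascoside": 0.003,
              "apigenin_7_glucoside": 0.004}),
)

DEFAULT_BAND_WIDTH = 40.0  # cm^-1


def default_band_library(width: float = DEFAULT_BAND_WIDTH) -> BandLibrary:
    """The seven-band olive-leaf library with a common Gaussian width."""
    return [Band(center=c, width=width, loadings=dict(l)) for c, l in _DEFAULT_BANDS]


# Leaf-matrix background: the non-phenolic bulk (cellulose, lignin,
# residual water) that dominates the absorbance of any dried plant
# powder. Shared by all samples; per-sample scatter multiplies it
# together with the compound bands. (center cm^-1, sigma cm^-1,
# relative amplitude).
MATRIX_BANDS: tuple[tuple[float, float, float], ...] = (
    (10300.0, 400.0, 0.10),  # O-H second overtone
    (8400.0, 300.0, 0.15),   # C-H second overtone
    (6900.0, 150.0, 0.50),   # O-H first overtone (water)
    (5600.0, 120.0, 0.40),   # C-H first overtone (cellulose)
    (5180.0, 90.0, 0.60),    # water combination
    (4740.0, 100.0, 0.45),   # O-H/C-O combination (cellulose)
    (4330.0, 80.0, 0.50),    # C-H combination
    (4020.0, 90.0, 0.35),    # C-O/C-C stretch combinations
)


def matrix_spectrum(wavenumbers: np.ndarray, amplitude: float = 1.0) -> np.ndarray:
    """Constant leaf-matrix absorbance spectrum on a given grid."""
    nu = np.asarray(wavenumbers, dtype=float)
    out = np.zeros_like(nu)
    for center, sigma, amp in MATRIX_BANDS:
        out += amp * np.exp(-0.5 * ((nu - center) / sigma) ** 2)
    return amplitude * out


@dataclass(frozen=True)
class AssayDesign:
    """Target statistics and compound weighting for one assay.

    ``shares`` are standardized weights: the contribution of each
    compound to the reference value, expressed in units of that
    compound's own standard deviation. They are converted to raw mg/g
    weights by :func:`assay_weights` so the noise-free values have mean
    ``mean`` and standard deviation ``sd``.
    """

    mean: float  # mM Trolox
    sd: float  # mM Trolox, pre-clipping
    clip_range: tuple[float, float] | None
    shares: dict[str, float]


# Means and ranges follow the study set statistics; the pre-clip SDs for
# DPPH and ABTS are set to range/3.6 so that values live inside the
# observed range (see docs/methods.md on why the printed SDs are not
# attainable inside the printed ranges).
DEFAULT_ASSAY_DESIGNS: dict[str, AssayDesign] = {
    "DPPH": AssayDesign(
        mean=0.69, sd=0.15, clip_range=(0.42, 0.96),
        shares={"oleuropein": 0.55, "hydroxytyrosol": 0.45,
                "hydroxytyrosol_hexoside": 0.15, "verbascoside": 0.01,
                "apigenin_7_glucoside": 0.05},
    ),
    "ABTS": AssayDesign(
        mean=0.74, sd=0.11, clip_range=(0.60, 0.99),
        shares={"oleuropein": 0.02, "hydroxytyrosol": -0.07,
                "hydroxytyrosol_hexoside": 0.30, "verbascoside": 0.40,
                "apigenin_7_glucoside": -0.27},
    ),
    "ORAC": AssayDesign(
        mean=2.72, sd=0.55, clip_range=(0.94, 4.10),
        shares={"oleuropein": 0.65, "hydroxytyrosol": 0.50,
                "hydroxytyrosol_hexoside": -0.06, "verbascoside": -0.20,
                "apigenin_7_glucoside": -0.12},
    ),
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic dataset generator."""

    n_samples: int = 120
    seed: int = 0
    compound_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOUND_DISTRIBUTIONS))
    assay_designs: dict[str, AssayDesign] = field(
        default_factory=lambda: dict(DEFAULT_ASSAY_DESIGNS))
    noise_sd_reference: float = 0.02  # mM Trolox
    # spectra
    wavenumber_start: float = 13333.0
    wavenumber_end: float = 4000.0
    wavenumber_step: float = 4.0
    band_width: float = DEFAULT_BAND_WIDTH
    matrix_amplitude: float = 1.0
    baseline_offset_range: tuple[float, float] = (0.0, 0.05)
    baseline_slope_range: tuple[float, float] = (-0.02, 0.02)
    multiplicative_scatter_sd: float = 0.05
    additive_scatter_sd: float = 0.01
    spectral_noise_sd: float = 2e-4

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.wavenumber_step <= 0:
            raise ValueError("wavenumber_step must be > 0")
        for name, value in (
            ("noise_sd_reference", self.noise_sd_reference),
            ("multiplicative_scatter_sd", self.multiplicative_scatter_sd),
            ("additive_scatter_sd", self.additive_scatter_sd),
            ("spectral_noise_sd", self.spectral_noise_sd),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")

    def wavenumber_grid(self) -> np.ndarray:
        """Descending grid from start down to the last point >= end."""
        return np.arange(self.wavenumber_start, self.wavenumber_end - 1e-9,
                         -self.wavenumber_step)

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # Independent, reproducible stream per generator stage.
    return np.random.default_rng([config.seed, stream])


def generate_profiles(config: GeneratorConfig) -> pd.DataFrame:
    """Draw per-sample phenolic profiles (mg/g dry leaf).

    Returns a DataFrame indexed by ``sample_id`` with one column per
    compound, all nonnegative. Log-normal per compound; a compound with
    coefficient of variation 0 is fixed at its mean.
    """
    rng = _rng(config, 1)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    cols = {}
    for compound in COMPOUNDS:
        mean, cv = config.compound_distributions[compound]
        if mean < 0:
            raise ValueError(f"negative mean for {compound}")
        if cv == 0 or mean == 0:
            cols[compound] = np.full(config.n_samples, mean)
        else:
            sigma2 = math.log1p(cv * cv)
            mu = math.log(mean) - sigma2 / 2.0
            cols[compound] = rng.lognormal(mu, math.sqrt(sigma2), config.n_samples)
    return pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))


def assay_weights(
    config: GeneratorConfig, assay: str
) -> tuple[float, dict[str, float]]:
    """Raw (intercept, per-compound mg/g weights) for one assay.

    Converts the assay design's standardized shares into weights such
    that the noise-free value ``intercept + sum_k w_k c_k`` has the
    design mean and standard deviation under the configured (assumed
    independent) compound distributions.
    """
    if assay not in config.assay_designs:
        raise ValueError(f"unknown assay {assay!r}")
    design = config.assay_designs[assay]
    means, sds, shares = {}, {}, {}
    for compound in COMPOUNDS:
        mean, cv = config.compound_distributions[compound]
        means[compound] = mean
        sds[compound] = mean * cv
        shares[compound] = design.shares.get(compound, 0.0)
    usable = {c: s for c, s in shares.items() if s != 0.0 and sds[c] > 0}
    norm = math.sqrt(sum(s * s for s in usable.values()))
    weights = {c: 0.0 for c in COMPOUNDS}
    if norm > 0:
        scale = design.sd / norm
        for c, s in usable.items():
            weights[c] = scale * s / sds[c]
    intercept = design.mean - sum(weights[c] * means[c] for c in COMPOUNDS)
    return intercept, weights


def generate_reference_values(
    profiles: pd.DataFrame,
    assay: str,
    config: GeneratorConfig,
    *,
    weights: dict[str, float] | None = None,
    intercept: float | None = None,
    noise_sd: float | None = None,
    clip_range: tuple[float, float] | None | str = "default",
) -> ReferenceValues:
    """Reference antioxidant values (mM Trolox) for one assay.

    value_i = intercept + sum_k weight_k * concentration_ik + eps_i with
    eps ~ Normal(0, noise_sd), then clipped to ``clip_range`` (pass
    ``None`` to disable clipping; the default comes from the assay
    design).
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    if len(profiles) == 0:
        raise ValueError("profiles table is empty")
    if weights is None or intercept is None:
        d_intercept, d_weights = assay_weights(config, assay)
        weights = weights if weights is not None else d_weights
        intercept = intercept if intercept is not None else d_intercept
    if noise_sd is None:
        noise_sd = config.noise_sd_reference
    if clip_range == "default":
        clip_range = config.assay_designs[assay].clip_range
    w = np.array([weights.get(c, 0.0) for c in profiles.columns])
    values = intercept + profiles.to_numpy(dtype=float) @ w
    if noise_sd > 0:
        rng = _rng(config, 10 + ASSAYS.index(assay))
        values = values + rng.normal(0.0, noise_sd, values.size)
    if clip_range is not None:
        values = np.clip(values, clip_range[0], clip_range[1])
    return ReferenceValues(assay=assay, values=values,
                           sample_ids=[str(i) for i in profiles.index])


def clean_spectra(
    profiles: pd.DataFrame,
    band_library: BandLibrary,
    wavenumbers: np.ndarray,
) -> np.ndarray:
    """Noise- and scatter-free absorbance matrix (Beer-Lambert mixing)."""
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    lo, hi = wavenumbers.min(), wavenumbers.max()
    n, p = len(profiles), wavenumbers.size
    out = np.zeros((n, p))
    conc = profiles.to_numpy(dtype=float)
    for band in band_library:
        if not (lo <= band.center <= hi):
            raise ValueError(
                f"band centre {band.center} cm^-1 lies outside the grid "
                f"[{lo}, {hi}] cm^-1"
            )
        shape = np.exp(-0.5 * ((wavenumbers - band.center) / band.width) ** 2)
        loading = np.array([band.loadings.get(c, 0.0) for c in profiles.columns])
        out += np.outer(conc @ loading, shape)
    return out


def generate_spectra(
    profiles: pd.DataFrame,
    config: GeneratorConfig,
    band_library: BandLibrary | None = None,
    *,
    return_clean: bool = False,
):
    """Observed NIR spectra: clean mixture degraded by scatter and noise.

    observed_i = m_i * (matrix + clean_i) + a_i + baseline_i(nu) + noise,
    with m_i ~ Normal(1, multiplicative_scatter_sd), a_i ~ Normal(0,
    additive_scatter_sd), and baseline_i linear in the position along
    the axis with per-sample random offset and slope. ``matrix`` is the
    constant leaf-matrix background (set ``matrix_amplitude=0`` for
    pure compound mixtures).
    """
    if band_library is None:
        band_library = default_band_library(config.band_width)
    grid = config.wavenumber_grid()
    clean = clean_spectra(profiles, band_library, grid)
    if config.matrix_amplitude != 0:
        clean = clean + matrix_spectrum(grid, config.matrix_amplitude)
    n = clean.shape[0]
    rng = _rng(config, 20)
    m = rng.normal(1.0, config.multiplicative_scatter_sd, n)
    a = rng.normal(0.0, config.additive_scatter_sd, n)
    off_lo, off_hi = config.baseline_offset_range
    slo_lo, slo_hi = config.baseline_slope_range
    offsets = rng.uniform(off_lo, off_hi, n)
    slopes = rng.uniform(slo_lo, slo_hi, n)
    # fractional position 0 at the low-wavenumber end, 1 at the high end
    x = (grid - grid.min()) / (grid.max() - grid.min())
    observed = (m[:, None] * clean + a[:, None]
                + offsets[:, None] + slopes[:, None] * x[None, :])
    if config.spectral_noise_sd > 0:
        observed = observed + rng.normal(0.0, config.spectral_noise_sd, clean.shape)
    spectra = SpectraSet(wavenumbers=grid, absorbance=observed,
                         sample_ids=[str(i) for i in profiles.index])
    if return_clean:
        return spectra, SpectraSet(wavenumbers=grid, absorbance=clean,
                                   sample_ids=[str(i) for i in profiles.index])
    return spectra


@dataclass
class KineticCurve:
    """Time course of an assay signal (fluorescence or absorbance decay).

    ``signal[0]`` is the initial reading F1 and ``signal[-1]`` the final
    reading Fn used by the area-under-curve statistics.
    """

    times: np.ndarray  # seconds, strictly increasing
    signal: np.ndarray  # nonnegative signal units
    mode: str = "fluorescence_decay"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        if self.times.size != self.signal.size:
            raise ValueError("times and signal must have equal length")
        if self.times.size < 1:
            raise ValueError("curve needs at least one reading")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal readings must be nonnegative")
        if self.mode not in ("fluorescence_decay", "absorbance_decay"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_readings(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KineticParams:
    """Exponential-decay kinetics with antioxidant protection.

    The uninhibited signal decays at ``decay_rate``; antioxidant at
    Trolox-equivalent concentration c slows the rate to
    decay_rate / (1 + c / half_protect_mm). Readings every
    ``interval_s`` seconds over ``duration_s`` (every 5 min over 1 h by
    default, matching plate-reader programming for these assays).
    """

    f0: float = 1000.0
    decay_rate: float = 0.002  # per second, uninhibited
    half_protect_mm: float = 0.2  # mM Trolox halving the rate
    duration_s: float = 3600.0
    interval_s: float = 300.0
    noise_sd: float = 0.0


def generate_kinetic_curve(
    trolox_equiv: float,
    mode: str = "fluorescence_decay",
    params: KineticParams | None = None,
    seed: int = 0,
) -> KineticCurve:
    """Simulated plate-reader decay curve for a given antioxidant level.

    The first reading equals the configured F0 exactly; measurement
    noise (if any) perturbs only the later readings.
    """
    if trolox_equiv < 0:
        raise ValueError("trolox_equiv must be >= 0")
    params = params or KineticParams()
    times = np.arange(0.0, params.duration_s + 1e-9, params.interval_s)
    rate = params.decay_rate / (1.0 + trolox_equiv / params.half_protect_mm)
    signal = params.f0 * np.exp(-rate * times)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal[1:] = np.maximum(
            signal[1:] + rng.normal(0.0, params.noise_sd, signal.size - 1), 0.0
        )
    return KineticCurve(times=times, signal=signal, mode=mode)


def generate_dataset(config: GeneratorConfig):
    """Profiles, spectra and all three assays' reference values.

    Returns ``(profiles, spectra, {assay: ReferenceValues})``.
    """
    profiles = generate_profiles(config)
    spectra = generate_spectra(profiles, config)
    references = {a: generate_reference_values(profiles, a, config) for a in ASSAYS}
    return profiles, spectra, references
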