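"""Centred single-response partial least squares regression (NIPALS).

PLS extracts latent variables — linear combinations of the spectral
variables — that maximise covariance with the response, then regresses
the response on those scores. With a single response the NIPALS weight
vector for each component is X'y (normalised) directly, so no inner
iteration is needed; components are extracted by deflation.

The regression coefficient vector for any component count ``a`` is
recovered through the rotation R = W (P'W)^-1 (triangular for NIPALS),
so one fit yields predictions at every component count — this is what
makes leave-one-out selection of the latent-variable count cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference import ReferenceValues
from .spectra import SpectraSet

__all__ = [
    "PLSModel",
    "CVCurve",
    "fit_pls",
    "predict",
    "cross_validate",
    "fit_count",
    "reset_fit_count",
]

# Deflation stops once the residual covariance is this small relative to
# the initial one; remaining requested components contribute nothing
# (the response is already interpolated).
_DEFLATION_TOL = 1e-14

_FIT_COUNT = 0


def fit_count() -> int:
    """Number of PLS model fits performed since the last reset."""
    return _FIT_COUNT


def reset_fit_count() -> None:
    global _FIT_COUNT
    _FIT_COUNT = 0


@dataclass
class PLSModel:
    """Fitted centred PLS1 model."""

    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (n_latent, p) — may have trailing zero rows
    x_loadings: np.ndarray  # (n_latent, p)
    y_loadings: np.ndarray  # (n_latent,)
    rotations: np.ndarray  # (n_latent, p): rows of R = W (P'W)^-1
    scores: np.ndarray  # (n, n_latent) training X-scores
    wavenumbers: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    n_effective: int = 0  # components actually extracted before exhaustion
    training_ids: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients over wavelengths at ``n_latent``."""
        return self.coefficients_at(self.n_latent)

    def coefficients_at(self, a: int) -> np.ndarray:
        if not 1 <= a <= self.n_latent:
            raise ValueError(f"component count must be in [1, {self.n_latent}]")
        b = self.rotations[:a].T @ self.y_loadings[:a]
        if self.x_scale is not None:
            b = b / self.x_scale
        return b

    def to_json(self, path: str | Path) -> None:
        """Serialise for bit-exact reload (floats survive JSON repr)."""
        payload = {
            "n_latent": self.n_latent,
            "n_effective": self.n_effective,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "rotations": self.rotations.tolist(),
            "scores": self.scores.tolist(),
            "wavenumbers": None if self.wavenumbers is None
            else self.wavenumbers.tolist(),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "training_ids": self.training_ids,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_latent=d["n_latent"],
            n_effective=d["n_effective"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            rotations=np.asarray(d["rotations"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            wavenumbers=None if d["wavenumbers"] is None
            else np.asarray(d["wavenumbers"], dtype=float),
            x_scale=None if d["x_scale"] is None
            else np.asarray(d["x_scale"], dtype=float),
            training_ids=list(d["training_ids"]),
        )


def _as_xy(X, y):
    """Extract aligned (matrix, vector, axis, ids) from domain objects."""
    wavenumbers, ids = None, []
    if isinstance(X, SpectraSet):
        wavenumbers = X.wavenumbers
        ids = list(X.sample_ids)
        xm = X.absorbance
    else:
        xm = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(y, ReferenceValues):
        if ids and y.sample_ids != ids:
            raise ValueError("X and y sample_ids are misaligned")
        yv = y.values
    else:
        yv = np.asarray(y, dtype=float).ravel()
    if yv.size != xm.shape[0]:
        raise ValueError("X rows and y length differ")
    return xm, yv, wavenumbers, ids


def fit_pls(
    X,
    y,
    n_latent: int,
    *,
    scale: bool = False,
) -> PLSModel:
    """Fit a centred NIPALS PLS1 model with ``n_latent`` components.

    ``scale=True`` additionally divides each X column by its standard
    deviation (off by default; scatter-corrected spectra are already on
    a common scale). If the response is exhausted before ``n_latent``
    components, the remaining components are zero and contribute
    nothing to predictions.
    """
    global _FIT_COUNT
    xm, yv, wavenumbers, ids = _as_xy(X, y)
    n, p = xm.shape
    if not 1 <= n_latent <= min(n - 1, p):
        raise ValueError(
            f"n_latent must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], "
            f"got {n_latent}"
        )
    _FIT_COUNT += 1
    x_mean = xm.mean(axis=0)
    y_mean = float(yv.mean())
    Xc = xm - x_mean
    x_scale = None
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xc = Xc / x_scale
    f = yv - y_mean

    W = np.zeros((n_latent, p))
    P = np.zeros((n_latent, p))
    q = np.zeros(n_latent)
    R = np.zeros((n_latent, p))
    T = np.zeros((n, n_latent))

    cov0 = float(np.linalg.norm(Xc.T @ f))
    n_eff = 0
    for h in range(n_latent):
        s = Xc.T @ f
        norm_s = float(np.linalg.norm(s))
        if cov0 == 0 or norm_s <= _DEFLATION_TOL * max(cov0, 1.0):
            break
        w = s / norm_s
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        pvec = (Xc.T @ t) / tt
        qh = float(f @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        f = f - qh * t
        W[h], P[h], q[h], T[:, h] = w, pvec, qh, t
        # rotation: r_h = w_h - sum_{j<h} (p_j . w_h) r_j
        r = w.copy()
        for j in range(h):
            r -= float(P[j] @ w) * R[j]
        R[h] = r
        n_eff = h + 1

    return PLSModel(
        n_latent=n_latent, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, rotations=R, scores=T,
        wavenumbers=None if wavenumbers is None else wavenumbers.copy(),
        x_scale=x_scale, n_effective=n_eff, training_ids=ids,
    )


def predict(model: PLSModel, X, n_latent: int | None = None) -> np.ndarray:
    """Predict responses: y_mean + (x - x_mean) . coefficients."""
    if isinstance(X, SpectraSet):
        if model.wavenumbers is not None:
            if X.wavenumbers.size != model.wavenumbers.size or not np.array_equal(
                X.wavenumbers, model.wavenumbers
            ):
                if X.wavenumbers.size == model.wavenumbers.size:
                    diff = np.nonzero(X.wavenumbers != model.wavenumbers)[0][0]
                    raise ValueError(
                        "wavenumber axis mismatch: first differing wavenumber "
                        f"at index {diff} ({X.wavenumbers[diff]} vs "
                        f"{model.wavenumbers[diff]} cm^-1)"
                    )
                raise ValueError(
                    f"wavenumber axis mismatch: {X.wavenumbers.size} points vs "
                    f"{model.wavenumbers.size} in the model"
                )
        xm = X.absorbance
    else:
        xm = np.atleast_2d(np.asarray(X, dtype=float))
    b = model.coefficients if n_latent is None else model.coefficients_at(n_latent)
    return model.y_mean + (xm - model.x_mean) @ b


@dataclass
class CVCurve:
    """RMSECV per latent-variable count and the selected count."""

    rmsecv: np.ndarray  # index a-1 -> RMSECV with a components
    selected_lv: int
    predictions: np.ndarray | None = None  # (n, max_lv) held-out predictions

    def __post_init__(self) -> None:
        self.rmsecv = np.asarray(self.rmsecv, dtype=float)
        best = float(self.rmsecv.min())
        if self.rmsecv[self.selected_lv - 1] > best + 1e-12:
            raise ValueError("selected_lv does not attain the minimum RMSECV")


def _folds(n: int, scheme) -> list[np.ndarray]:
    if scheme in ("loo", "leave-one-out"):
        return [np.array([i]) for i in range(n)]
    if isinstance(scheme, tuple) and scheme[0] in ("kfold", "k-fold"):
        _, k, seed = scheme
        if k > n:
            raise ValueError(f"fold count {k} exceeds n={n}")
        perm = np.random.default_rng(seed).permutation(n)
        return [np.sort(perm[i::k]) for i in range(k)]
    raise ValueError(f"unknown cross-validation scheme {scheme!r}")


def cross_validate(
    X,
    y,
    max_lv: int = 20,
    scheme="loo",
    *,
    scale: bool = False,
) -> CVCurve:
    """Cross-validated latent-variable selection.

    Refits the model once per fold (each refit yields predictions at
    every component count 1..max_lv) and computes RMSECV from held-out
    predictions only. The selected count is the smallest one within
    1e-12 of the minimum RMSECV.
    """
    xm, yv, wavenumbers, ids = _as_xy(X, y)
    n = xm.shape[0]
    max_lv = min(max_lv, n - 2, xm.shape[1])  # n-2: one sample held out
    if max_lv < 1:
        raise ValueError("too few samples for cross-validation")
    folds = _folds(n, scheme)
    preds = np.full((n, max_lv), np.nan)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        model = fit_pls(xm[train], yv[train], max_lv, scale=scale)
        for a in range(1, max_lv + 1):
            preds[fold, a - 1] = predict(model, xm[fold], n_latent=a)
    rmsecv = np.sqrt(np.mean((preds - yv[:, None]) ** 2, axis=0))
    best = float(rmsecv.min())
    selected = int(np.nonzero(rmsecv <= best + 1e-12)[0][0]) + 1
    return CVCurve(rmsecv=rmsecv, selected_lv=selected, predictions=preds)
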