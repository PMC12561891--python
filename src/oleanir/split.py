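"""Kennard-Stone sample selection and calibration/prediction splitting.

The Kennard-Stone algorithm picks a representative subset by Euclidean
distance in spectral space: the first two picks are the farthest pair;
each further pick maximises its minimum distance to the already-selected
samples. Applied here to carve a full sample set into a
cross-validation set (Set 1, ~70%) and an external prediction set
(Set 2, ~30%), with the union (Set 1+2) available for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraSet

__all__ = ["SplitResult", "kennard_stone", "split_sets"]


@dataclass
class SplitResult:
    """Index partition of a sample set.

    ``cv_indices`` is Set 1 (cross-validation), ``prediction_indices``
    Set 2 (external prediction); ``all_indices`` their union (Set 1+2).
    """

    all_indices: np.ndarray
    cv_indices: np.ndarray
    prediction_indices: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.all_indices = np.asarray(self.all_indices, dtype=int)
        self.cv_indices = np.asarray(self.cv_indices, dtype=int)
        self.prediction_indices = np.asarray(self.prediction_indices, dtype=int)
        cv, pred = set(self.cv_indices.tolist()), set(self.prediction_indices.tolist())
        if cv & pred:
            raise ValueError("cv and prediction sets overlap")
        if cv | pred != set(self.all_indices.tolist()):
            raise ValueError("cv and prediction sets do not partition all_indices")

    @property
    def n_cv(self) -> int:
        return self.cv_indices.size

    @property
    def n_prediction(self) -> int:
        return self.prediction_indices.size


def kennard_stone(
    spectra: SpectraSet | np.ndarray, k: int, *, center: bool = True
) -> np.ndarray:
    """Ordered Kennard-Stone selection of ``k`` samples.

    Greedy max-min on Euclidean distances: start from the farthest
    pair, then repeatedly add the sample whose minimum distance to the
    selected set is largest. Ties break to the lowest index, so the
    selection is deterministic for a given sample order. Distances are
    computed on mean-centred rows by default (``center=False``
    disables).
    """
    x = spectra.absorbance if isinstance(spectra, SpectraSet) else np.asarray(
        spectra, dtype=float)
    x = np.atleast_2d(x)
    n = x.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"k must satisfy 2 <= k <= n_samples ({n}), got {k}")
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    sq = np.sum(x * x, axis=1)
    # full pairwise squared distance matrix; fine at calibration scale
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    first, second = (i, j) if i < j else (j, i)
    selected = [int(first), int(second)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_d2 = np.minimum(d2[first], d2[second])
    while len(selected) < k:
        masked = np.where(remaining, min_d2, -np.inf)
        pick = int(np.argmax(masked))  # argmax ties -> lowest index
        selected.append(pick)
        remaining[pick] = False
        min_d2 = np.minimum(min_d2, d2[pick])
    return np.asarray(selected, dtype=int)


def split_sets(
    spectra: SpectraSet | np.ndarray, fraction: float = 0.7, *, center: bool = True
) -> SplitResult:
    """Kennard-Stone split into Set 1 (cv) and Set 2 (prediction).

    Set 1 gets ``round(fraction * n)`` samples picked by Kennard-Stone;
    the remainder is Set 2. With 120 samples and the default 0.7 this
    gives the 84/36 partition.
    """
    x = spectra.absorbance if isinstance(spectra, SpectraSet) else np.asarray(
        spectra, dtype=float)
    n = np.atleast_2d(x).shape[0]
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    k = int(round(fraction * n))
    if k < 2 or k > n - 1:
        raise ValueError(
            f"fraction {fraction} leaves a degenerate split for n={n}"
        )
    cv = np.sort(kennard_stone(spectra, k, center=center))
    mask = np.ones(n, dtype=bool)
    mask[cv] = False
    pred = np.nonzero(mask)[0]
    ids = spectra.sample_ids if isinstance(spectra, SpectraSet) else []
    return SplitResult(all_indices=np.arange(n), cv_indices=cv,
                       prediction_indices=pred, sample_ids=list(ids))
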