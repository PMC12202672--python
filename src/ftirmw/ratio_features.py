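"""Absorbance-ratio surfaces R(nu1, nu2) = A(nu1)/A(nu2) and flat feature vectors.

Ratios of absorbances cancel the multiplicative path-length (film-thickness)
factor of the Beer-Lambert law, so they are robust to sample-preparation
inconsistencies — a generalized internal standard that normalizes every point
by every other point.  Entries where either absorbance fails the noise
threshold are masked invalid; the mask is explicit and authoritative (values
carry NaN as a sentinel, never a silent zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .preprocessing import WindowConfig, threshold_mask
from .spectra_io import Spectrum

__all__ = ["RatioSurface", "FeatureVector", "ratio_surface", "extract_features",
           "pair_name", "RatioFeaturizer"]


@dataclass(frozen=True)
class RatioSurface:
    """All pairwise absorbance ratios of one spectrum over the cropped grid.

    ``values[i, j] = A(nu_i) / A(nu_j)`` where both absorbances exceed the
    threshold; ``valid[i, j]`` marks defined entries, and invalid entries hold
    NaN.  Reciprocity ``values[i, j] * values[j, i] == 1`` holds on the valid
    set, and the valid diagonal is exactly 1.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def value_at(self, nu1: float, nu2: float) -> float:
        i = _index_of(self.wavenumbers, nu1)
        j = _index_of(self.wavenumbers, nu2)
        return float(self.values[i, j])

    def valid_at(self, nu1: float, nu2: float) -> bool:
        i = _index_of(self.wavenumbers, nu1)
        j = _index_of(self.wavenumbers, nu2)
        return bool(self.valid[i, j])


@dataclass(frozen=True)
class FeatureVector:
    """Selected ratios of one spectrum, in pair order."""

    pair_ids: tuple[tuple[float, float], ...]
    values: np.ndarray
    sample_id: str
    replicate_id: str

    def __post_init__(self) -> None:
        if len(self.pair_ids) != len(self.values):
            raise ValueError("pair_ids and values must have equal length")


def _index_of(wavenumbers: np.ndarray, nu: float, atol: float = 1e-6) -> int:
    hits = np.nonzero(np.isclose(wavenumbers, nu, rtol=0.0, atol=atol))[0]
    if hits.size == 0:
        raise KeyError(f"wavenumber {nu} not on grid")
    return int(hits[0])


def pair_name(nu1: float, nu2: float) -> str:
    """Column name for a ratio feature, e.g. ``R_1724_1278``."""
    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else str(v)
    return f"R_{fmt(nu1)}_{fmt(nu2)}"


def ratio_surface(s: Spectrum, cfg: WindowConfig = WindowConfig()) -> RatioSurface:
    """Full n x n ratio surface of one (already cropped) spectrum."""
    a = s.absorbances
    mask = threshold_mask(s, cfg)
    valid = np.outer(mask, mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.outer(a, 1.0 / a)
    np.fill_diagonal(values, 1.0)  # a/a is exactly 1; outer(a, 1/a) is not
    values[~valid] = np.nan
    return RatioSurface(s.wavenumbers.copy(), values, valid)


def extract_features(
    s: Spectrum,
    pairs: Sequence[tuple[float, float]],
    cfg: WindowConfig = WindowConfig(),
    invalid: str = "raise",
    medians: Sequence[float] | None = None,
) -> FeatureVector:
    """Ratio values of ``s`` at the requested (nu1, nu2) pairs, in pair order.

    ``invalid`` controls what happens when a requested pair fails the
    absorbance threshold in *this* spectrum: ``"raise"`` (default) refuses,
    ``"impute"`` substitutes the caller-supplied training-set ``medians``
    (aligned with ``pairs``) and emits a warning.  Silent imputation is never
    done: a selected pair that goes dark changes the meaning of the feature.
    """
    if invalid not in ("raise", "impute"):
        raise ValueError("invalid must be 'raise' or 'impute'")
    if invalid == "impute" and (medians is None or len(medians) != len(pairs)):
        raise ValueError("impute policy requires one median per pair")
    a = s.absorbances
    mask = threshold_mask(s, cfg)
    out = np.empty(len(pairs))
    for k, (nu1, nu2) in enumerate(pairs):
        i = _index_of(s.wavenumbers, nu1)
        j = _index_of(s.wavenumbers, nu2)
        if mask[i] and mask[j]:
            out[k] = a[i] / a[j]
        elif invalid == "impute":
            warnings.warn(
                f"pair ({nu1}, {nu2}) invalid in {s.sample_id}:{s.replicate_id}; "
                "imputing training median",
                stacklevel=2,
            )
            out[k] = medians[k]
        else:
            raise ValueError(
                f"pair ({nu1}, {nu2}) fails the absorbance threshold in "
                f"{s.sample_id}:{s.replicate_id}"
            )
    return FeatureVector(tuple((float(p), float(q)) for p, q in pairs), out,
                         s.sample_id, s.replicate_id)


class RatioFeaturizer(TransformerMixin, BaseEstimator):
    """Turn absorbance rows into ratio features at fixed wavenumber pairs.

    Operates on an ``(n_spectra, n_wavenumbers)`` absorbance matrix whose
    columns follow ``wavenumbers``.  ``transform`` returns the
    ``(n_spectra, n_pairs)`` matrix of A(nu1)/A(nu2) values.

    Parameters
    ----------
    wavenumbers : array-like
        Wavenumber of each input column (the cropped grid).
    pairs : sequence of (nu1, nu2)
        Ratio positions to extract.
    abs_threshold : float
        Noise threshold; entries where either absorbance is not strictly
        above it follow the ``invalid`` policy.
    invalid : {"raise", "impute"}
        "impute" uses the per-pair training median learned in ``fit``.
    """

    def __init__(self, wavenumbers=None, pairs=None, abs_threshold: float = 0.03,
                 invalid: str = "raise"):
        self.wavenumbers = wavenumbers
        self.pairs = pairs
        self.abs_threshold = abs_threshold
        self.invalid = invalid

    def _resolve_indices(self) -> np.ndarray:
        w = np.asarray(self.wavenumbers, dtype=float)
        idx = np.array(
            [[_index_of(w, nu1), _index_of(w, nu2)] for nu1, nu2 in self.pairs],
            dtype=int,
        ).reshape(-1, 2)
        return idx

    def fit(self, X, y=None):
        if self.wavenumbers is None or self.pairs is None:
            raise ValueError("wavenumbers and pairs must be set")
        X = check_array(X)
        if X.shape[1] != len(np.asarray(self.wavenumbers)):
            raise ValueError("X width does not match wavenumbers")
        self.pair_indices_ = self._resolve_indices()
        vals, ok = self._raw(X)
        med = np.nanmedian(np.where(ok, vals, np.nan), axis=0)
        self.training_medians_ = med
        self.n_features_in_ = X.shape[1]
        return self

    def _raw(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i, j = self.pair_indices_[:, 0], self.pair_indices_[:, 1]
        num, den = X[:, i], X[:, j]
        ok = (num > self.abs_threshold) & (den > self.abs_threshold)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = num / den
        return vals, ok

    def transform(self, X):
        check_is_fitted(self, "pair_indices_")
        X = check_array(X)
        vals, ok = self._raw(X)
        if np.all(ok):
            return vals
        if self.invalid == "impute":
            warnings.warn(
                f"{int((~ok).sum())} ratio values below threshold; imputing training medians",
                stacklevel=2,
            )
            return np.where(ok, vals, self.training_medians_)
        bad = np.argwhere(~ok)[0]
        nu1, nu2 = self.pairs[bad[1]]
        raise ValueError(
            f"pair ({nu1}, {nu2}) fails the absorbance threshold in row {bad[0]}"
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "pair_indices_")
        return np.array([pair_name(nu1, nu2) for nu1, nu2 in self.pairs], dtype=object)
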