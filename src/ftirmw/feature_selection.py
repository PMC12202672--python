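"""Suitability-based selection of absorbance-ratio positions.

Every pair (nu1, nu2) in the analysis window is scored against the M_w labels
with three statistics computed over the replicate spectra:

* Pearson r — linear correlation of R(nu1, nu2) with M_w (diagnostic only:
  it understates saturating, monotone trends);
* Spearman rho — rank correlation, robust to the nonlinearity;
* OLS slope of R against scaled M_w — guards against the "flat ratio"
  pathology, where two strongly co-varying absorbances give a perfectly
  monotone but almost constant ratio (Spearman 1, slope ~ 0): a model built
  on such a pair would be hypersensitive to minor perturbations.

The *suitability indicator* is the product ``spearman * slope``.  Because a
monotone trend gives both factors the same sign, the product is positive for
usable pairs in either orientation, near zero for flat or noisy pairs, and a
single threshold (default 0.5) selects the model inputs.

The slope has units of ratio per unit of scaled M_w; by default M_w is mapped
to the unit interval over the training range so the suitability value (and
the 0.5 threshold) are dimensionless and portable across M_w ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .preprocessing import WindowConfig, crop_window
from .ratio_features import RatioFeaturizer, pair_name
from .spectra_io import LabelledDataset

__all__ = [
    "MwScaler",
    "SelectionMap",
    "spearman_rho",
    "pearson_r",
    "regression_slope",
    "suitability_map",
    "SuitabilitySelector",
]


# ---------------------------------------------------------------------------
# scalar statistics (also the oracle-grade single-pair API)


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return x, y


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Tie-free data uses the exact rank-difference formula
    ``1 - 6*sum(d^2)/(n*(n^2-1))``, so strictly monotone series give exactly
    +/-1; tied data falls back to Pearson on average ranks.  Raises on
    constant input (the coefficient is undefined there, and a silent 0 would
    corrupt the suitability product).
    """
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_rho undefined for constant input")
    if np.unique(x).size == x.size and np.unique(y).size == y.size:
        n = x.size
        d = stats.rankdata(x) - stats.rankdata(y)
        return float(1.0 - 6.0 * float(d @ d) / (n * (n * n - 1)))
    return float(stats.spearmanr(x, y).statistic)


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises on constant input."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def regression_slope(mw_scaled, ratios) -> float:
    """OLS slope of ``ratios`` on ``mw_scaled`` (cov(x, y) / var(x))."""
    x, y = _check_xy(mw_scaled, ratios)
    xc = x - x.mean()
    ss = float(xc @ xc)
    if ss == 0:
        raise ValueError("zero variance in mw_scaled")
    return float((xc @ (y - y.mean())) / ss)


# ---------------------------------------------------------------------------
# M_w scaling


@dataclass(frozen=True)
class MwScaler:
    """Affine M_w scaling applied before the slope computation.

    ``unit_interval`` maps the training range [mw_min, mw_max] onto [0, 1],
    making slope and suitability dimensionless; ``kilodalton`` divides by 1000
    (for sensitivity analysis of the threshold).
    """

    mw_min: float
    mw_max: float
    mode: str = "unit_interval"

    def __post_init__(self) -> None:
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if self.mode not in ("unit_interval", "kilodalton"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_targets(cls, mw: Sequence[float], mode: str = "unit_interval") -> "MwScaler":
        mw = np.asarray(mw, dtype=float)
        return cls(float(mw.min()), float(mw.max()), mode)

    def transform(self, mw) -> np.ndarray:
        mw = np.asarray(mw, dtype=float)
        if self.mode == "unit_interval":
            return (mw - self.mw_min) / (self.mw_max - self.mw_min)
        return mw / 1000.0


# ---------------------------------------------------------------------------
# the selection map


@dataclass
class SelectionMap:
    """Per-pair statistics over the candidate grid and the selection mask.

    All 2-D arrays are indexed ``[i, j]`` for the pair (nu_i in the numerator,
    nu_j in the denominator); non-candidate entries hold NaN (statistics) or
    False (masks).  A pair is a *candidate* only if both absorbances exceed
    the noise threshold in every sample's mean spectrum.
    """

    wavenumbers: np.ndarray
    pearson: np.ndarray
    spearman: np.ndarray
    slope: np.ndarray
    suitability: np.ndarray
    candidate: np.ndarray
    selected: np.ndarray
    threshold: float
    scaler: MwScaler

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def pair_stats(self, nu1: float, nu2: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.wavenumbers - nu1)))
        j = int(np.argmin(np.abs(self.wavenumbers - nu2)))
        return {
            "pearson": float(self.pearson[i, j]),
            "spearman": float(self.spearman[i, j]),
            "slope": float(self.slope[i, j]),
            "suitability": float(self.suitability[i, j]),
            "candidate": bool(self.candidate[i, j]),
            "selected": bool(self.selected[i, j]),
        }

    def selected_pairs(self, max_pairs: int | None = None) -> list[tuple[float, float]]:
        """Selected (nu1, nu2) pairs in descending suitability order."""
        ii, jj = np.nonzero(self.selected)
        order = np.argsort(-self.suitability[ii, jj], kind="stable")
        pairs = [(float(self.wavenumbers[i]), float(self.wavenumbers[j]))
                 for i, j in zip(ii[order], jj[order])]
        return pairs if max_pairs is None else pairs[:max_pairs]

    def to_frame(self, only_candidates: bool = True) -> pd.DataFrame:
        ii, jj = np.nonzero(self.candidate if only_candidates
                            else np.ones_like(self.candidate))
        return pd.DataFrame(
            {
                "nu1": self.wavenumbers[ii],
                "nu2": self.wavenumbers[jj],
                "pair": [pair_name(self.wavenumbers[i], self.wavenumbers[j])
                         for i, j in zip(ii, jj)],
                "pearson": self.pearson[ii, jj],
                "spearman": self.spearman[ii, jj],
                "slope": self.slope[ii, jj],
                "suitability": self.suitability[ii, jj],
                "selected": self.selected[ii, jj],
            }
        )


def _score_pairs(
    wavenumbers: np.ndarray,
    X: np.ndarray,
    mw: np.ndarray,
    sample_ids: Sequence[str] | None,
    abs_threshold: float,
    scaler: MwScaler,
    threshold: float,
    chunk_elems: int = 8_000_000,
) -> SelectionMap:
    """Vectorized per-pair scoring over all candidate (nu1, nu2) positions.

    Spearman is computed as Pearson on average ranks; ranks of the ratio
    values are taken along the observation axis in chunks so memory stays
    bounded even on a dense 1 1/cm grid.
    """
    n_obs, n_nu = X.shape
    if len(np.unique(mw)) < 3:
        raise ValueError("insufficient M_w levels: need at least 3 distinct labels")

    # candidacy from per-sample mean spectra (replicate noise must not flicker
    # the candidate set)
    if sample_ids is not None:
        sample_ids = np.asarray(sample_ids)
        means = np.vstack([X[sample_ids == sid].mean(axis=0)
                           for sid in pd.unique(sample_ids)])
    else:
        means = X
    point_ok = np.all(means > abs_threshold, axis=0)
    cand_idx = np.nonzero(point_ok)[0]
    m = cand_idx.size

    full = np.full((n_nu, n_nu), np.nan)
    pearson, spearman, slope = full.copy(), full.copy(), full.copy()
    candidate = np.zeros((n_nu, n_nu), dtype=bool)
    selected = np.zeros((n_nu, n_nu), dtype=bool)

    if m > 0:
        candidate[np.ix_(cand_idx, cand_idx)] = True
        mw_s = scaler.transform(mw)
        xs = mw_s - mw_s.mean()
        ss_x = float(xs @ xs)
        rk_mw = stats.rankdata(mw, method="average")
        rk_mw_c = rk_mw - rk_mw.mean()
        nrm_rk_mw = float(np.sqrt(rk_mw_c @ rk_mw_c))
        mw_c = mw - mw.mean()
        nrm_mw = float(np.sqrt(mw_c @ mw_c))

        Xc = X[:, cand_idx]  # (n_obs, m)
        rows_per_chunk = max(1, chunk_elems // (m * n_obs))
        for start in range(0, m, rows_per_chunk):
            rows = slice(start, min(start + rows_per_chunk, m))
            # R[c, j, o] = A_o(nu_row_c) / A_o(nu_col_j)
            R = (Xc[:, rows].T)[:, None, :] / Xc.T[None, :, :]
            Rc = R - R.mean(axis=-1, keepdims=True)
            nrm_R = np.sqrt(np.einsum("cjo,cjo->cj", Rc, Rc))
            with np.errstate(divide="ignore", invalid="ignore"):
                pe = (Rc @ mw_c) / (nrm_R * nrm_mw)
                sl = (Rc @ xs) / ss_x
                rk = stats.rankdata(R, method="average", axis=-1)
                rk -= rk.mean(axis=-1, keepdims=True)
                nrm_rk = np.sqrt(np.einsum("cjo,cjo->cj", rk, rk))
                sp = (rk @ rk_mw_c) / (nrm_rk * nrm_rk_mw)
            block = np.ix_(cand_idx[rows], cand_idx)
            pearson[block], spearman[block], slope[block] = pe, sp, sl

        suitability = spearman * slope
        with np.errstate(invalid="ignore"):
            selected = np.where(np.isnan(suitability), False, suitability > threshold)
    else:
        suitability = full.copy()

    return SelectionMap(
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        pearson=pearson,
        spearman=spearman,
        slope=slope,
        suitability=suitability,
        candidate=candidate,
        selected=selected,
        threshold=threshold,
        scaler=scaler,
    )


def suitability_map(
    dataset: LabelledDataset,
    cfg: WindowConfig = WindowConfig(),
    scaler: MwScaler | None = None,
    threshold: float = 0.5,
) -> SelectionMap:
    """Score and select ratio positions for a labelled replicate dataset.

    Statistics are computed across the individual replicate spectra (each
    replicate inherits its sample's M_w); candidacy is decided on the
    per-sample mean spectra.
    """
    cropped = [crop_window(s, cfg) for s in dataset.spectra]
    sub = LabelledDataset(cropped, dataset.labels)
    grid, X, sids, _ = sub.to_matrix()
    mw = sub.mw_targets()
    if scaler is None:
        scaler = MwScaler.from_targets(mw)
    return _score_pairs(grid, X, mw, sids, cfg.abs_threshold, scaler, threshold)


def _order_by_snr(
    pairs: list[tuple[float, float]],
    wavenumbers: np.ndarray,
    X: np.ndarray,
    sample_ids: np.ndarray,
    smap: SelectionMap,
) -> list[tuple[float, float]]:
    """Order selected pairs by feature signal-to-noise, descending.

    The suitability product deliberately has no noise term, so its largest
    values sit on weak-absorbance points whose big regression slopes are an
    artefact of dividing by a small number.  For the network input we prefer
    pairs whose M_w trend (the slope over the scaled M_w range) is large
    relative to the feature's within-sample scatter — i.e. ratios of
    well-measured bands.
    """
    index = {float(nu): k for k, nu in enumerate(wavenumbers)}
    ii = np.array([index[p[0]] for p in pairs])
    jj = np.array([index[p[1]] for p in pairs])
    R = X[:, ii] / X[:, jj]  # (n_obs, n_pairs)
    resid = np.vstack([
        R[sample_ids == sid] - R[sample_ids == sid].mean(axis=0)
        for sid in pd.unique(sample_ids)
    ])
    noise = resid.std(axis=0)
    noise[noise == 0] = np.inf  # noiseless synthetic data: order falls back below
    iw = np.array([index[p[0]] for p in pairs])
    jw = np.array([index[p[1]] for p in pairs])
    signal = np.abs(smap.slope[iw, jw])
    snr = np.where(np.isfinite(noise), signal / noise, signal)
    order = np.argsort(-snr, kind="stable")
    return [pairs[k] for k in order]


def _thin_pairs(pairs: list[tuple[float, float]], sep: float) -> list[tuple[float, float]]:
    """Greedy diversity thinning in suitability order.

    Neighbouring grid points on the same band carry nearly identical ratio
    information; a pair is kept only if it differs from every already-kept
    pair by at least ``sep`` 1/cm in the numerator or denominator position.
    """
    kept: list[tuple[float, float]] = []
    for p in pairs:
        if all(abs(p[0] - q[0]) >= sep or abs(p[1] - q[1]) >= sep for q in kept):
            kept.append(p)
    return kept


class SuitabilitySelector(TransformerMixin, BaseEstimator):
    """scikit-learn transformer: suitability-selected ratio features.

    ``fit(X, y)`` takes the cropped absorbance matrix (rows = replicate
    spectra, columns follow ``wavenumbers``) and the per-row M_w targets,
    builds the full :class:`SelectionMap`, and keeps the selected pairs in
    descending suitability order (optionally capped at ``max_features``).
    ``transform`` then produces the ratio feature matrix for those pairs.

    Replicate-level threshold dips in selected pairs are imputed with the
    training median (with a warning) by default: candidacy is decided on
    sample means, so an individual replicate grazing the noise threshold must
    not crash feature extraction.  Pass ``invalid="raise"`` to refuse instead.
    """

    def __init__(
        self,
        wavenumbers=None,
        threshold: float = 0.5,
        abs_threshold: float = 0.03,
        mw_scaling: str = "unit_interval",
        max_features: int | None = None,
        min_separation: float = 0.0,
        invalid: str = "impute",
    ):
        self.wavenumbers = wavenumbers
        self.threshold = threshold
        self.abs_threshold = abs_threshold
        self.mw_scaling = mw_scaling
        self.max_features = max_features
        self.min_separation = min_separation
        self.invalid = invalid

    def fit(self, X, y, sample_ids: Sequence[str] | None = None):
        if self.wavenumbers is None:
            raise ValueError("wavenumbers must be set")
        X = check_array(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("y length must match X rows")
        w = np.asarray(self.wavenumbers, dtype=float)
        scaler = MwScaler.from_targets(y, self.mw_scaling)
        self.selection_map_ = _score_pairs(
            w, X, y, sample_ids, self.abs_threshold, scaler, self.threshold
        )
        # network inputs are additionally required to be valid in every
        # individual training replicate: a pair whose denominator grazes the
        # noise threshold in single spectra is dominated by detector noise
        # (which is also what inflates its regression slope), and imputing it
        # would corrupt the feature semantics
        robust = X.min(axis=0) > self.abs_threshold
        nu_ok = {float(nu) for nu, good in zip(w, robust) if good}
        pairs = [p for p in self.selection_map_.selected_pairs()
                 if p[0] in nu_ok and p[1] in nu_ok]
        if sample_ids is not None and pairs:
            pairs = _order_by_snr(pairs, w, X, np.asarray(sample_ids),
                                  self.selection_map_)
        if self.min_separation > 0:
            pairs = _thin_pairs(pairs, self.min_separation)
        self.pairs_ = pairs if self.max_features is None else pairs[: self.max_features]
        if not self.pairs_:
            raise ValueError("no pair exceeds the suitability threshold")
        self.featurizer_ = RatioFeaturizer(
            wavenumbers=w, pairs=self.pairs_,
            abs_threshold=self.abs_threshold, invalid=self.invalid,
        ).fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "featurizer_")
        return self.featurizer_.transform(X)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "featurizer_")
        return self.featurizer_.get_feature_names_out()
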