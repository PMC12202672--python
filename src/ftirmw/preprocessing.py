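"""Window cropping, absorbance thresholding and the SNV baseline transform.

Only the 800-1800 1/cm region carries usable polyester band information at
acceptable signal-to-noise (the C-H stretches near 2800-3000 1/cm are too
weak), so all feature computation happens inside a configurable closed window.
Absorbances at or below a small threshold (default 0.03) are treated as noise
and excluded from ratio formation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .spectra_io import Spectrum

__all__ = ["WindowConfig", "crop_window", "threshold_mask", "snv", "SNVScaler"]


@dataclass(frozen=True)
class WindowConfig:
    """Analysis window and absorbance noise threshold.

    nu_min, nu_max : closed wavenumber interval in 1/cm (default 800-1800).
    abs_threshold : absorbance below/at which a point is considered noise and
        excluded from ratio computation (strict ``>`` comparison).
    """

    nu_min: float = 800.0
    nu_max: float = 1800.0
    abs_threshold: float = 0.03

    def __post_init__(self) -> None:
        if not self.nu_min < self.nu_max:
            raise ValueError("nu_min must be < nu_max")
        if self.abs_threshold < 0:
            raise ValueError("abs_threshold must be >= 0")


def crop_window(s: Spectrum, cfg: WindowConfig = WindowConfig()) -> Spectrum:
    """Restrict a spectrum to the closed interval [nu_min, nu_max]."""
    keep = (s.wavenumbers >= cfg.nu_min) & (s.wavenumbers <= cfg.nu_max)
    if not np.any(keep):
        raise ValueError(
            f"window [{cfg.nu_min}, {cfg.nu_max}] outside grid "
            f"[{s.wavenumbers.min()}, {s.wavenumbers.max()}]"
        )
    return Spectrum(s.sample_id, s.replicate_id, s.wavenumbers[keep], s.absorbances[keep])


def threshold_mask(s: Spectrum, cfg: WindowConfig = WindowConfig()) -> np.ndarray:
    """Boolean mask, True where A(nu) strictly exceeds the noise threshold."""
    return s.absorbances > cfg.abs_threshold


def snv(s: Spectrum, ddof: int = 1) -> Spectrum:
    """Standard Normal Variate: per-spectrum centering and unit-variance scaling.

    The conventional chemometric normalization used as the comparison baseline
    for the ratio features.  Uses the sample standard deviation (``ddof=1``)
    by default.
    """
    a = s.absorbances
    if a.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = a.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance: SNV undefined for a constant spectrum")
    return Spectrum(s.sample_id, s.replicate_id, s.wavenumbers.copy(), (a - a.mean()) / sd)


class SNVScaler(TransformerMixin, BaseEstimator):
    """Row-wise SNV transform over an (n_spectra, n_wavenumbers) matrix.

    Stateless; ``fit`` only records the input width.  Provided so the SNV
    baseline composes with scikit-learn pipelines next to the ratio features.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        sd = X.std(axis=1, ddof=self.ddof, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero variance row: SNV undefined")
        return (X - X.mean(axis=1, keepdims=True)) / sd
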