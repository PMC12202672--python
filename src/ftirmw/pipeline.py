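"""End-to-end calibration: spectra + SEC labels -> fitted M_w estimator.

Ties the stages together the way the method is meant to be used: crop to the
informative window, score every absorbance-ratio position against M_w, keep
the top suitability-selected pairs as network inputs, train the
Levenberg-Marquardt network on a stratified 80/20 replicate split, and report
validation accuracy split at the 200 kDa knee.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ann_model import (
    AnnModel,
    EvaluationReport,
    LMRegressor,
    TrainingError,
    TrainingReport,
    evaluate,
    forward,
    forward_matrix,
    model_from_doc,
    model_to_doc,
    split_dataset,
)
from .feature_selection import SelectionMap, SuitabilitySelector
from .preprocessing import WindowConfig, crop_window
from .ratio_features import extract_features
from .spectra_io import LabelledDataset, Spectrum

__all__ = ["MwCalibration"]

_CALIB_FORMAT_VERSION = 1


@dataclass
class MwCalibration:
    """Fit and apply the full FTIR -> M_w calibration.

    Parameters mirror the stage estimators.  ``max_features`` and
    ``min_separation`` cap the network input at a small, diverse subset of the
    suitability-selected pairs: on a dense 1 1/cm grid the 0.5 threshold
    admits thousands of near-duplicate neighbouring band points, and keeping
    the parameter count below the number of training spectra is what keeps
    the network from interpolating replicate noise.

    The network is fitted ``n_candidate_fits`` times from independent seeds;
    the deployed candidate is the one least sensitive to synthetic replicate
    noise injected into the *training* features (their within-sample
    scatter), an audit that uses no validation data.  Predictions are clipped
    to the calibrated M_w range: the method is an interpolating calibration
    and carries no information outside the training ladder.

    ``target_transform`` controls the space the network is calibrated in:
    ``"log10"`` (default) regresses log10(M_w) so that accuracy is balanced
    across the ~200x molecular-weight ladder (predictions are exponentiated
    back to Da); ``"linear"`` regresses M_w directly, which lets the squared
    loss be dominated by the highest-M_w samples.

    Fitted attributes: ``selection_map_``, ``pairs_``, ``model_``,
    ``report_``, ``evaluation_``.
    """

    window: WindowConfig = WindowConfig()
    selection_threshold: float = 0.5
    mw_scaling: str = "unit_interval"
    max_features: int | None = 8
    min_separation: float = 4.0
    hidden_layer_sizes: tuple[int, ...] = (5,)
    n_restarts: int = 10
    n_candidate_fits: int = 5
    train_fraction: float = 0.8
    stratify_by_sample: bool = True
    target_transform: str = "log10"
    random_state: int = 0

    def fit(self, dataset: LabelledDataset) -> "MwCalibration":
        cropped = LabelledDataset(
            [crop_window(s, self.window) for s in dataset.spectra], dataset.labels
        )
        grid, X, sids, _ = cropped.to_matrix()
        y = cropped.mw_targets()

        selector = SuitabilitySelector(
            wavenumbers=grid,
            threshold=self.selection_threshold,
            abs_threshold=self.window.abs_threshold,
            mw_scaling=self.mw_scaling,
            max_features=self.max_features,
            min_separation=self.min_separation,
        ).fit(X, y, sample_ids=sids)
        F = selector.transform(X)

        if self.target_transform not in ("log10", "linear"):
            raise ValueError("target_transform must be 'log10' or 'linear'")
        t = np.log10(y) if self.target_transform == "log10" else y

        F_tr, F_va, t_tr, _, idx_tr, idx_va = split_dataset(
            F, t, sample_ids=sids,
            train_fraction=self.train_fraction,
            seed=self.random_state,
            stratify_by_sample=self.stratify_by_sample,
        )
        y_va = y[idx_va]
        sids_tr = [sids[i] for i in idx_tr]
        reg = self._fit_network(F_tr, t_tr, sids_tr)

        self.selector_ = selector
        self.selection_map_: SelectionMap = selector.selection_map_
        self.pairs_ = selector.pairs_
        self.training_medians_ = selector.featurizer_.training_medians_
        self.model_: AnnModel = reg.model_
        self.report_: TrainingReport = reg.report_
        self.report_.split_seed = self.random_state
        self.report_.train_fraction = self.train_fraction
        self.t_min_, self.t_max_ = float(t_tr.min()), float(t_tr.max())
        self.train_indices_, self.validation_indices_ = idx_tr, idx_va
        va_sids = [sids[i] for i in idx_va]
        self.evaluation_: EvaluationReport = evaluate(
            None, F_va, y_va, sample_ids=va_sids,
            predictions=self._inverse_target(forward_matrix(self.model_, F_va)),
        )
        return self

    def _fit_network(self, F_tr: np.ndarray, t_tr: np.ndarray,
                     sids_tr: Sequence[str]) -> LMRegressor:
        """Candidate fits from independent seeds; keep the least noise-sensitive.

        Replicate spectra of one sample differ only by measurement noise, so
        a trustworthy network must map a training row and a noise-perturbed
        copy of it to nearly the same M_w.  Each candidate is scored by its
        mean squared target-space error on training features jittered with
        their own within-sample standard deviation; the audit is seeded and
        never touches validation rows.
        """
        groups = pd.Series(range(len(sids_tr))).groupby(list(sids_tr))
        resid = np.vstack([
            F_tr[idx.to_numpy()] - F_tr[idx.to_numpy()].mean(axis=0)
            for _, idx in groups
        ])
        noise_sd = resid.std(axis=0)
        rng = np.random.default_rng(self.random_state)
        best: tuple[float, LMRegressor] | None = None
        errors: list[Exception] = []
        for k in range(self.n_candidate_fits):
            try:
                reg = LMRegressor(
                    hidden_layer_sizes=self.hidden_layer_sizes,
                    n_restarts=self.n_restarts,
                    random_state=self.random_state + 1000 * k,
                ).fit(F_tr, t_tr)
            except TrainingError as err:
                errors.append(err)
                continue
            score = 0.0
            for _ in range(5):
                jitter = rng.normal(0.0, noise_sd, F_tr.shape)
                score += float(np.mean((reg.predict(F_tr + jitter) - t_tr) ** 2))
            if best is None or score < best[0]:
                best = (score, reg)
        if best is None:
            raise errors[-1]
        return best[1]

    def _inverse_target(self, t: np.ndarray | float):
        # extrapolation guard: a calibration carries no information outside
        # the training ladder, but a small margin is allowed so honest
        # misestimates at the extreme levels are not censored to zero error
        margin = 0.1 * (self.t_max_ - self.t_min_)
        t = np.clip(t, self.t_min_ - margin, self.t_max_ + margin)
        return 10.0 ** t if self.target_transform == "log10" else t

    # -- prediction ---------------------------------------------------------

    def _predict_one(self, s: Spectrum) -> float:
        fv = extract_features(
            crop_window(s, self.window), self.pairs_, self.window,
            invalid="impute", medians=self.training_medians_,
        )
        return float(self._inverse_target(forward(self.model_, fv)))

    def predict(self, spectra: Sequence[Spectrum]) -> pd.DataFrame:
        """Predicted M_w (Da) per replicate spectrum."""
        rows = [
            {
                "sample_id": s.sample_id,
                "replicate_id": s.replicate_id,
                "mw_pred_da": self._predict_one(s),
            }
            for s in spectra
        ]
        return pd.DataFrame(rows)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "format_version": _CALIB_FORMAT_VERSION,
            "window": {
                "nu_min": self.window.nu_min,
                "nu_max": self.window.nu_max,
                "abs_threshold": self.window.abs_threshold,
            },
            "pairs": [list(p) for p in self.pairs_],
            "training_medians": np.asarray(self.training_medians_).tolist(),
            "target_transform": self.target_transform,
            "target_range": [self.t_min_, self.t_max_],
            "model": model_to_doc(self.model_),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MwCalibration":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != _CALIB_FORMAT_VERSION:
            raise ValueError("unsupported calibration format")
        obj = cls(window=WindowConfig(**doc["window"]),
                  target_transform=doc.get("target_transform", "log10"))
        obj.pairs_ = [tuple(p) for p in doc["pairs"]]
        obj.training_medians_ = np.array(doc["training_medians"], dtype=float)
        obj.t_min_, obj.t_max_ = (float(v) for v in doc["target_range"])
        obj.model_ = model_from_doc(doc["model"])
        return obj
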