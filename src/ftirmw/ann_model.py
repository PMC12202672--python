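"""Small sigmoid feed-forward network trained by Levenberg-Marquardt.

The regression from selected absorbance ratios to the weight-average molecular
weight is deliberately tiny: the ratio-M_w trends are smooth and saturating,
so a single hidden layer of 3-5 sigmoid units (default 4) approximates them
well, while more capacity only invites overparameterization.  The output unit
is linear; targets are affinely mapped to [0.1, 0.9] of the training M_w range
and inputs standardized per feature, both for conditioning of the least-squares
problem.

Training minimizes the sum of squared residuals in scaled output space with a
damped Gauss-Newton (Levenberg-Marquardt) iteration over the full parameter
vector.  The Jacobian is computed analytically by reverse accumulation
(backpropagation).  Because convergence depends on the random start, training
is restarted from several seeded initializations and the best converged run is
kept; the :class:`TrainingReport` records the convergence audit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "AnnModel",
    "TrainingReport",
    "TrainingError",
    "LMRegressor",
    "forward",
    "forward_matrix",
    "train_lm",
    "split_dataset",
    "evaluate",
    "EvaluationReport",
    "save_model",
    "load_model",
    "model_to_doc",
    "model_from_doc",
]

_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# the serializable model


@dataclass
class AnnModel:
    """Weights, scalers and activation settings of a fitted network.

    ``weights[l]`` has shape (units_out, units_in); predictions are made in
    physical units (Da): inputs pass through the stored per-feature affine
    standardization, the layered affine+sigmoid stack, the linear output unit,
    and the inverse output scaling.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_mean: np.ndarray
    input_scale: np.ndarray
    output_offset: float  # y_scaled = output_offset + output_slope * y
    output_slope: float
    hidden_activation: str = "sigmoid"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        if len(sizes) < 2 or any(s <= 0 for s in sizes):
            raise ValueError("layer_sizes must be >= 2 positive integers")
        if sizes[-1] != 1:
            raise ValueError("output layer must have exactly one unit")
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise ValueError("one weight/bias array per layer transition required")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l + 1], sizes[l]) or b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l}: inconsistent weight/bias shapes")
        if self.hidden_activation not in ("sigmoid", "identity"):
            raise ValueError("hidden_activation must be 'sigmoid' or 'identity'")
        if self.output_activation != "linear":
            raise ValueError("only a linear output unit is supported")
        object.__setattr__(self, "layer_sizes", sizes)

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def scaled_forward(self, Xs: np.ndarray) -> np.ndarray:
        """Network output in scaled space for already-standardized inputs."""
        act = expit if self.hidden_activation == "sigmoid" else (lambda z: z)
        a = Xs
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = act(a @ w.T + b)
        return (a @ self.weights[-1].T + self.biases[-1]).ravel()


def forward_matrix(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Predicted M_w (Da) for each row of a raw feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"expected {model.layer_sizes[0]} features, got {X.shape[1]}"
        )
    Xs = (X - model.input_mean) / model.input_scale
    ys = model.scaled_forward(Xs)
    return (ys - model.output_offset) / model.output_slope


def forward(model: AnnModel, features) -> float:
    """Predicted M_w (Da) for one feature vector."""
    vals = getattr(features, "values", features)
    return float(forward_matrix(model, np.asarray(vals, dtype=float)[None, :])[0])


def model_to_doc(model: AnnModel) -> dict:
    """JSON-ready dict; floats keep shortest round-trip repr, so a load
    reproduces the model bit-exactly."""
    return {
        "format_version": _FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "input_mean": model.input_mean.tolist(),
        "input_scale": model.input_scale.tolist(),
        "output_offset": model.output_offset,
        "output_slope": model.output_slope,
        "hidden_activation": model.hidden_activation,
        "output_activation": model.output_activation,
    }


def save_model(model: AnnModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_doc(model), indent=1))


def model_from_doc(doc: dict) -> AnnModel:
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format {doc.get('format_version')!r}")
    return AnnModel(
        layer_sizes=tuple(doc["layer_sizes"]),
        weights=[np.array(w, dtype=float) for w in doc["weights"]],
        biases=[np.array(b, dtype=float) for b in doc["biases"]],
        input_mean=np.array(doc["input_mean"], dtype=float),
        input_scale=np.array(doc["input_scale"], dtype=float),
        output_offset=float(doc["output_offset"]),
        output_slope=float(doc["output_slope"]),
        hidden_activation=doc["hidden_activation"],
        output_activation=doc["output_activation"],
    )


def load_model(path: str | Path) -> AnnModel:
    return model_from_doc(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core


def _pack(weights: list[np.ndarray], biases: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in zip(weights, biases)])


def _unpack(theta: np.ndarray, sizes: Sequence[int]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases, k = [], [], 0
    for l in range(len(sizes) - 1):
        n_out, n_in = sizes[l + 1], sizes[l]
        weights.append(theta[k:k + n_out * n_in].reshape(n_out, n_in))
        k += n_out * n_in
        biases.append(theta[k:k + n_out])
        k += n_out
    return weights, biases


def _forward_pass(theta, sizes, Xs, activation):
    """Returns per-layer activations and pre-activations; output is linear."""
    weights, biases = _unpack(theta, sizes)
    act = expit if activation == "sigmoid" else (lambda z: z)
    a = Xs
    acts, zs = [Xs], []
    for w, b in zip(weights[:-1], biases[:-1]):
        z = a @ w.T + b
        a = act(z)
        zs.append(z)
        acts.append(a)
    out = (a @ weights[-1].T + biases[-1]).ravel()
    return out, acts, zs, weights


def _jacobian(theta, sizes, Xs, activation):
    """d(output)/d(theta) by reverse accumulation; rows are samples."""
    out, acts, zs, weights = _forward_pass(theta, sizes, Xs, activation)
    n = Xs.shape[0]
    L = len(sizes) - 1
    deltas = [None] * L
    deltas[L - 1] = np.ones((n, 1))
    for l in range(L - 2, -1, -1):
        back = deltas[l + 1] @ weights[l + 1]
        if activation == "sigmoid":
            s = expit(zs[l])
            back = back * s * (1.0 - s)
        deltas[l] = back
    cols = []
    for l in range(L):
        cols.append(np.einsum("nu,nv->nuv", deltas[l], acts[l]).reshape(n, -1))
        cols.append(deltas[l])
    return out, np.concatenate(cols, axis=1)


def _lm_fit(theta0, sizes, Xs, ys, activation, max_iter, tol_grad, tol_sse, patience,
            lam0=1e-3, lam_max=1e12):
    """One LM run.  Returns (theta, sse, status, n_iter).

    status: "grad_tol" | "sse_tol" | "stalled" | "max_iter".  The damping
    factor shrinks after an accepted step and grows after a rejection; a step
    that cannot be accepted at any damping means no descent direction remains
    (a numerical stationary point, reported as "stalled").
    """
    theta = theta0.copy()
    out = _forward_pass(theta, sizes, Xs, activation)[0]
    r = out - ys
    sse = float(r @ r)
    lam = lam0
    flat_count = 0
    status = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        out, J = _jacobian(theta, sizes, Xs, activation)
        r = out - ys
        g = J.T @ r
        if np.max(np.abs(g)) < tol_grad:
            status = "grad_tol"
            break
        A = J.T @ J
        dA = np.diag(A).copy()
        dA[dA < 1e-12] = 1e-12
        accepted = False
        while lam <= lam_max:
            try:
                step = np.linalg.solve(A + lam * np.diag(dA), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            theta_new = theta + step
            out_new = _forward_pass(theta_new, sizes, Xs, activation)[0]
            r_new = out_new - ys
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                rel_drop = (sse - sse_new) / max(sse, 1e-300)
                theta, sse = theta_new, sse_new
                lam = max(lam / 10.0, 1e-12)
                flat_count = flat_count + 1 if rel_drop < tol_sse else 0
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            status = "stalled"
            break
        if flat_count >= patience:
            status = "sse_tol"
            break
    return theta, sse, status, it


@dataclass
class TrainingReport:
    """Convergence audit over the restarts of one training call.

    ``best_restart`` is the restart with the lowest final SSE; ``converged``
    records, per restart, whether a stationarity tolerance fired before the
    iteration budget ran out.
    """

    n_restarts: int
    converged: list[bool]
    final_sse: list[float]
    n_iter: list[int]
    statuses: list[str]
    best_restart: int
    split_seed: int | None = None
    train_fraction: float = 0.8

    @property
    def converged_fraction(self) -> float:
        return sum(self.converged) / self.n_restarts

    def to_dict(self) -> dict:
        return asdict(self)


class TrainingError(RuntimeError):
    """No restart produced a usable fit; carries the per-restart diagnostics."""

    def __init__(self, message: str, report: TrainingReport):
        super().__init__(message)
        self.report = report


class LMRegressor(RegressorMixin, BaseEstimator):
    """Feed-forward sigmoid network regressor trained by Levenberg-Marquardt.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        One or two hidden layers; the default (4,) sits in the 3-5 unit range
        that suffices for smooth saturating ratio-M_w trends.
    n_restarts : int
        Seeded random re-initializations; the best converged run is kept.
    max_iter, tol_grad, tol_sse, sse_patience : LM stopping controls —
        gradient infinity-norm, relative SSE improvement, and how many
        consecutive near-flat accepted steps count as converged.  The
        iteration budget is generous because Gauss-Newton converges only
        linearly once the noisy-residual floor is reached.
    hidden_activation : "sigmoid" or "identity" (the latter makes the network
        purely linear, provided for testing against ordinary least squares).
    random_state : int or None
        Seeds every restart initialization.

    Attributes
    ----------
    model_ : AnnModel, the serializable fitted network.
    report_ : TrainingReport.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (4,),
        n_restarts: int = 10,
        max_iter: int = 2000,
        tol_grad: float = 1e-8,
        tol_sse: float = 1e-10,
        sse_patience: int = 5,
        hidden_activation: str = "sigmoid",
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol_grad = tol_grad
        self.tol_sse = tol_sse
        self.sse_patience = sse_patience
        self.hidden_activation = hidden_activation
        self.random_state = random_state

    def _init_theta(self, rng: np.random.Generator, sizes: Sequence[int]) -> np.ndarray:
        """Nguyen-Widrow initialization for the sigmoid layers.

        Hidden-unit weight vectors are scaled so their active (non-saturated)
        regions tile the standardized input range; without this, early LM
        steps routinely jump into saturation and strand the run in a poor
        local minimum.  The linear output layer starts small and random.
        """
        parts = []
        for l in range(len(sizes) - 2):
            fan_in, fan_out = sizes[l], sizes[l + 1]
            w = rng.standard_normal((fan_out, fan_in))
            norm = np.linalg.norm(w, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            scale = 0.7 * fan_out ** (1.0 / fan_in)
            parts.append((scale * w / norm).ravel())
            parts.append(rng.uniform(-scale, scale, fan_out))
        fan_in = sizes[-2]
        parts.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), sizes[-1] * fan_in))
        parts.append(rng.normal(0.0, 0.1, sizes[-1]))
        return np.concatenate(parts)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        hidden = tuple(int(h) for h in self.hidden_layer_sizes)
        if not 1 <= len(hidden) <= 2:
            raise ValueError("one or two hidden layers are supported")
        sizes = (X.shape[1], *hidden, 1)

        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = (X - mean) / scale
        span = float(np.ptp(y))
        if span == 0:
            raise ValueError("constant targets: nothing to regress")
        slope = 0.8 / span
        offset = 0.1 - slope * float(y.min())
        ys = offset + slope * y

        n_params = sum(sizes[l + 1] * (sizes[l] + 1) for l in range(len(sizes) - 1))
        if n_params > X.shape[0]:
            warnings.warn(
                f"{n_params} parameters for {X.shape[0]} training rows: "
                "the network is overparameterized",
                stacklevel=2,
            )

        root = np.random.default_rng(self.random_state)
        seeds = root.integers(0, 2**31 - 1, size=self.n_restarts)
        thetas, sses, statuses, iters = [], [], [], []
        for s in seeds:
            theta0 = self._init_theta(np.random.default_rng(int(s)), sizes)
            theta, sse, status, it = _lm_fit(
                theta0, sizes, Xs, ys, self.hidden_activation,
                self.max_iter, self.tol_grad, self.tol_sse, self.sse_patience,
            )
            thetas.append(theta)
            sses.append(sse)
            statuses.append(status)
            iters.append(it)
        converged = [st != "max_iter" for st in statuses]
        finite = [i for i in range(self.n_restarts) if np.isfinite(sses[i])]
        if not finite:
            report = TrainingReport(self.n_restarts, converged, sses, iters,
                                    statuses, best_restart=-1)
            raise TrainingError("every restart diverged", report)
        # the convergence flags are an audit of the optimizer, not a gate on
        # deployment: a restart that exhausts its iteration budget while
        # still micro-improving at the noisy-residual floor is routinely a
        # far better model than a sharp local minimum that trips the strict
        # stationarity tolerances, so the best restart is simply the lowest
        # final SSE
        best = min(finite, key=lambda i: sses[i])
        self.report_ = TrainingReport(self.n_restarts, converged, sses, iters,
                                      statuses, best_restart=best)
        weights, biases = _unpack(thetas[best], sizes)
        self.model_ = AnnModel(
            layer_sizes=sizes,
            weights=[w.copy() for w in weights],
            biases=[b.copy() for b in biases],
            input_mean=mean,
            input_scale=scale,
            output_offset=offset,
            output_slope=slope,
            hidden_activation=self.hidden_activation,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return forward_matrix(self.model_, X)


def train_lm(
    X,
    y,
    hidden_layer_sizes: tuple[int, ...] = (4,),
    n_restarts: int = 10,
    seed: int | None = 0,
    **kwargs,
) -> tuple[AnnModel, TrainingReport]:
    """Functional wrapper over :class:`LMRegressor`."""
    reg = LMRegressor(
        hidden_layer_sizes=hidden_layer_sizes,
        n_restarts=n_restarts,
        random_state=seed,
        **kwargs,
    ).fit(X, y)
    return reg.model_, reg.report_


# ---------------------------------------------------------------------------
# split & evaluation harness


def split_dataset(
    X,
    y,
    sample_ids: Sequence[str] | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_by_sample: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random 80/20 row split, stratified by sample so every M_w level is
    represented in validation.  Returns (X_tr, X_va, y_tr, y_va, idx_tr, idx_va).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    idx = np.arange(X.shape[0])
    strat = np.asarray(sample_ids) if (stratify_by_sample and sample_ids is not None) else None
    idx_tr, idx_va = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=strat
    )
    idx_tr, idx_va = np.sort(idx_tr), np.sort(idx_va)
    return X[idx_tr], X[idx_va], y[idx_tr], y[idx_va], idx_tr, idx_va


@dataclass
class EvaluationReport:
    """Predicted-vs-measured table plus region-binned accuracy."""

    frame: pd.DataFrame = field(repr=False)
    rmse: float
    by_region: pd.DataFrame = field(repr=False)

    def region_mean_rel_error(self, label: str) -> float:
        row = self.by_region[self.by_region["region"] == label]
        if row.empty:
            raise KeyError(label)
        return float(row["mean_rel_error"].iloc[0])


def evaluate(
    model: AnnModel | None,
    X,
    y,
    sample_ids: Sequence[str] | None = None,
    bin_edges: Sequence[float] = (200_000.0,),
    predictions: np.ndarray | None = None,
) -> EvaluationReport:
    """Prediction accuracy overall and per M_w region.

    The default single edge at 200 kDa splits the range where the saturating
    ratio-M_w relationship still resolves molecular weight from the region
    where its inverse becomes ill-conditioned.  Pass ``predictions`` to score
    an external predictor instead of ``model``.
    """
    y = np.asarray(y, dtype=float)
    if predictions is None:
        if model is None:
            raise ValueError("either model or predictions must be given")
        predictions = forward_matrix(model, np.asarray(X, dtype=float))
    pred = np.asarray(predictions, dtype=float)
    rel = np.abs(pred - y) / y
    frame = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else [""] * y.size,
            "mw_true_da": y,
            "mw_pred_da": pred,
            "rel_error": rel,
        }
    )
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    edges = [-np.inf, *sorted(bin_edges), np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (y >= lo) & (y < hi)
        if lo == -np.inf:
            label = f"< {hi / 1000:g} kDa"
        elif hi == np.inf:
            label = f">= {lo / 1000:g} kDa"
        else:
            label = f"[{lo / 1000:g}, {hi / 1000:g}) kDa"
        if not np.any(sel):
            continue
        rows.append(
            {
                "region": label,
                "n": int(sel.sum()),
                "rmse_da": float(np.sqrt(np.mean((pred[sel] - y[sel]) ** 2))),
                "mean_rel_error": float(rel[sel].mean()),
            }
        )
    return EvaluationReport(frame=frame, rmse=rmse, by_region=pd.DataFrame(rows))
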