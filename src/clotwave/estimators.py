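"""Feature-based fibrinogen estimators and their leave-one-out evaluation.

Two regressors map the four clot-waveform features (minimum transparency,
maximum absolute gradient, second-derivative extrema) to fibrinogen in
g/L:

* ordinary least squares on the raw features;
* a 4-3-1 neural network (3 tanh hidden units, linear output) trained
  full-batch with Adam on standardized features.

The two are combined by a gating rule: when the network itself predicts
at least 6 g/L its output is used, otherwise the linear prediction is
(the linear model is the more accurate below 6 g/L, the network above).
Evaluation is leave-one-out: for each retained sample, standardizer and
both models are refit on the remaining samples, so no information from
the held-out sample leaks into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from clotwave.waveform import (
    FEATURE_NAMES,
    FeatureVector,
    SampleRecord,
    classify_sample,
    extract_features,
)

COMBINED_GATE_G_PER_L = 6.0


class EstimatorError(ValueError):
    """Invalid estimator input or failed fit."""


def _as_matrix(features) -> np.ndarray:
    rows = [f.as_array() if isinstance(f, FeatureVector) else
            np.asarray(f, dtype=float) for f in features]
    X = np.vstack(rows)
    if X.shape[1] != 4:
        raise EstimatorError("feature matrix must have 4 columns")
    return X


@dataclass(frozen=True)
class Standardizer:
    """Per-feature zero-mean / unit-SD transform fitted on training data."""

    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds


def fit_standardizer(features) -> Standardizer:
    """Fit per-feature mean and SD (sample SD, denominator n-1)."""
    X = _as_matrix(features)
    if X.shape[0] < 2:
        raise EstimatorError("standardizer needs >= 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if s <= 0:
            raise EstimatorError(
                f"feature {FEATURE_NAMES[j]!r} has zero variance")
    return Standardizer(means=means, sds=sds)


@dataclass(frozen=True)
class LinearModel:
    """OLS fibrinogen model: intercept + coefficients on raw features."""

    intercept: float
    coefficients: np.ndarray

    def predict(self, f) -> float:
        x = f.as_array() if isinstance(f, FeatureVector) else \
            np.asarray(f, dtype=float)
        return float(self.intercept + x @ self.coefficients)


def fit_linear(features, targets) -> LinearModel:
    """Ordinary least squares with intercept on the raw features."""
    X = _as_matrix(features)
    y = np.asarray(targets, dtype=float)
    if X.shape[0] != y.size:
        raise EstimatorError("features and targets length mismatch")
    if X.shape[0] < 6:
        raise EstimatorError("OLS needs at least 6 samples (5 parameters)")
    A = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise EstimatorError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    if not np.all(np.isfinite(beta)):
        raise EstimatorError("non-finite OLS solution")
    return LinearModel(intercept=float(beta[0]), coefficients=beta[1:])


@dataclass(frozen=True)
class TrainConfig:
    """Adam training configuration (Keras-style defaults)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    # full-batch Adam moves each parameter by at most ~learning_rate per
    # epoch; covering the g/L output scale from a near-zero initialization
    # needs on the order of 2e4 epochs at the default rate
    epochs: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise EstimatorError("learning_rate must be > 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise EstimatorError("beta1/beta2 must lie in (0, 1)")
        if self.epochs < 1:
            raise EstimatorError("epochs must be >= 1")


@dataclass(frozen=True)
class NNModel:
    """4-3-1 network: y = W2 tanh(W1 x_std + b1) + b2 on standardized x."""

    W1: np.ndarray           # (3, 4)
    b1: np.ndarray           # (3,)
    W2: np.ndarray           # (1, 3)
    b2: float
    standardizer: Standardizer
    seed: int = 0

    def __post_init__(self) -> None:
        if self.W1.shape != (3, 4) or self.b1.shape != (3,) \
                or self.W2.shape != (1, 3):
            raise EstimatorError("weight shapes must match the 4-3-1 "
                                 "architecture")


def nn_forward(model: NNModel, f) -> float:
    """Evaluate the network on one feature vector (g/L output)."""
    x = f.as_array() if isinstance(f, FeatureVector) else \
        np.asarray(f, dtype=float)
    z = model.standardizer.transform(x)
    h = np.tanh(model.W1 @ z + model.b1)
    return float((model.W2 @ h).item() + model.b2)


def _glorot_uniform(rng: np.random.Generator, fan_in: int,
                    fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def fit_nn(features, targets, cfg: Optional[TrainConfig] = None,
           standardizer: Optional[Standardizer] = None) -> NNModel:
    """Train the 4-3-1 network with full-batch Adam on the MSE loss.

    Features are standardized (zero mean, unit SD on the training set)
    before entering the network; weights are Glorot-uniform initialized
    from ``cfg.seed``, making the fit deterministic.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    X = _as_matrix(features)
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if n != y.size:
        raise EstimatorError("features and targets length mismatch")
    if n < 8:
        raise EstimatorError("NN training needs at least 8 samples")
    std = standardizer if standardizer is not None else fit_standardizer(X)
    Z = std.transform(X)

    rng = np.random.default_rng(cfg.seed)
    params = [
        _glorot_uniform(rng, 4, 3, (3, 4)),   # W1
        np.zeros(3),                           # b1
        _glorot_uniform(rng, 3, 1, (1, 3)),   # W2
        np.zeros(1),                           # b2
    ]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]

    for epoch in range(1, cfg.epochs + 1):
        W1, b1, W2, b2 = params
        A1 = Z @ W1.T + b1                    # (n, 3)
        H = np.tanh(A1)
        pred = H @ W2.T + b2                  # (n, 1)
        err = pred[:, 0] - y
        loss = float(np.mean(err ** 2))
        if not math.isfinite(loss):
            raise EstimatorError(f"non-finite training loss at epoch {epoch}")
        # backprop of the full-batch MSE
        g_pred = (2.0 / n) * err[:, None]     # (n, 1)
        gW2 = g_pred.T @ H
        gb2 = g_pred.sum(axis=0)
        g_h = g_pred @ W2                     # (n, 3)
        g_a1 = g_h * (1.0 - H ** 2)
        gW1 = g_a1.T @ Z
        gb1 = g_a1.sum(axis=0)
        grads = [gW1, gb1, gW2, gb2]
        for i in range(4):
            m[i] = cfg.beta1 * m[i] + (1 - cfg.beta1) * grads[i]
            v[i] = cfg.beta2 * v[i] + (1 - cfg.beta2) * grads[i] ** 2
            mhat = m[i] / (1 - cfg.beta1 ** epoch)
            vhat = v[i] / (1 - cfg.beta2 ** epoch)
            params[i] = params[i] - cfg.learning_rate * mhat / (
                np.sqrt(vhat) + cfg.epsilon)

    W1, b1, W2, b2 = params
    return NNModel(W1=W1, b1=b1, W2=W2, b2=float(b2[0]),
                   standardizer=std, seed=cfg.seed)


def predict_combined(lr: LinearModel, nn: NNModel, f) -> float:
    """Gate between the linear and network predictions at 6 g/L.

    The gate variable is the network's own prediction: at or above
    6 g/L the network output is returned, below it the linear output.
    """
    y_nn = nn_forward(nn, f)
    if y_nn >= COMBINED_GATE_G_PER_L:
        return y_nn
    return lr.predict(f)


@dataclass
class Prediction:
    """Per-sample leave-one-out outcome."""

    sample_id: str
    truth: Optional[float]
    linear: Optional[float] = None
    nn: Optional[float] = None
    combined: Optional[float] = None
    inr_stratum: str = "unknown"
    antixa_positive: bool = False
    ddimer_elevated: bool = False
    excluded: bool = False
    reason: str = ""


@dataclass
class PredictionSet:
    """Leave-one-out predictions for a cohort and assay."""

    assay: str
    predictions: list = field(default_factory=list)

    @property
    def retained(self) -> list:
        return [p for p in self.predictions if not p.excluded]

    @property
    def excluded(self) -> list:
        return [p for p in self.predictions if p.excluded]

    def arrays(self, method: str, strata_filter: str = "all"):
        """Paired (truth, prediction) arrays for one method.

        ``strata_filter``: ``"all"`` or ``"regular_only"`` (drops samples
        with INR above 1.1 or positive anti-Xa).
        """
        truths, preds = [], []
        for p in self.retained:
            if strata_filter == "regular_only":
                if p.inr_stratum in ("intermediate", "high") \
                        or p.antixa_positive:
                    continue
            elif strata_filter != "all":
                raise EstimatorError(f"unknown strata filter "
                                     f"{strata_filter!r}")
            truths.append(p.truth)
            preds.append(getattr(p, method))
        return np.asarray(truths, dtype=float), np.asarray(preds, dtype=float)


_ASSAY_KEY = {"PT": "pt", "RT": "rt"}


def loo_evaluate(records: Sequence[SampleRecord], assay: str,
                 cfg: Optional[TrainConfig] = None,
                 methods: Sequence[str] = ("linear", "nn", "combined"),
                 window: int = 5, polyorder: int = 2) -> PredictionSet:
    """Leave-one-out evaluation of all three estimators on a cohort.

    For each retained sample the standardizer, OLS model and network are
    fitted on the remaining samples only; the network seed is offset by
    the fold index so folds are reproducible but not weight-correlated.
    Records missing the assay waveform or the reference fibrinogen are
    excluded with a recorded reason.
    """
    if assay not in _ASSAY_KEY:
        raise EstimatorError("assay must be 'PT' or 'RT'")
    for m in methods:
        if m not in ("linear", "nn", "combined"):
            raise EstimatorError(f"unknown method {m!r}")
    need_nn = "nn" in methods or "combined" in methods
    need_lr = "linear" in methods or "combined" in methods
    cfg = cfg if cfg is not None else TrainConfig()
    key = _ASSAY_KEY[assay]

    out = PredictionSet(assay=assay)
    usable = []
    for rec in records:
        strata = classify_sample(rec)
        pred = Prediction(sample_id=rec.sample_id, truth=rec.fibrinogen_ref,
                          inr_stratum=strata.inr_stratum,
                          antixa_positive=strata.antixa_positive,
                          ddimer_elevated=strata.ddimer_elevated)
        wf = rec.waveforms.get(key)
        if wf is None:
            pred.excluded, pred.reason = True, f"missing {assay} waveform"
        elif rec.fibrinogen_ref is None:
            pred.excluded, pred.reason = True, "missing reference fibrinogen"
        else:
            try:
                feats = extract_features(wf, window=window,
                                         polyorder=polyorder)
            except Exception as exc:
                pred.excluded, pred.reason = True, f"feature extraction: {exc}"
            else:
                usable.append((pred, feats))
        out.predictions.append(pred)

    if len(usable) < 8:
        raise EstimatorError(
            f"only {len(usable)} usable records; need >= 8 for LOO")

    X = _as_matrix([f for _, f in usable])
    y = np.asarray([p.truth for p, _ in usable])
    for i, (pred, feats) in enumerate(usable):
        mask = np.ones(len(usable), dtype=bool)
        mask[i] = False
        fold_cfg = TrainConfig(learning_rate=cfg.learning_rate,
                               beta1=cfg.beta1, beta2=cfg.beta2,
                               epsilon=cfg.epsilon, epochs=cfg.epochs,
                               seed=cfg.seed + i)
        lr = fit_linear(X[mask], y[mask]) if need_lr else None
        nn = fit_nn(X[mask], y[mask], fold_cfg) if need_nn else None
        if "linear" in methods:
            pred.linear = lr.predict(feats)
        if "nn" in methods:
            pred.nn = nn_forward(nn, feats)
        if "combined" in methods:
            pred.combined = predict_combined(lr, nn, feats)
    return out


def pearson_eval(preds: PredictionSet, method: str = "combined",
                 strata_filter: str = "all"):
    """Pearson correlation between predictions and reference fibrinogen.

    Returns ``(r, p, n)`` with a two-sided p-value from the t distribution
    with n - 2 degrees of freedom.
    """
    truths, vals = preds.arrays(method, strata_filter)
    if truths.size < 3:
        raise EstimatorError("Pearson correlation needs >= 3 pairs")
    res = stats.pearsonr(truths, vals)
    return float(res.statistic), float(res.pvalue), int(truths.size)
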