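"""Model construction and training: pathway-masked sparse MLPs and dense
baselines for survival risk and malignancy classification.

The pathway-informed architecture constrains the first layer with a binary
metabolite x pathway incidence mask: the effective first-layer weight is the
elementwise product of a dense weight matrix with the mask, so a connection
exists only where a metabolite belongs to a pathway and the post-ReLU units
are one-per-pathway "pathway activations". Deeper variants add ReLU hidden
layers of a fixed width; the head is a single linear risk unit (Cox loss), a
sigmoid probability (classification), or m units feeding the DeepHit /
PC-Hazard discretizations.

Because the mask multiplies the weight inside the forward pass, gradients at
masked positions are identically zero and those weights stay exactly zero
through any number of training steps.

Training is full-batch Adam with early stopping on validation loss. Inputs
are z-scored per metabolite with training-fold statistics stored in the
model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .data_model import SurvivalDataset
from .losses import (
    TimeGrid,
    balanced_class_weights,
    deephit_gradient,
    deephit_loss,
    pc_hazard_gradient,
    pc_hazard_loss,
    weighted_bce_gradient,
    weighted_binary_cross_entropy,
    _sigmoid,
)
from .pathway_matrix import PathwayMatrix

logger = logging.getLogger("pathsurv")

LossName = Literal["cox", "deephit", "pc_hazard", "bce"]


@dataclass
class RiskModelConfig:
    """Architecture and training hyperparameters.

    ``depth`` counts trainable layers: 2 = first layer + head, 3 adds one
    hidden layer of ``hidden_width``, 4 adds two. ``depth=1`` is a purely
    linear model (risk = w.x + b), used to cross-check the classical Cox fit.
    ``first_width`` sets the first hidden layer's width for dense models
    (ignored when pathway-informed, where it equals the number of pathways).
    """

    depth: int = 3
    input_dim: int = 37
    pathway_informed: bool = False
    hidden_width: int = 64
    first_width: int | None = None
    loss: LossName = "cox"
    head: Literal["survival", "classification"] = "survival"
    n_intervals: int = 10  # m, for deephit / pc_hazard
    alpha: float = 0.5  # deephit mixing
    sigma: float = 0.1  # deephit ranking temperature
    dropout_rate: float = 0.0
    learning_rate: float = 0.003
    max_epochs: int = 400
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth not in (1, 2, 3, 4):
            raise ValueError("depth must be 1, 2, 3 or 4")
        if self.depth == 1 and self.pathway_informed:
            raise ValueError("a linear model has no pathway layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be at least 1")
        if self.head == "classification" and self.loss != "bce":
            raise ValueError("classification head requires the bce loss")
        if self.head == "survival" and self.loss == "bce":
            raise ValueError("survival head cannot use the bce loss")


@dataclass
class RiskModel:
    config: RiskModelConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    mask: PathwayMatrix | None = None
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None
    grid: TimeGrid | None = None
    class_weights: tuple[float, float] | None = None
    fitted: bool = False
    epochs_trained: int = 0
    train_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)

    @property
    def output_dim(self) -> int:
        return self.weights[-1].shape[1]

    # -- forward ---------------------------------------------------------
    def _normalize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in model input")
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected {self.config.input_dim} features, got {X.shape[1]}"
            )
        if self.norm_mean is None:
            return X
        return (X - self.norm_mean) / self.norm_std

    def _effective_first_weight(self) -> np.ndarray:
        if self.mask is not None:
            return self.weights[0] * self.mask.matrix
        return self.weights[0]

    def _forward(self, Xn: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Raw network output plus cached activations for backprop."""
        acts, pres, drop_mask = [Xn], [], None
        h = Xn
        n_layers = len(self.weights)
        for l in range(n_layers - 1):
            W = self._effective_first_weight() if l == 0 else self.weights[l]
            pre = h @ W + self.biases[l]
            h = np.maximum(pre, 0.0)
            if l == 0 and dropout_rng is not None and self.config.dropout_rate > 0:
                keep = 1.0 - self.config.dropout_rate
                drop_mask = (dropout_rng.random(h.shape) < keep) / keep
                h = h * drop_mask
            pres.append(pre)
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return out, acts, pres, drop_mask

    def raw_output(self, X: np.ndarray) -> np.ndarray:
        """Linear-head output on raw (unnormalized) inputs, (N, out_dim)."""
        out, _, _, _ = self._forward(self._normalize(X))
        return out

    def pathway_activations(self, X: np.ndarray) -> np.ndarray:
        """Post-ReLU pathway-layer activations PA, shape (N, Q)."""
        if self.mask is None:
            raise ValueError("model is not pathway-informed")
        Xn = self._normalize(X)
        return np.maximum(Xn @ self._effective_first_weight() + self.biases[0], 0.0)

    def output_from_pathway(self, PA: np.ndarray) -> np.ndarray:
        """Head output of the sub-network mapping pathway activations to the
        model output (used for pathway-level attribution)."""
        if self.mask is None:
            raise ValueError("model is not pathway-informed")
        h = np.asarray(PA, dtype=float)
        for l in range(1, len(self.weights) - 1):
            h = np.maximum(h @ self.weights[l] + self.biases[l], 0.0)
        out = h @ self.weights[-1] + self.biases[-1]
        return self._head_transform(out)

    def _head_transform(self, out: np.ndarray) -> np.ndarray:
        if self.config.loss == "cox":
            return out.ravel()
        if self.config.loss == "bce":
            return _sigmoid(out).ravel()
        if self.config.loss == "deephit":
            from scipy.special import softmax

            return softmax(out, axis=1)
        return np.logaddexp(0.0, out)  # pc_hazard: softplus rates


def build_model(cfg: RiskModelConfig, pm: PathwayMatrix | None = None) -> RiskModel:
    """Initialize a model per config: uniform He-style fan-in init on dense
    weights (applied before masking), zero biases, seeded."""
    if cfg.pathway_informed:
        if pm is None:
            raise ValueError("pathway-informed model requires a pathway matrix")
        if pm.shape[0] != cfg.input_dim:
            raise ValueError(
                f"mask has {pm.shape[0]} metabolite rows for input_dim={cfg.input_dim}"
            )
    rng = np.random.default_rng(cfg.seed)
    out_dim = cfg.n_intervals if cfg.loss in ("deephit", "pc_hazard") else 1
    if cfg.depth == 1:
        dims = [cfg.input_dim, out_dim]
    else:
        first = pm.shape[1] if cfg.pathway_informed else (cfg.first_width or cfg.hidden_width)
        dims = [cfg.input_dim, first] + [cfg.hidden_width] * (cfg.depth - 2) + [out_dim]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    model = RiskModel(config=cfg, weights=weights, biases=biases,
                      mask=pm if cfg.pathway_informed else None)
    if model.mask is not None:
        model.weights[0] = model.weights[0] * model.mask.matrix
    return model


def forward_risk(model: RiskModel, X: np.ndarray) -> np.ndarray:
    """Model output on raw inputs: risk scores (Cox head), sigmoid
    probabilities (classification), hazard masses (DeepHit, rows sum to 1)
    or piecewise hazard rates (PC-Hazard, nonnegative)."""
    return model._head_transform(model.raw_output(X))


def pathway_activations(model: RiskModel, X: np.ndarray) -> np.ndarray:
    return model.pathway_activations(X)


# -- training ------------------------------------------------------------


class _SortedCoxLoss:
    """O(N log N) Cox partial likelihood value/gradient with precomputed
    sort order and tie groups (Breslow denominators, inclusive risk set).
    Normalized by the number of events so learning rates transfer across
    cohort sizes."""

    def __init__(self, events: np.ndarray, durations: np.ndarray):
        events = np.asarray(events, dtype=float).ravel()
        if events.sum() < 1:
            raise ValueError("Cox loss needs at least one event")
        d = np.asarray(durations, dtype=float).ravel()
        self.order = np.argsort(-d, kind="stable")
        ds = d[self.order]
        self.events_sorted = events[self.order]
        # tie groups over the descending-sorted durations
        starts = np.flatnonzero(np.r_[True, ds[1:] != ds[:-1]])
        group_of = np.cumsum(np.r_[False, ds[1:] != ds[:-1]])
        ends = np.r_[starts[1:] - 1, len(ds) - 1]
        self.group_start = starts[group_of]
        self.group_end = ends[group_of]
        self.n_events = float(events.sum())
        self.inv_order = np.argsort(self.order)

    def value_grad(self, risks: np.ndarray):
        h = np.asarray(risks, dtype=float).ravel()[self.order]
        c = np.logaddexp.accumulate(h)  # cumulative logsumexp, descending d
        log_den = c[self.group_end]  # risk set = prefix through tie group
        e = self.events_sorted
        value = -np.sum(e * (h - log_den)) / self.n_events
        s = np.where(e > 0, np.exp(-log_den), 0.0)
        suffix = np.cumsum(s[::-1])[::-1]
        suffix = np.r_[suffix, 0.0]
        grad = -e + np.exp(h) * suffix[self.group_start]
        grad /= self.n_events
        return value, grad[self.inv_order].reshape(-1, 1)


class _LossAdapter:
    """Maps a dataset fold to (value, gradient wrt raw outputs)."""

    def __init__(self, model: RiskModel, events, durations, malignancy):
        self.cfg = model.config
        self.events = np.asarray(events, dtype=int).ravel()
        self.durations = np.asarray(durations, dtype=float).ravel()
        self.malignancy = malignancy
        if self.cfg.loss == "cox":
            self._cox = _SortedCoxLoss(self.events, self.durations)
        elif self.cfg.loss == "deephit":
            self.bin_index = model.grid.bin_index(self.durations)
            self.n = len(self.events)
        elif self.cfg.loss == "pc_hazard":
            self.grid = model.grid
        elif self.cfg.loss == "bce":
            if malignancy is None:
                raise ValueError("bce loss requires malignancy labels")
            self.labels = np.asarray(malignancy, dtype=int).ravel()
            self.class_weights = model.class_weights

    def value(self, out: np.ndarray) -> float:
        cfg = self.cfg
        if cfg.loss == "cox":
            v, _ = self._cox.value_grad(out.ravel())
            return v
        if cfg.loss == "deephit":
            from scipy.special import softmax

            masses = softmax(out, axis=1)
            return deephit_loss(masses, self.events, self.bin_index,
                                cfg.alpha, cfg.sigma) / self.n
        if cfg.loss == "pc_hazard":
            return pc_hazard_loss(np.logaddexp(0.0, out), self.events,
                                  self.durations, self.grid)
        probs = _sigmoid(out.ravel())
        return weighted_binary_cross_entropy(probs, self.labels, self.class_weights)

    def grad(self, out: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        if cfg.loss == "cox":
            _, g = self._cox.value_grad(out.ravel())
            return g
        if cfg.loss == "deephit":
            return deephit_gradient(out, self.events, self.bin_index,
                                    cfg.alpha, cfg.sigma) / self.n
        if cfg.loss == "pc_hazard":
            return pc_hazard_gradient(out, self.events, self.durations, self.grid)
        return weighted_bce_gradient(out, self.labels, self.class_weights)


def fit_model(
    model: RiskModel,
    train: SurvivalDataset,
    val: SurvivalDataset | None = None,
) -> RiskModel:
    """Full-batch Adam with early stopping on validation loss.

    Normalization statistics, the time grid (DeepHit / PC-Hazard, spanning
    [0, max training duration]) and classification class weights are all
    derived from the training fold only. Training restores the best
    validation-loss weights; without a validation fold it runs for
    ``max_epochs``.
    """
    cfg = model.config
    model.norm_mean = train.features.mean(axis=0)
    std = train.features.std(axis=0)
    model.norm_std = np.where(std > 1e-12, std, 1.0)
    if cfg.loss in ("deephit", "pc_hazard"):
        model.grid = TimeGrid.uniform(max(train.durations.max(), 1e-8), cfg.n_intervals)
    if cfg.loss == "bce":
        model.class_weights = balanced_class_weights(train.malignancy)

    Xtr = model._normalize(train.features)
    tr_loss = _LossAdapter(model, train.events, train.durations, train.malignancy)
    if val is not None:
        Xva = model._normalize(val.features)
        va_loss = _LossAdapter(model, val.events, val.durations, val.malignancy)

    rng = np.random.default_rng((cfg.seed * 2654435761 + 17) % (2**31))
    params = model.weights + model.biases
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_val, best_state, best_epoch = np.inf, None, 0
    model.train_history, model.val_history = [], []

    for epoch in range(1, cfg.max_epochs + 1):
        drop_rng = rng if cfg.dropout_rate > 0 else None
        out, acts, pres, drop_mask = model._forward(Xtr, dropout_rng=drop_rng)
        g_out = tr_loss.grad(out)
        grads = _backprop(model, g_out, acts, pres, drop_mask)
        for i, (p, g) in enumerate(zip(params, grads)):
            m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
            v_t[i] = beta2 * v_t[i] + (1 - beta2) * g * g
            mhat = m_t[i] / (1 - beta1**epoch)
            vhat = v_t[i] / (1 - beta2**epoch)
            p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        if model.mask is not None:
            model.weights[0] *= model.mask.matrix  # keep masked entries exact zero
        model.train_history.append(tr_loss.value(out))
        if val is not None:
            vout, _, _, _ = model._forward(Xva)
            vl = va_loss.value(vout)
            model.val_history.append(vl)
            if vl < best_val - 1e-9:
                best_val, best_epoch = vl, epoch
                best_state = ([w.copy() for w in model.weights],
                              [b.copy() for b in model.biases])
            elif epoch - best_epoch >= cfg.patience:
                break
    if best_state is not None:
        model.weights, model.biases = best_state
    model.epochs_trained = epoch
    model.fitted = True
    return model


def _backprop(model: RiskModel, g_out, acts, pres, drop_mask):
    """Gradients of the loss wrt all weights and biases; the first-layer
    weight gradient is masked, so masked entries never move."""
    n_layers = len(model.weights)
    w_grads = [None] * n_layers
    b_grads = [None] * n_layers
    w_grads[-1] = acts[-1].T @ g_out
    b_grads[-1] = g_out.sum(axis=0)
    g = g_out @ model.weights[-1].T
    for l in range(n_layers - 2, -1, -1):
        if l == 0 and drop_mask is not None:
            g = g * drop_mask
        g = g * (pres[l] > 0)
        w_grads[l] = acts[l].T @ g
        b_grads[l] = g.sum(axis=0)
        if l == 0 and model.mask is not None:
            w_grads[0] = w_grads[0] * model.mask.matrix
        if l > 0:
            g = g @ model.weights[l].T
    return w_grads + b_grads


# -- classical Cox-PH ----------------------------------------------------


def fit_cox_ph(X: np.ndarray, events, durations, ridge: float = 0.0) -> np.ndarray:
    """Maximum partial likelihood coefficients of the linear Cox model
    (Newton iterations, Breslow ties). Falls back to a small ridge penalty
    with a warning if the unpenalized fit diverges (separation-like data)."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    X = np.asarray(X, dtype=float)
    events = np.asarray(events, dtype=int).ravel()
    if events.sum() < 1:
        raise ValueError("Cox-PH needs at least one event")
    y = np.empty(len(events), dtype=[("event", bool), ("time", float)])
    y["event"] = events.astype(bool)
    y["time"] = np.asarray(durations, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            est = CoxPHSurvivalAnalysis(alpha=ridge, n_iter=100, tol=1e-9)
            est.fit(X, y)
        except (ValueError, ArithmeticError):
            logger.warning("Cox-PH Newton diverged; refitting with ridge 0.1")
            est = CoxPHSurvivalAnalysis(alpha=0.1, n_iter=100, tol=1e-9)
            est.fit(X, y)
    return est.coef_.copy()


# -- checkpointing -------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(model: RiskModel, path) -> None:
    """Single-archive checkpoint: weights, mask, normalization, config, seed."""
    import json

    arrays = {f"W{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    if model.mask is not None:
        arrays["mask"] = model.mask.matrix
        arrays["mask_metabolites"] = np.array(model.mask.metabolite_names)
        arrays["mask_pathways"] = np.array(model.mask.pathway_names)
    if model.norm_mean is not None:
        arrays["norm_mean"] = model.norm_mean
        arrays["norm_std"] = model.norm_std
    if model.grid is not None:
        arrays["grid"] = model.grid.boundaries
    if model.class_weights is not None:
        arrays["class_weights"] = np.array(model.class_weights)
    meta = {"schema": CHECKPOINT_SCHEMA, "n_layers": len(model.weights),
            "fitted": model.fitted, "config": asdict(model.config)}
    np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> RiskModel:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["_meta"]))
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        cfg = RiskModelConfig(**meta["config"])
        n = meta["n_layers"]
        weights = [z[f"W{i}"] for i in range(n)]
        biases = [z[f"b{i}"] for i in range(n)]
        mask = None
        if "mask" in z:
            mask = PathwayMatrix(z["mask"], [str(s) for s in z["mask_metabolites"]],
                                 [str(s) for s in z["mask_pathways"]])
        model = RiskModel(config=cfg, weights=weights, biases=biases, mask=mask,
                          fitted=bool(meta["fitted"]))
        if "norm_mean" in z:
            model.norm_mean, model.norm_std = z["norm_mean"], z["norm_std"]
        if "grid" in z:
            model.grid = TimeGrid(z["grid"])
        if "class_weights" in z:
            model.class_weights = tuple(z["class_weights"])
    return model
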