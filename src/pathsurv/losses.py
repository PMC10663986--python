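"""Training objectives for deep survival models and the classification head.

Four losses are implemented, each as a value function plus the gradient with
respect to the network's raw outputs (the trainer backpropagates these
through the layers):

* Cox negative log partial likelihood (the DeepSurv objective) with the
  inclusive risk set R(i) = {j : d_j >= d_i} and Breslow handling of ties.
* The DeepHit composite loss: a discrete negative log-likelihood over hazard
  masses plus a pairwise ranking loss on the predicted survival function,
  mixed by ``alpha``.
* The piecewise-constant-hazard (PC-Hazard) mean negative log-likelihood on
  a shared time grid, with hazard-rate constants multiplied by interval
  lengths.
* Class-weighted binary cross-entropy for the malignancy head.

All losses are full-batch: with cohorts of a few hundred samples the Cox
risk set is always complete, avoiding the biased mini-batch partial
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

EPS = 1e-12


# -- time grid -----------------------------------------------------------


@dataclass
class TimeGrid:
    """Ordered interval boundaries T_0 < T_1 < ... < T_m shared by the
    DeepHit discretization and the PC-Hazard pieces."""

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.ndim != 1 or len(self.boundaries) < 2:
            raise ValueError("a grid needs at least two boundaries")
        if not np.all(np.isfinite(self.boundaries)):
            raise ValueError("grid boundaries must be finite")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("grid boundaries must be strictly increasing")
        if self.boundaries[0] < 0:
            raise ValueError("grid boundaries must be nonnegative")

    @property
    def m(self) -> int:
        return len(self.boundaries) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @classmethod
    def uniform(cls, t_max: float, m: int) -> "TimeGrid":
        """Uniform grid of m intervals over [0, t_max]."""
        if t_max <= 0:
            raise ValueError("t_max must be positive")
        return cls(np.linspace(0.0, float(t_max), m + 1))

    def bin_index(self, t: np.ndarray) -> np.ndarray:
        """Right-continuous 1-based bin of each time: T_{k-1} < t <= T_k,
        with t <= T_0 mapped to bin 1 and t > T_m clamped to bin m."""
        t = np.asarray(t, dtype=float)
        k = np.searchsorted(self.boundaries[1:-1], t, side="left") + 1
        return np.clip(k, 1, self.m)


def interval_fraction(t, grid: TimeGrid):
    """Interval index kappa(t) (1-based) and fraction rho(t) in [0, 1].

    Intervals are left-closed, kappa(t) = k iff T_{k-1} <= t < T_k, except
    t = T_m which belongs to the last interval with rho = 1. Times outside
    [T_0, T_m] are clamped to the nearest boundary.
    """
    t = np.clip(np.asarray(t, dtype=float), grid.boundaries[0], grid.boundaries[-1])
    kappa = np.searchsorted(grid.boundaries, t, side="right")
    kappa = np.clip(kappa, 1, grid.m)
    rho = (t - grid.boundaries[kappa - 1]) / grid.widths[kappa - 1]
    return kappa, rho


# -- Cox partial likelihood ----------------------------------------------


def _risk_matrix(durations: np.ndarray) -> np.ndarray:
    """R[i, j] = 1 iff sample j is in the risk set of sample i (d_j >= d_i)."""
    d = np.asarray(durations, dtype=float)
    return (d[None, :] >= d[:, None]).astype(float)


def cox_negative_log_partial_likelihood(risks, events, durations) -> float:
    """-sum over events i of [h_i - log sum_{j: d_j >= d_i} exp(h_j)].

    The inclusive risk set with Breslow-style shared denominators for tied
    event times; shift-invariant in the risks and stabilized by log-sum-exp.
    """
    risks = np.asarray(risks, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    if events.sum() < 1:
        raise ValueError("Cox partial likelihood is undefined with zero events")
    atrisk = _risk_matrix(durations)
    # per-sample denominator over its own risk set, masked logsumexp
    log_den = logsumexp(np.where(atrisk > 0, risks[None, :], -np.inf), axis=1)
    return float(-np.sum(events * (risks - log_den)))


def cox_gradient(risks, events, durations) -> np.ndarray:
    """d loss / d risks for the Cox negative log partial likelihood."""
    risks = np.asarray(risks, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    atrisk = _risk_matrix(durations)
    masked = np.where(atrisk > 0, risks[None, :], -np.inf)
    log_den = logsumexp(masked, axis=1, keepdims=True)
    p = np.exp(masked - log_den)  # p[i, j]: softmax of risks over R(i)
    return -events + events @ p


# -- DeepHit -------------------------------------------------------------


def _check_masses(masses: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    masses = np.asarray(masses, dtype=float)
    if masses.ndim != 2:
        raise ValueError("masses must be an (N, m) matrix")
    if (masses < -tol).any():
        raise ValueError("hazard masses must be nonnegative")
    if np.abs(masses.sum(axis=1) - 1.0).max() > tol:
        raise ValueError("hazard mass rows must sum to 1")
    return masses


def deephit_loss(masses, events, bin_index, alpha: float = 0.5,
                 sigma: float = 0.1) -> float:
    """alpha * loss_L + (1 - alpha) * loss_rank on discrete hazard masses.

    loss_L sums -log mass at the event bin for deceased samples and
    -log S(bin) for censored ones, with S(j) = 1 - cumulative mass through
    bin j. loss_rank sums exp((S_i(k_i) - S_j(k_i)) / sigma) over comparable
    pairs: i deceased and j still at risk past i's time (here: a strictly
    later bin).
    """
    masses = _check_masses(masses)
    events = np.asarray(events, dtype=int).ravel()
    k = np.asarray(bin_index, dtype=int).ravel()  # 1-based
    if k.min() < 1 or k.max() > masses.shape[1]:
        raise ValueError("bin_index out of range")
    surv = 1.0 - np.cumsum(masses, axis=1)  # S(T_j) per sample
    n = len(events)
    own_mass = masses[np.arange(n), k - 1]
    own_surv = surv[np.arange(n), k - 1]
    loss_l = -np.sum(events * np.log(np.maximum(own_mass, EPS))
                     + (1 - events) * np.log(np.maximum(own_surv, EPS)))
    # ranking: pair (i, j) comparable iff event_i and k_j > k_i
    comp = (events[:, None] == 1) & (k[None, :] > k[:, None])
    s_at_i = surv[:, k - 1].T  # s_at_i[i, j] = S_j evaluated at i's bin
    loss_rank = float(np.sum(np.exp((own_surv[:, None] - s_at_i) / sigma) * comp))
    return float(alpha * loss_l + (1 - alpha) * loss_rank)


def deephit_gradient(logits, events, bin_index, alpha: float = 0.5,
                     sigma: float = 0.1) -> np.ndarray:
    """Gradient of the DeepHit loss with respect to the m raw outputs
    (masses = softmax(logits))."""
    logits = np.asarray(logits, dtype=float)
    masses = softmax(logits, axis=1)
    events = np.asarray(events, dtype=int).ravel()
    k = np.asarray(bin_index, dtype=int).ravel()
    n, m = masses.shape
    surv = 1.0 - np.cumsum(masses, axis=1)
    own_mass = np.maximum(masses[np.arange(n), k - 1], EPS)
    own_surv = np.maximum(surv[np.arange(n), k - 1], EPS)

    g_mass = np.zeros_like(masses)  # d loss / d masses
    # loss_L, event samples: -1/mass at own bin
    g_mass[np.arange(n), k - 1] -= alpha * events / own_mass
    # loss_L, censored: -1/S(k) * dS/dmass_j = +1/S(k) for j <= k
    bins = np.arange(1, m + 1)
    le_own = bins[None, :] <= k[:, None]  # j <= k_i
    g_mass += alpha * ((1 - events) / own_surv)[:, None] * le_own

    # ranking term: E[i,j] = exp((S_i(k_i) - S_j(k_i)) / sigma) over pairs
    comp = (events[:, None] == 1) & (k[None, :] > k[:, None])
    s_at_i = surv[:, k - 1].T
    e_pair = np.exp((own_surv[:, None] - s_at_i) / sigma) * comp
    w = (1 - alpha) / sigma
    # dS_i(k_i)/dmass_{i,b} = -[b <= k_i]; dS_j(k_i)/dmass_{j,b} = -[b <= k_i]
    g_mass += -w * e_pair.sum(axis=1)[:, None] * le_own        # via S_i
    g_mass += w * (e_pair.T @ le_own.astype(float))            # via S_j at k_i
    # softmax backward
    return masses * (g_mass - np.sum(g_mass * masses, axis=1, keepdims=True))


# -- PC-Hazard -----------------------------------------------------------


def pc_hazard_loss(etas, events, durations, grid: TimeGrid) -> float:
    """Mean negative log-likelihood under piecewise-constant hazard rates.

    Per sample: -[e * log eta_k - eta_k * rho * dT_k - sum_{j<k} eta_j * dT_j]
    with k = kappa(t), rho the interval fraction, dT the interval widths.
    """
    etas = np.asarray(etas, dtype=float)
    if (etas < 0).any():
        raise ValueError("hazard constants must be nonnegative")
    events = np.asarray(events, dtype=int).ravel()
    kappa, rho = interval_fraction(durations, grid)
    n = len(events)
    dts = grid.widths
    own = etas[np.arange(n), kappa - 1]
    before = np.arange(1, grid.m + 1)[None, :] < kappa[:, None]  # j < kappa
    cum = np.sum(etas * dts[None, :] * before, axis=1)
    ll = events * np.log(np.maximum(own, EPS)) - own * rho * dts[kappa - 1] - cum
    return float(-np.mean(ll))


def pc_hazard_gradient(raw, events, durations, grid: TimeGrid) -> np.ndarray:
    """Gradient with respect to the m raw outputs (etas = softplus(raw))."""
    raw = np.asarray(raw, dtype=float)
    etas = np.logaddexp(0.0, raw)  # softplus
    events = np.asarray(events, dtype=int).ravel()
    kappa, rho = interval_fraction(durations, grid)
    n, m = etas.shape
    dts = grid.widths
    own = np.maximum(etas[np.arange(n), kappa - 1], EPS)
    g = np.zeros_like(etas)
    before = np.arange(1, m + 1)[None, :] < kappa[:, None]
    g += before * dts[None, :]
    g[np.arange(n), kappa - 1] += rho * dts[kappa - 1] - events / own
    g /= n
    return g * _sigmoid(raw)  # softplus backward


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# -- weighted binary cross-entropy ---------------------------------------


def weighted_binary_cross_entropy(probs, labels, class_weights=(1.0, 1.0),
                                  eps: float = 1e-7) -> float:
    """Mean of w_{y_i} * [-y_i log p_i - (1 - y_i) log(1 - p_i)].

    ``class_weights`` is (weight of class 0, weight of class 1); a weight of
    c on one class is equivalent to replicating its samples c times.
    """
    p = np.clip(np.asarray(probs, dtype=float).ravel(), eps, 1 - eps)
    y = np.asarray(labels, dtype=float).ravel()
    w = np.where(y == 1, class_weights[1], class_weights[0])
    ce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(np.mean(w * ce))


def weighted_bce_gradient(logits, labels, class_weights=(1.0, 1.0)) -> np.ndarray:
    """Gradient with respect to the raw logit (probs = sigmoid(logits))."""
    z = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    w = np.where(y == 1, class_weights[1], class_weights[0])
    return (w * (_sigmoid(z) - y) / len(y)).reshape(-1, 1)


def balanced_class_weights(labels) -> tuple[float, float]:
    """Inverse-frequency weights normalized to mean 1 over samples."""
    y = np.asarray(labels, dtype=int).ravel()
    n, n1 = len(y), int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    return n / (2.0 * n0), n / (2.0 * n1)
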