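"""Survival and classification metrics.

Harrell's concordance index scores pairs by a single scalar risk; the
time-dependent (Antolini) variant scores each comparable pair by the
predicted survival probabilities at the earlier patient's event time, so
models whose predicted curves cross are not forced into a single ordering.
Cox-type models get curves through the Breslow baseline cumulative hazard;
discrete-time and piecewise-hazard models carry their own curves.

A pair (i, j) is comparable iff i is an event and d_i < d_j; ties in the
score count 0.5. Tied event durations with both events are handled by the
same 0.5 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .losses import TimeGrid, interval_fraction


@dataclass
class BreslowBaseline:
    """Right-continuous step estimate of the baseline cumulative hazard."""

    times: np.ndarray  # distinct event times, increasing
    jumps: np.ndarray  # hazard increments at those times

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        cum = np.r_[0.0, np.cumsum(self.jumps)]
        return cum[idx]


def breslow_baseline(risks, events, durations) -> BreslowBaseline:
    """Baseline cumulative hazard: sum over event times t_i <= t of
    d_i / sum_{j in R(i)} exp(h_j), risk set inclusive (d_j >= t_i)."""
    risks = np.asarray(risks, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    durations = np.asarray(durations, dtype=float).ravel()
    if events.sum() < 1:
        raise ValueError("Breslow estimator needs at least one event")
    # stabilize exp against large risks; rescaling cancels in S = exp(-L0 e^h)
    # only if applied consistently, so shift both here and in callers' e^h.
    event_times = np.unique(durations[events == 1])
    jumps = np.empty_like(event_times)
    exp_h = np.exp(risks - risks.max())
    scale = np.exp(risks.max())
    for i, t in enumerate(event_times):
        d_i = np.sum((durations == t) & (events == 1))
        denom = exp_h[durations >= t].sum() * scale
        jumps[i] = d_i / denom
    return BreslowBaseline(times=event_times, jumps=jumps)


@dataclass
class SurvivalCurveMatrix:
    """Predicted survival probabilities, one row per sample over a shared
    ordered evaluation-time axis; rows are nonincreasing in time."""

    times: np.ndarray
    S: np.ndarray  # (N, T)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape[1] != len(self.times):
            raise ValueError("S columns must match evaluation times")
        if (self.S < -1e-9).any() or (self.S > 1 + 1e-9).any():
            raise ValueError("survival probabilities must lie in [0, 1]")
        if (np.diff(self.S, axis=1) > 1e-9).any():
            raise ValueError("survival curves must be nonincreasing")

    def at(self, t) -> np.ndarray:
        """Step-function lookup S(t) per sample: value at the largest
        evaluation time <= t, and 1 before the first one."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        padded = np.hstack([np.ones((self.S.shape[0], 1)), self.S])
        return padded[:, idx + 1]


def cox_survival_curves(risks, baseline: BreslowBaseline, times=None) -> SurvivalCurveMatrix:
    """S(t | x) = exp(-L0(t) * exp(h(x))) on a shared baseline."""
    risks = np.asarray(risks, dtype=float).ravel()
    times = baseline.times if times is None else np.asarray(times, dtype=float)
    L0 = baseline.cumulative_hazard(times)
    S = np.exp(-np.outer(np.exp(risks), L0))
    return SurvivalCurveMatrix(times=times, S=S)


def deephit_survival_curves(masses, grid: TimeGrid) -> SurvivalCurveMatrix:
    """S(T_j) = 1 - cumulative hazard mass through bin j, evaluated at the
    right boundaries of the grid."""
    masses = np.asarray(masses, dtype=float)
    S = np.clip(1.0 - np.cumsum(masses, axis=1), 0.0, 1.0)
    return SurvivalCurveMatrix(times=grid.boundaries[1:], S=S)


def pc_hazard_survival_curves(etas, grid: TimeGrid, times=None) -> SurvivalCurveMatrix:
    """S(t) = exp(-sum_{j<k} eta_j dT_j - eta_k rho(t) dT_k)."""
    etas = np.asarray(etas, dtype=float)
    times = grid.boundaries[1:] if times is None else np.asarray(times, dtype=float)
    kappa, rho = interval_fraction(times, grid)
    dts = grid.widths
    cum_full = np.hstack([np.zeros((etas.shape[0], 1)),
                          np.cumsum(etas * dts[None, :], axis=1)])
    H = cum_full[:, kappa - 1] + etas[:, kappa - 1] * (rho * dts[kappa - 1])[None, :]
    return SurvivalCurveMatrix(times=times, S=np.exp(-H))


def survival_curves(model, X, baseline: BreslowBaseline | None = None,
                    times=None) -> SurvivalCurveMatrix:
    """Predicted survival curves for a fitted network of any survival head."""
    from .networks import RiskModel, forward_risk

    assert isinstance(model, RiskModel)
    out = forward_risk(model, X)
    if model.config.loss == "cox":
        if baseline is None:
            raise ValueError("Cox-type curves need a Breslow baseline")
        return cox_survival_curves(out, baseline, times=times)
    if model.config.loss == "deephit":
        return deephit_survival_curves(out, model.grid)
    if model.config.loss == "pc_hazard":
        return pc_hazard_survival_curves(out, model.grid, times=times)
    raise ValueError("classification models have no survival curves")


# -- concordance ---------------------------------------------------------


def _comparable_mask(events, durations):
    events = np.asarray(events, dtype=int).ravel()
    d = np.asarray(durations, dtype=float).ravel()
    return (events[:, None] == 1) & (d[:, None] < d[None, :])


def harrell_cindex(risks, events, durations) -> float:
    """Fraction of comparable pairs ranked concordantly by scalar risk
    (higher risk for the earlier event), ties counting one half."""
    risks = np.asarray(risks, dtype=float).ravel()
    comp = _comparable_mask(events, durations)
    n_pairs = comp.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    conc = (risks[:, None] > risks[None, :]) & comp
    tied = (risks[:, None] == risks[None, :]) & comp
    return float((conc.sum() + 0.5 * tied.sum()) / n_pairs)


def antolini_cindex(curves: SurvivalCurveMatrix, events, durations) -> float:
    """Time-dependent concordance: pair (i, j) with i an event at d_i < d_j
    is concordant iff S_i(d_i) < S_j(d_i)."""
    d = np.asarray(durations, dtype=float).ravel()
    comp = _comparable_mask(events, durations)
    n_pairs = comp.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    s_at = curves.at(d)  # s_at[j, i] = S_j(d_i)
    s_own = s_at[np.arange(len(d)), np.arange(len(d))]
    conc = (s_own[:, None] < s_at.T) & comp
    tied = (s_own[:, None] == s_at.T) & comp
    return float((conc.sum() + 0.5 * tied.sum()) / n_pairs)


def classification_metrics(probs, labels) -> dict[str, float]:
    """AUROC (trapezoidal) and AUPRC (precision-recall step integration)."""
    labels = np.asarray(labels, dtype=int).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return {
        "auroc": float(roc_auc_score(labels, probs)),
        "auprc": float(average_precision_score(labels, probs)),
    }
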