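"""Shapley-value importance for input metabolites and pathway activations.

Attributions use the interventional convention: a feature absent from a
coalition is replaced by its background-set mean. ``exact_shapley``
enumerates all coalitions (feasible to ~12 features) and is the oracle for
the permutation-sampling estimator used at metabolite (P=37) and pathway
(Q=138) scale. Per-feature importance is the mean absolute attribution
across evaluated samples, so effects of opposite sign across samples do not
cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np


@dataclass
class AttributionReport:
    feature_names: list[str]
    attributions: np.ndarray  # (N, d) per-sample Shapley values
    importance: np.ndarray  # (d,) mean |attribution|
    ranking: np.ndarray  # feature indices, most important first

    @classmethod
    def from_attributions(cls, attributions: np.ndarray,
                          feature_names: list[str]) -> "AttributionReport":
        attributions = np.atleast_2d(np.asarray(attributions, dtype=float))
        importance = np.abs(attributions).mean(axis=0)
        # stable sort so exact ties rank deterministically by feature order
        ranking = np.argsort(-importance, kind="stable")
        return cls(list(feature_names), attributions, importance, ranking)

    def top(self, k: int) -> list[str]:
        return [self.feature_names[i] for i in self.ranking[:k]]


def _coalition_values(scoring_fn, x, background_mean, coalitions) -> np.ndarray:
    """Evaluate f on x with features outside each coalition mean-imputed;
    one batched call covering all coalitions."""
    X = np.where(coalitions, x[None, :], background_mean[None, :])
    return np.asarray(scoring_fn(X), dtype=float).ravel()


def exact_shapley(scoring_fn, x, background, max_features: int = 12) -> np.ndarray:
    """Classic Shapley values by full coalition enumeration.

    ``scoring_fn`` maps an (n, d) matrix to n scalars; ``background`` is the
    reference matrix whose column means impute absent features. Satisfies
    efficiency: attributions sum to f(x) - f(background mean).
    """
    x = np.asarray(x, dtype=float).ravel()
    d = len(x)
    if d > max_features:
        raise ValueError(
            f"{d} features exceeds max_features={max_features}; "
            "use sampled_shapley instead"
        )
    bg_mean = np.asarray(background, dtype=float).reshape(-1, d).mean(axis=0)
    # all 2^d coalitions as a bit table
    codes = np.arange(2**d)
    coalitions = (codes[:, None] >> np.arange(d)) & 1 == 1
    values = _coalition_values(scoring_fn, x, bg_mean, coalitions)
    sizes = coalitions.sum(axis=1)
    w = np.array([factorial(s) * factorial(d - s - 1) / factorial(d)
                  for s in range(d)])
    phi = np.zeros(d)
    for i in range(d):
        has_i = coalitions[:, i]
        without = codes[has_i] ^ (1 << i)  # same coalition minus feature i
        marginal = values[has_i] - values[without]
        phi[i] = np.sum(w[sizes[has_i] - 1] * marginal)
    return phi


def sampled_shapley(scoring_fn, x, background, n_permutations: int = 200,
                    seed: int = 0) -> np.ndarray:
    """Unbiased permutation-sampling Shapley estimate.

    For each sampled permutation, features are inserted one by one and the
    marginal change in f is credited to the inserted feature; all coalition
    evaluations for a permutation go through one batched call.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    x = np.asarray(x, dtype=float).ravel()
    d = len(x)
    bg_mean = np.asarray(background, dtype=float).reshape(-1, d).mean(axis=0)
    rng = np.random.default_rng(seed)
    base = float(np.asarray(scoring_fn(bg_mean[None, :])).ravel()[0])
    phi = np.zeros(d)
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        coalitions = np.zeros((d, d), dtype=bool)
        mask = np.zeros(d, dtype=bool)
        for step, j in enumerate(perm):
            mask[j] = True
            coalitions[step] = mask
        values = _coalition_values(scoring_fn, x, bg_mean, coalitions)
        prev = np.r_[base, values[:-1]]
        phi[perm] += values - prev
    return phi / n_permutations


def _shapley_matrix(scoring_fn, X, background, n_permutations, seed,
                    exact_limit: int = 10) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    out = np.empty_like(X)
    for i, x in enumerate(X):
        if d <= exact_limit:
            out[i] = exact_shapley(scoring_fn, x, background, max_features=exact_limit)
        else:
            out[i] = sampled_shapley(scoring_fn, x, background,
                                     n_permutations=n_permutations,
                                     seed=(seed + 31 * i) % (2**31))
    return out


def metabolite_importance(model, X, background, n_permutations: int = 200,
                          seed: int = 0) -> AttributionReport:
    """Per-sample attributions of the model's scalar output (risk score or
    class probability) to the P input metabolites."""
    from .networks import RiskModel, forward_risk

    assert isinstance(model, RiskModel)
    if model.config.loss not in ("cox", "bce"):
        raise ValueError("attribution needs a scalar-output model")
    attrs = _shapley_matrix(lambda A: forward_risk(model, A), X, background,
                            n_permutations, seed)
    if model.mask is not None:
        names = list(model.mask.metabolite_names)
    else:
        names = [f"feature_{j}" for j in range(np.atleast_2d(X).shape[1])]
    return AttributionReport.from_attributions(attrs, names)


def pathway_importance(model, X, background, n_permutations: int = 200,
                       seed: int = 0) -> AttributionReport:
    """Attributions of the sub-network mapping pathway activations to the
    output, with each sample's activation vector as the explained input and
    the background set's activations as the reference."""
    from .networks import RiskModel

    assert isinstance(model, RiskModel)
    if model.mask is None:
        raise ValueError("pathway importance requires a pathway-informed model")
    if model.config.loss not in ("cox", "bce"):
        raise ValueError("attribution needs a scalar-output model")
    PA = model.pathway_activations(np.atleast_2d(X))
    PA_bg = model.pathway_activations(np.atleast_2d(background))
    attrs = _shapley_matrix(model.output_from_pathway, PA, PA_bg,
                            n_permutations, seed)
    return AttributionReport.from_attributions(attrs, list(model.mask.pathway_names))


def contribution_flows(model, X, background, pathway_report: AttributionReport,
                       n_permutations: int = 50, seed: int = 0):
    """Edge-weighted metabolite-to-pathway flow table behind a Sankey view.

    For every mask edge (metabolite m, pathway q) the flow weight is the
    mean over samples of |Shapley share of m among q's member inputs| for
    the single-unit function x -> PA_q(x), rescaled so each pathway's
    incoming flows sum to that pathway's importance.
    """
    import pandas as pd

    from .networks import RiskModel

    assert isinstance(model, RiskModel)
    if model.mask is None:
        raise ValueError("flows require a pathway-informed model")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mask = model.mask.matrix
    rows = []
    imp = {name: pathway_report.importance[i]
           for i, name in enumerate(pathway_report.feature_names)}
    for q, pname in enumerate(model.mask.pathway_names):
        members = np.flatnonzero(mask[:, q])
        if len(members) == 0:
            continue

        def unit(A, q=q, members=members):
            # PA_q as a function of the member metabolites only
            full = np.tile(X.mean(axis=0), (A.shape[0], 1))
            full[:, members] = A
            return model.pathway_activations(full)[:, q]

        shares = np.abs(_shapley_matrix(
            unit, X[:, members], np.asarray(background)[:, members],
            n_permutations, (seed + q) % (2**31))).mean(axis=0)
        total = shares.sum()
        target = imp[pname]
        scaled = shares * (target / total) if total > 0 else np.full(
            len(members), target / len(members))
        for m_idx, weight in zip(members, scaled):
            rows.append({"metabolite": model.mask.metabolite_names[m_idx],
                         "pathway": pname, "flow": float(weight)})
    return pd.DataFrame(rows, columns=["metabolite", "pathway", "flow"])
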