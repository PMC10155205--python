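"""Model-agnostic Shapley attribution of predicted class-1 probability.

Treats a prediction as a cooperative game among features: a feature's
Shapley value is its average marginal contribution over orderings, with
absent features marginalised by drawing their values from background
(training) rows. Two estimators are provided — a Monte-Carlo permutation
sampler for real use, and an exact subset enumerator (feasible to ~12
features) that serves as its oracle. Global importance is ranked by the
mean absolute per-sample attribution (|avSHAP|).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd


@dataclass
class AttributionSet:
    """Per-sample, per-feature Shapley values in probability units."""

    values: pd.DataFrame  # samples × features
    std_errors: pd.DataFrame  # Monte-Carlo SE per value (0 for exact)
    baseline: float  # expected model output over the background
    model_outputs: np.ndarray  # f(x) per explained sample


@dataclass(frozen=True)
class ImportanceRow:
    feature: str
    av_shap: float
    rank: int


@dataclass
class DependenceSeries:
    feature: str
    feature_values: np.ndarray
    shap_values: np.ndarray
    coloring_feature: str | None
    coloring_values: np.ndarray | None
    notice: str | None = None


def _to_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def shapley_sampling(
    model_fn,
    X,
    background,
    n_permutations: int = 200,
    seed: int = 0,
) -> AttributionSet:
    """Monte-Carlo permutation estimate of Shapley values.

    For each explained sample, ``n_permutations`` random feature orderings
    are drawn, each paired with one background row; walking along the
    ordering, features switch from the background value to the sample's
    value and the model-output increments are credited to the switched
    feature. Per-value standard errors come from the spread over
    permutations. Deterministic for a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Xf = _to_frame(X)
    Bf = _to_frame(background)
    if len(Bf) == 0:
        raise ValueError("background must be non-empty")
    if list(Xf.columns) != list(Bf.columns):
        raise ValueError("X and background must share feature columns")
    feats = list(Xf.columns)
    d = len(feats)
    Xa = Xf.to_numpy(dtype=float)
    Ba = Bf.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    baseline = float(np.mean(model_fn(Ba)))
    outputs = np.asarray(model_fn(Xa), dtype=float)

    phi = np.zeros((len(Xa), d))
    se = np.zeros((len(Xa), d))
    for s in range(len(Xa)):
        x = Xa[s]
        contrib = np.zeros((n_permutations, d))
        for m in range(n_permutations):
            order = rng.permutation(d)
            b = Ba[rng.integers(len(Ba))]
            # build the chain of mixed vectors in one batched model call
            chain = np.tile(b, (d + 1, 1))
            mask = np.zeros(d, dtype=bool)
            for step, j in enumerate(order):
                mask[j] = True
                chain[step + 1, mask] = x[mask]
            out = np.asarray(model_fn(chain), dtype=float)
            contrib[m, order] = np.diff(out)
        phi[s] = contrib.mean(axis=0)
        se[s] = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations) \
            if n_permutations > 1 else np.zeros(d)
    return AttributionSet(
        values=pd.DataFrame(phi, index=Xf.index, columns=feats),
        std_errors=pd.DataFrame(se, index=Xf.index, columns=feats),
        baseline=baseline,
        model_outputs=outputs,
    )


def shapley_exact(model_fn, x, background, max_features: int = 12) -> np.ndarray:
    """Exact Shapley values by full subset enumeration (d <= ``max_features``).

    The value of a coalition S is the mean model output with features in S
    taken from ``x`` and the rest from each background row in turn.
    """
    Bf = _to_frame(background)
    Ba = Bf.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    if d > max_features:
        raise ValueError(f"exact enumeration limited to {max_features} features, got {d}")
    if len(Ba) == 0:
        raise ValueError("background must be non-empty")

    n_subsets = 1 << d
    # batched coalition values: v[S] = mean_b f(x_S, b_~S)
    v = np.zeros(n_subsets)
    rows = np.empty((n_subsets * len(Ba), d))
    for S in range(n_subsets):
        mask = np.array([(S >> j) & 1 for j in range(d)], dtype=bool)
        block = Ba.copy()
        block[:, mask] = x[mask]
        rows[S * len(Ba):(S + 1) * len(Ba)] = block
    out = np.asarray(model_fn(rows), dtype=float)
    v = out.reshape(n_subsets, len(Ba)).mean(axis=1)

    phi = np.zeros(d)
    fact = [factorial(k) for k in range(d + 1)]
    for S in range(n_subsets):
        size = bin(S).count("1")
        w = fact[size] * fact[d - size - 1] / fact[d]
        for j in range(d):
            if not (S >> j) & 1:
                phi[j] += w * (v[S | (1 << j)] - v[S])
    return phi


def importance_ranking(attributions: AttributionSet, top_k: int = 10) -> list[ImportanceRow]:
    """Features ranked by mean absolute Shapley value (|avSHAP|), descending."""
    if attributions.values.empty:
        raise ValueError("empty attribution set")
    av = attributions.values.abs().mean(axis=0).sort_values(ascending=False)
    return [
        ImportanceRow(feature=name, av_shap=float(val), rank=i + 1)
        for i, (name, val) in enumerate(av.head(top_k).items())
    ]


def dependence_data(attributions: AttributionSet, X, feature: str) -> DependenceSeries:
    """(feature value, Shapley value) pairs for one feature, coloured by the
    input feature most Pearson-correlated with it (multicollinearity check)."""
    Xf = _to_frame(X)
    if feature not in Xf.columns:
        raise KeyError(f"feature {feature!r} not in X")
    fv = Xf[feature].to_numpy(dtype=float)
    sv = attributions.values[feature].to_numpy(dtype=float)

    coloring = None
    coloring_vals = None
    notice = None
    if np.std(fv) == 0:
        notice = f"feature {feature!r} is constant; coloring feature omitted"
    else:
        best_name, best_corr = None, 0.0
        for other in Xf.columns:
            if other == feature:
                continue
            ov = Xf[other].to_numpy(dtype=float)
            if np.std(ov) == 0:
                continue
            c = abs(float(np.corrcoef(fv, ov)[0, 1]))
            if np.isfinite(c) and c > best_corr:
                best_name, best_corr = other, c
        if best_name is not None:
            coloring = best_name
            coloring_vals = Xf[best_name].to_numpy(dtype=float)
        else:
            notice = "no varying co-feature available for coloring"
    return DependenceSeries(
        feature=feature,
        feature_values=fv,
        shap_values=sv,
        coloring_feature=coloring,
        coloring_values=coloring_vals,
        notice=notice,
    )


def write_importance_csv(path, ranking: list[ImportanceRow]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variable,avSHAP\n")
        for row in ranking:
            fh.write(f"{row.feature},{row.av_shap}\n")


def write_attributions_csv(path, attributions: AttributionSet) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# baseline,{attributions.baseline}\n")
        attributions.values.to_csv(fh)
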