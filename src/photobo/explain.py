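"""Shapley-value attribution for surrogate predictions.

A prediction f(x) is decomposed into a base value (the expected model output
over a background set) plus one additive contribution phi_i per feature,
satisfying the efficiency axiom base + sum(phi) = f(x).  Absent features are
marginalized over the background: the value of a coalition S is the mean of
f over instances whose features in S are taken from x and whose remaining
features come from background rows.

Two estimators are provided: exact enumeration of all feature coalitions
(capped at 20 features) and a seeded permutation-sampling estimator that
converges to the exact values as the number of permutations grows.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError


@dataclass
class ShapExplanation:
    """Per-feature contributions for one explained instance."""

    instance_id: str
    base_value: float
    phi: np.ndarray
    prediction: float
    feature_names: list[str] | None = None

    def efficiency_gap(self) -> float:
        return abs(self.base_value + float(np.sum(self.phi)) - self.prediction)


@dataclass
class ShapConfig:
    mode: str = "exact"     # "exact" | "sampled"
    n_samples: int = 2048   # permutations for the sampled estimator
    seed: int = 0
    exact_feature_cap: int = 20


def _coalition_value(predict_fn, background: np.ndarray, x: np.ndarray, mask: np.ndarray) -> float:
    """Mean model output with features in `mask` fixed to x, rest from background."""
    hybrid = background.copy()
    hybrid[:, mask] = x[mask]
    return float(np.mean(predict_fn(hybrid)))


def _exact_shapley(predict_fn, background, x):
    m = x.size
    idx = np.arange(m)
    # cache coalition values keyed by bitmask
    values: dict[int, float] = {}

    def value(bits: int) -> float:
        if bits not in values:
            mask = np.array([(bits >> i) & 1 for i in range(m)], dtype=bool)
            values[bits] = _coalition_value(predict_fn, background, x, mask)
        return values[bits]

    phi = np.zeros(m)
    fact = [math.factorial(i) for i in range(m + 1)]
    for size in range(m):
        w = fact[size] * fact[m - size - 1] / fact[m]
        for S in itertools.combinations(idx, size):
            bits = sum(1 << i for i in S)
            vS = value(bits)
            for i in idx:
                if not (bits >> i) & 1:
                    phi[i] += w * (value(bits | (1 << i)) - vS)
    return phi, value(0), value((1 << m) - 1)


def _sampled_shapley(predict_fn, background, x, n_samples, seed):
    m = x.size
    rng = np.random.default_rng(seed)
    phi = np.zeros(m)
    base = float(np.mean(predict_fn(background)))
    for _ in range(n_samples):
        order = rng.permutation(m)
        hybrid = background.copy()
        prev = base
        for i in order:
            hybrid[:, i] = x[i]
            cur = float(np.mean(predict_fn(hybrid)))
            phi[i] += cur - prev
            prev = cur
    return phi / n_samples, base


def shapley_values(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
    cfg: ShapConfig = ShapConfig(),
    instance_id: str = "",
    feature_names: Sequence[str] | None = None,
) -> ShapExplanation:
    """Background-marginalized Shapley attribution of one model prediction.

    Exact mode enumerates all 2^m coalitions and satisfies efficiency by
    construction; sampled mode averages marginal contributions over seeded
    random feature orderings and converges to exact as n_samples grows.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(instance, dtype=float).ravel()
    if background.shape[0] < 1:
        raise ValidationError("background set must be non-empty")
    if background.shape[1] != x.size:
        raise ValidationError("instance and background feature counts differ")
    m = x.size
    prediction = float(np.mean(predict_fn(x[None, :])))
    if cfg.mode == "exact":
        if m > cfg.exact_feature_cap:
            raise ValidationError(
                f"exact mode enumerates 2^{m} coalitions; use mode='sampled' "
                f"beyond {cfg.exact_feature_cap} features"
            )
        phi, base, _ = _exact_shapley(predict_fn, background, x)
    elif cfg.mode == "sampled":
        phi, base = _sampled_shapley(predict_fn, background, x, cfg.n_samples, cfg.seed)
    else:
        raise ValidationError(f"unknown mode {cfg.mode!r}")
    return ShapExplanation(
        instance_id=instance_id, base_value=base, phi=phi, prediction=prediction,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def explain_set(predict_fn, background, instances, cfg=ShapConfig(), ids=None, feature_names=None):
    """Explain a batch of instances against a shared background."""
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    ids = ids or [f"instance-{i}" for i in range(len(instances))]
    return [
        shapley_values(predict_fn, background, row, cfg, instance_id=iid,
                       feature_names=feature_names)
        for iid, row in zip(ids, instances)
    ]


def global_importance(explanations: Sequence[ShapExplanation]) -> list[tuple[str, float]]:
    """Rank features by mean |phi| across instances (descending).

    Ties break by canonical feature order.  All explanations must share one
    feature ordering.
    """
    if not explanations:
        raise ValidationError("no explanations given")
    names = explanations[0].feature_names
    m = explanations[0].phi.size
    for e in explanations:
        if e.phi.size != m or e.feature_names != names:
            raise ValidationError("explanations have inconsistent feature sets")
    names = names or [f"f{i}" for i in range(m)]
    mean_abs = np.mean([np.abs(e.phi) for e in explanations], axis=0)
    order = sorted(range(m), key=lambda i: (-mean_abs[i], i))
    return [(names[i], float(mean_abs[i])) for i in order]
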