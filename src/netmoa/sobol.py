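"""Variance-based Sobol sensitivity indices via Saltelli-style sampling.

First-order and total-order indices are estimated with the Jansen (1999)
estimators on the classic A/B/AB_i sample design: for d parameters and a
base sample of size N the model is evaluated N * (d + 2) times. Inputs are
sampled uniformly on per-parameter intervals.

Estimator forms (V = Var of all f(A), f(B) evaluations pooled):

    S_i = (V - mean((f(B) - f(AB_i))^2) / 2) / V
    T_i = mean((f(A) - f(AB_i))^2) / (2 V)

For additive models the first-order indices sum to 1 up to Monte-Carlo
error, and T_i >= S_i within the same tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


class SobolError(ValueError):
    pass


@dataclass
class SobolResult:
    first_order: np.ndarray
    total_order: np.ndarray
    n_samples: int


def saltelli_sample(bounds: Sequence[tuple[float, float]], n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample matrix of shape (n * (d + 2), d) in A, B, AB_1..AB_d order."""
    d = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    a = lo + (hi - lo) * rng.random((n, d))
    b = lo + (hi - lo) * rng.random((n, d))
    blocks = [a, b]
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    return np.vstack(blocks)


def sobol_indices_from_evals(values: np.ndarray, d: int, n: int) -> SobolResult:
    """Indices from model evaluations laid out as saltelli_sample output."""
    if len(values) != n * (d + 2):
        raise SobolError("evaluation count does not match sample layout")
    f_a = values[:n]
    f_b = values[n:2 * n]
    variance = float(np.var(np.concatenate([f_a, f_b])))
    if variance == 0:
        raise SobolError("model output has zero variance over the sample")
    first = np.empty(d)
    total = np.empty(d)
    for i in range(d):
        f_ab = values[(2 + i) * n:(3 + i) * n]
        first[i] = (variance - np.mean((f_b - f_ab) ** 2) / 2) / variance
        total[i] = np.mean((f_a - f_ab) ** 2) / (2 * variance)
    return SobolResult(first_order=first, total_order=total, n_samples=n)


def sobol_indices(func: Callable[[np.ndarray], np.ndarray] | Callable,
                  bounds: Sequence[tuple[float, float]], n: int,
                  rng: np.random.Generator,
                  vectorized: bool = True) -> SobolResult:
    """Estimate Sobol indices of ``func`` over a uniform box.

    ``func`` maps an (m, d) sample matrix to m outputs when vectorized,
    otherwise a single d-vector to a scalar.
    """
    d = len(bounds)
    if d < 2:
        raise SobolError("variance decomposition needs >= 2 parameters")
    if n < 64:
        raise SobolError("use at least 64 base samples")
    sample = saltelli_sample(bounds, n, rng)
    if vectorized:
        values = np.asarray(func(sample), dtype=float)
    else:
        values = np.array([float(func(x)) for x in sample])
    return sobol_indices_from_evals(values, d, n)
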