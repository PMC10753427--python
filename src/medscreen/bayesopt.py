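"""Sequential model-based (Bayesian) minimization for hyperparameter search.

A compact Gaussian-process optimizer in the style of classical SMBO: the
search space is mapped to the unit cube (log-scaled dimensions where
declared), an anisotropic Matern-5/2 GP models the observed objective, and
each iteration maximizes expected improvement over a random candidate set.
Integer dimensions are rounded on decode. Fully deterministic given a seed.

The first ``n_initial`` evaluations are space-filling random draws; with a
budget of 1 the single random configuration is returned, which keeps the
optimizer usable as a plain random search at tiny budgets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    scale: str = "linear"  # "linear" | "log" | "int"

    def decode(self, u: float) -> float | int:
        if self.scale == "log":
            lo, hi = np.log(self.low), np.log(self.high)
            return float(np.exp(lo + u * (hi - lo)))
        value = self.low + u * (self.high - self.low)
        if self.scale == "int":
            return int(np.clip(round(value), self.low, self.high))
        return float(value)


def parse_space(space: Mapping[str, tuple]) -> list[Dimension]:
    """Space entries are ``name: (low, high)`` or ``(low, high, scale)``."""
    dims = []
    for name, spec in space.items():
        lo, hi = float(spec[0]), float(spec[1])
        scale = spec[2] if len(spec) > 2 else "linear"
        if hi < lo:
            raise ValueError(f"dimension '{name}': bounds not ordered")
        if scale == "log" and lo <= 0:
            raise ValueError(f"dimension '{name}': log scale needs positive bounds")
        dims.append(Dimension(name, lo, hi, scale))
    return dims


def _decode(dims: list[Dimension], u: np.ndarray) -> dict:
    return {d.name: d.decode(ui) for d, ui in zip(dims, u)}


def _expected_improvement(mu, sigma, best) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def minimize(
    objective: Callable[[dict], float],
    space: Mapping[str, tuple],
    n_iter: int,
    seed: int = 0,
    n_initial: int | None = None,
    n_candidates: int = 256,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Minimize ``objective`` over ``space`` with ``n_iter`` evaluations.

    Returns the best configuration and the full evaluation history.
    """
    dims = parse_space(space)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    if n_initial is None:
        n_initial = max(3, min(n_iter, n_iter // 3 + 1))
    n_initial = min(n_initial, n_iter)

    U: list[np.ndarray] = []
    losses: list[float] = []
    history: list[tuple[dict, float]] = []

    def evaluate(u: np.ndarray) -> None:
        params = _decode(dims, u)
        loss = float(objective(params))
        U.append(u)
        losses.append(loss)
        history.append((params, loss))

    for _ in range(n_initial):
        evaluate(rng.random(len(dims)))

    kernel = Matern(length_scale=np.full(len(dims), 0.3), nu=2.5) * 1.0
    for _ in range(n_iter - n_initial):
        X_obs = np.vstack(U)
        y_obs = np.asarray(losses)
        finite = np.isfinite(y_obs)
        if finite.sum() < 2:
            evaluate(rng.random(len(dims)))
            continue
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-6,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X_obs[finite], y_obs[finite])
        cand = rng.random((n_candidates, len(dims)))
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, y_obs[finite].min())
        evaluate(cand[int(np.argmax(ei))])

    best = int(np.nanargmin(losses))
    return history[best][0], history
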