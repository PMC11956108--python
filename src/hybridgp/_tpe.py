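"""Minimal tree-structured Parzen estimator (TPE) for hyperparameter search.

Implements the standard TPE recipe: after a random start-up phase, past
trials are split into a "good" quantile and the rest by objective value;
candidate values are drawn from a Parzen (Gaussian kernel) density fitted to
the good observations and ranked by the density ratio good/bad. Parameters
are sampled independently. Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ParamSpec", "tpe_minimize"]


@dataclass(frozen=True)
class ParamSpec:
    """One search dimension: kind in {'uniform', 'loguniform', 'int'}."""

    kind: str
    low: float
    high: float

    def transform(self, x: float) -> float:
        return float(np.log(x)) if self.kind == "loguniform" else float(x)

    def inverse(self, z: float) -> float:
        if self.kind == "loguniform":
            return float(np.exp(z))
        if self.kind == "int":
            return int(round(np.clip(z, self.low, self.high)))
        return float(np.clip(z, self.low, self.high))

    @property
    def bounds(self) -> tuple[float, float]:
        if self.kind == "loguniform":
            return float(np.log(self.low)), float(np.log(self.high))
        return float(self.low), float(self.high)

    def sample_prior(self, rng: np.random.Generator) -> float:
        lo, hi = self.bounds
        return self.inverse(rng.uniform(lo, hi))


def _parzen_logpdf(z: np.ndarray, obs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Log density of a Parzen mixture over observations plus a uniform
    prior component spanning the search interval."""
    width = hi - lo
    bw = max(width / max(np.sqrt(len(obs)), 1.0), 1e-6 * width)
    comp = np.concatenate([obs, [(lo + hi) / 2.0]])
    bws = np.full(comp.size, bw)
    bws[-1] = width  # broad prior component
    z = np.atleast_1d(z)
    diff = (z[:, None] - comp[None, :]) / bws[None, :]
    log_k = -0.5 * diff**2 - np.log(bws[None, :] * np.sqrt(2.0 * np.pi))
    return np.logaddexp.reduce(log_k, axis=1) - np.log(comp.size)


def tpe_minimize(
    objective: Callable[[dict], float],
    space: dict[str, ParamSpec],
    n_trials: int,
    seed: int,
    n_startup: int = 10,
    n_candidates: int = 24,
    gamma: float = 0.25,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Minimize ``objective`` over ``space``; returns (best params, trace)."""
    if n_trials < 5:
        raise ValueError("n_trials must be at least 5")
    rng = np.random.default_rng(seed)
    trace: list[tuple[dict, float]] = []
    for t in range(n_trials):
        if t < n_startup or len(trace) < 2:
            params = {name: sp.sample_prior(rng) for name, sp in space.items()}
        else:
            losses = np.array([loss for _, loss in trace])
            order = np.argsort(losses, kind="stable")
            n_good = max(1, int(np.ceil(gamma * len(trace))))
            good = order[:n_good]
            bad = order[n_good:]
            params = {}
            for name, sp in space.items():
                lo, hi = sp.bounds
                zg = np.array([sp.transform(trace[i][0][name]) for i in good])
                zb = np.array([sp.transform(trace[i][0][name]) for i in bad])
                # draw candidates from the good-density mixture
                cand = np.empty(n_candidates)
                for c in range(n_candidates):
                    pick = rng.integers(0, zg.size + 1)
                    if pick == zg.size:
                        cand[c] = rng.uniform(lo, hi)
                    else:
                        bw = max((hi - lo) / max(np.sqrt(zg.size), 1.0), 1e-6 * (hi - lo))
                        cand[c] = np.clip(rng.normal(zg[pick], bw), lo, hi)
                score = _parzen_logpdf(cand, zg, lo, hi)
                if zb.size:
                    score = score - _parzen_logpdf(cand, zb, lo, hi)
                params[name] = sp.inverse(cand[int(np.argmax(score))])
        loss = float(objective(params))
        trace.append((params, loss))
    best_idx = int(np.argmin([loss for _, loss in trace]))
    return dict(trace[best_idx][0]), trace
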