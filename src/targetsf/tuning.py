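"""Sequential Bayesian hyperparameter search (Tree-structured Parzen
Estimator).

A compact TPE in the style of Bergstra et al.'s algorithm: after a
random start-up phase, observed trials are split into a "good" fraction
(the lowest-loss ``gamma`` quantile) and the rest; candidate points are
drawn from a Parzen (kernel-density) model of the good trials and the
one maximizing the density ratio l(x)/g(x) is evaluated next. Numeric
dimensions use Gaussian kernels (log-space for log-uniform dimensions);
categorical dimensions use Laplace-smoothed frequency ratios. The whole
trajectory is a deterministic function of the seed.

Search-space dimensions are declared with :func:`uniform`,
:func:`loguniform`, :func:`quniform` and :func:`choice`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "uniform",
    "loguniform",
    "quniform",
    "choice",
    "Trial",
    "TuningResult",
    "tpe_minimize",
]


def uniform(low: float, high: float) -> tuple:
    """Continuous dimension sampled uniformly on [low, high]."""
    return ("uniform", float(low), float(high))


def loguniform(low: float, high: float) -> tuple:
    """Continuous dimension uniform in log space on [low, high]."""
    if low <= 0 or high <= 0:
        raise ValueError("loguniform bounds must be positive")
    return ("loguniform", float(low), float(high))


def quniform(low: int, high: int, q: int = 1) -> tuple:
    """Integer dimension on [low, high], quantized to multiples of q."""
    return ("quniform", int(low), int(high), int(q))


def choice(options) -> tuple:
    """Categorical dimension."""
    options = list(options)
    if not options:
        raise ValueError("empty choice")
    return ("choice", options)


@dataclass
class Trial:
    params: dict
    loss: float


@dataclass
class TuningResult:
    best_params: dict
    best_loss: float
    trials: list[Trial] = field(default_factory=list)

    @property
    def trace(self) -> list[float]:
        return [t.loss for t in self.trials]


def _is_degenerate(space: dict) -> bool:
    for spec in space.values():
        kind = spec[0]
        if kind == "choice" and len(spec[1]) > 1:
            return False
        if kind in ("uniform", "loguniform") and spec[1] != spec[2]:
            return False
        if kind == "quniform" and spec[1] != spec[2]:
            return False
    return True


def _sample_prior(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "uniform":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "loguniform":
            out[name] = float(np.exp(rng.uniform(math.log(spec[1]),
                                                 math.log(spec[2]))))
        elif kind == "quniform":
            lo, hi, q = spec[1], spec[2], spec[3]
            v = rng.uniform(lo, hi + q)
            out[name] = int(min(hi, max(lo, int(v // q) * q)))
        elif kind == "choice":
            out[name] = spec[1][int(rng.integers(len(spec[1])))]
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return out


def _numeric_view(spec, value) -> float:
    return math.log(value) if spec[0] == "loguniform" else float(value)


def _parzen_logpdf(x: float, obs: np.ndarray, lo: float, hi: float) -> float:
    """Log density of a Gaussian mixture over observations + uniform prior."""
    span = hi - lo if hi > lo else 1.0
    bw = max(span / 20.0, float(np.std(obs)) / max(len(obs), 1) ** 0.5, 1e-6)
    comps = -0.5 * ((x - obs) / bw) ** 2 - math.log(bw * math.sqrt(2 * math.pi))
    comps = np.append(comps, -math.log(span))  # uniform prior component
    m = float(np.max(comps))
    return m + math.log(float(np.exp(comps - m).sum())) - math.log(len(comps))


def tpe_minimize(objective, space: dict, max_evals: int = 50,
                 seed: int = 0, n_startup: int = 10, gamma: float = 0.25,
                 n_candidates: int = 24) -> TuningResult:
    """Minimize ``objective(params)`` over ``space`` with TPE.

    Returns the best configuration, its loss, and the full trial trace.
    A degenerate (single-point) space is evaluated exactly once.
    """
    if max_evals < 1:
        raise ValueError("max_evals must be >= 1")
    rng = np.random.default_rng(seed)
    if _is_degenerate(space):
        max_evals = 1
    trials: list[Trial] = []
    for it in range(max_evals):
        if it < n_startup or len(trials) < 2:
            params = _sample_prior(space, rng)
        else:
            params = _suggest(space, trials, rng, gamma, n_candidates)
        trials.append(Trial(params=params, loss=float(objective(params))))
    best = min(trials, key=lambda t: t.loss)
    return TuningResult(best_params=dict(best.params), best_loss=best.loss,
                        trials=trials)


def _suggest(space, trials, rng, gamma, n_candidates) -> dict:
    order = sorted(range(len(trials)), key=lambda i: trials[i].loss)
    n_good = max(1, int(math.ceil(gamma * len(trials))))
    good = [trials[i] for i in order[:n_good]]
    bad = [trials[i] for i in order[n_good:]] or good

    candidates = []
    for _ in range(n_candidates):
        cand = {}
        for name, spec in space.items():
            kind = spec[0]
            if kind == "choice":
                options = spec[1]
                counts = np.ones(len(options))
                for t in good:
                    counts[options.index(t.params[name])] += 1
                cand[name] = options[int(rng.choice(len(options),
                                                    p=counts / counts.sum()))]
            else:
                lo, hi = _numeric_view(spec, spec[1]), _numeric_view(spec, spec[2])
                obs = np.array([_numeric_view(spec, t.params[name])
                                for t in good])
                center = float(obs[int(rng.integers(len(obs)))])
                span = hi - lo if hi > lo else 1.0
                bw = max(span / 20.0, float(np.std(obs)), 1e-6)
                x = float(np.clip(rng.normal(center, bw), lo, hi))
                if spec[0] == "loguniform":
                    cand[name] = float(math.exp(x))
                elif spec[0] == "quniform":
                    q = spec[3]
                    cand[name] = int(min(spec[2], max(spec[1],
                                                      int(round(x / q)) * q)))
                else:
                    cand[name] = x
        candidates.append(cand)

    def ratio(cand) -> float:
        score = 0.0
        for name, spec in space.items():
            kind = spec[0]
            if kind == "choice":
                options = spec[1]
                cg = np.ones(len(options))
                cb = np.ones(len(options))
                for t in good:
                    cg[options.index(t.params[name])] += 1
                for t in bad:
                    cb[options.index(t.params[name])] += 1
                k = options.index(cand[name])
                score += math.log(cg[k] / cg.sum()) - math.log(cb[k] / cb.sum())
            else:
                lo, hi = _numeric_view(spec, spec[1]), _numeric_view(spec, spec[2])
                x = _numeric_view(spec, cand[name])
                og = np.array([_numeric_view(spec, t.params[name]) for t in good])
                ob = np.array([_numeric_view(spec, t.params[name]) for t in bad])
                score += (_parzen_logpdf(x, og, lo, hi)
                          - _parzen_logpdf(x, ob, lo, hi))
        return score

    return max(candidates, key=ratio)
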