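"""First-order methods on the tropical projective torus.

Tropical descent (TD) is steepest descent with respect to the tropical norm:
the normalized descent direction raises exactly the coordinates with strictly
negative subgradient (min convention).  The module implements the classical
and tropical deterministic, stochastic and momentum variants

    CD, TD, SGD, TSGD, Adam, Adamax, TrAdamax

under the shared step rule ``a_m = gamma * ||g_m|| / sqrt(m)`` (Euclidean
norm for classical methods, tropical norm for tropical ones; Adam-family
methods use a constant rate), together with the O(1/sqrt(m)) convergence
bound calculator and its D-budget estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import canonicalize, d_asym, trop_norm
from .objectives import LocationObjective

__all__ = [
    "trop_direction",
    "run_optimizer",
    "OptimizerRun",
    "BoundInputs",
    "convergence_bound",
    "estimate_D",
    "METHODS",
]

METHODS = ("CD", "TD", "SGD", "TSGD", "Adam", "Adamax", "TrAdamax")
_STOCHASTIC = {"SGD", "TSGD"}


def trop_direction(g, convention: Literal["min", "max"] = "min") -> np.ndarray:
    """Normalized tropical steepest descent direction for gradient ``g``.

    Min convention: the indicator of strictly negative components; max
    convention: minus the indicator of strictly positive components.  For
    nonzero ``g`` (which sums to zero on the torus) either choice has
    tropical norm 1 and minimizes ``g . v`` over the tropical unit sphere.
    """
    g = np.asarray(g, dtype=float)
    if convention == "min":
        return (g < 0).astype(float)
    if convention == "max":
        return -(g > 0).astype(float)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class OptimizerRun:
    """Trace of one optimizer run.

    ``iterates`` holds the canonical (sum-zero) iterates t_0..t_M row-wise;
    ``objective`` the full-data objective at each iterate.  Runs terminated
    at a zero subgradient carry a shorter trace.
    """

    method: str
    gamma: float
    iterates: np.ndarray  # (M+1, N)
    objective: np.ndarray  # (M+1,)
    seed: int | None = None
    converged: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def final(self) -> np.ndarray:
        return self.iterates[-1]

    @property
    def final_value(self) -> float:
        return float(self.objective[-1])


def run_optimizer(
    obj: LocationObjective,
    t0,
    method: str,
    gamma: float,
    steps: int,
    rng=None,
    betas: tuple[float, float] = (0.9, 0.999),
    eps: float = 1e-8,
    normalize: bool = True,
    convention: str = "min",
) -> OptimizerRun:
    """Run ``steps`` iterations of the chosen method from ``t0``.

    ``rng`` seeds the sample draws of SGD/TSGD (ignored by deterministic
    methods).  ``normalize`` re-canonicalizes every iterate by subtracting
    the coordinate mean — the objective is invariant, and this prevents the
    unbounded coordinate growth inherent to tropical descent.  The run stops
    early if the (sampled) subgradient vanishes.

    ``convention`` selects the tropical descent direction for TD, TSGD and
    TrAdamax: ``"min"`` raises the coordinates with negative subgradient,
    ``"max"`` lowers the coordinates with positive subgradient.  Both are
    steepest directions in the tropical norm; for objectives that are both
    min- and max-tropical location problems (the centrality statistics)
    either applies, and their stable points differ on structured data —
    ultrametric-supported (cophenetic) datasets favor the max convention.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if steps < 1 or gamma <= 0:
        raise ValueError("need steps >= 1 and gamma > 0")
    rng = np.random.default_rng(rng)
    beta1, beta2 = betas
    t = canonicalize(t0)
    n = t.shape[0]
    iterates = [t.copy()]
    values = [obj.value(t)]
    mom = np.zeros(n)  # first moment (Adam family)
    sec = np.zeros(n)  # second / infinity moment
    converged = False
    for m in range(1, steps + 1):
        if method in _STOCHASTIC:
            k = int(rng.integers(obj.n_samples))
            g = obj.sample_subgrad(t, k)
        else:
            g = obj.subgrad(t)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite subgradient at step {m} of {method}"
            )
        if not np.any(g):
            converged = True
            break
        if method in ("CD", "SGD"):
            # a_m = gamma * ||g||_2 / sqrt(m) along -g/||g||_2
            t = t - (gamma / np.sqrt(m)) * g
        elif method in ("TD", "TSGD"):
            d = trop_direction(g, convention)
            t = t + (gamma * trop_norm(g) / np.sqrt(m)) * d
        elif method == "Adam":
            mom = beta1 * mom + (1 - beta1) * g
            sec = beta2 * sec + (1 - beta2) * g**2
            m_hat = mom / (1 - beta1**m)
            v_hat = sec / (1 - beta2**m)
            t = t - gamma * m_hat / (np.sqrt(v_hat) + eps)
        elif method == "Adamax":
            mom = beta1 * mom + (1 - beta1) * g
            sec = np.maximum(beta2 * sec, np.abs(g))
            t = t - (gamma / (1 - beta1**m)) * mom / (sec + eps)
        elif method == "TrAdamax":
            # moments of the unnormalized tropical descent direction
            if convention == "min":
                d_raw = np.where(g < 0, -g, 0.0)
            else:
                d_raw = np.where(g > 0, g, 0.0)
            mom = beta1 * mom + (1 - beta1) * d_raw
            sec = np.maximum(beta2 * sec, d_raw)
            safe = np.where(sec > 0, sec, 1.0)
            step = np.where(sec > 0, mom / (1 - beta1**m) / safe, 0.0)
            t = t + gamma * step if convention == "min" else t - gamma * step
        if normalize:
            t = t - t.mean()
        v = obj.value(t)
        if not np.isfinite(v):
            raise FloatingPointError(
                f"non-finite objective at step {m} of {method}"
            )
        iterates.append(t.copy())
        values.append(v)
    return OptimizerRun(
        method=method,
        gamma=gamma,
        iterates=np.array(iterates),
        objective=np.array(values),
        converged=converged,
    )


@dataclass
class BoundInputs:
    """Inputs of the O(1/sqrt(m)) convergence bound.

    alpha — step-size scale (a_m = alpha ||g|| / sqrt(m));
    N, K  — dimension and sample size;
    L     — gradient-norm pinch, 1/L <= ||grad f||_tr <= 2;
    D     — budget on the mean directed d_max distance from the data to the
            iterates (sum_k d_max(x_k, t_m) <= K D).
    """

    alpha: float
    N: int
    K: int
    L: float
    D: float


def convergence_bound(
    inputs: BoundInputs, m: int, one_sample: bool = False
) -> tuple[float, bool]:
    """Distance-to-hull bound eps_m after m steps of tropical descent.

        eps_m = 2 sqrt(2) alpha N
                / (sqrt(m+1) - K D L / (2 alpha) + sqrt(L K N - 1) - sqrt(2))

    valid only once m clears both floors
    ``(sqrt(2) + KDL/2alpha - sqrt(LKN-1))^2 - 1`` and ``(2 alpha N / D)^2``.
    With ``one_sample`` (K forced to 1) the same expression bounds the
    distance to the global minimum of a star-quasi-convex problem (eps'_m).
    Returns ``(eps, valid)``; a nonpositive denominator reports +inf.
    """
    a, n, k, L, D = (
        inputs.alpha,
        inputs.N,
        1 if one_sample else inputs.K,
        inputs.L,
        inputs.D,
    )
    if min(a, n, k, L, D) <= 0:
        raise ValueError("all bound inputs must be positive")
    root = np.sqrt(L * k * n - 1)
    m_floor = max(
        (np.sqrt(2) + k * D * L / (2 * a) - root) ** 2 - 1,
        (2 * a * n / D) ** 2,
    )
    valid = m >= m_floor
    denom = np.sqrt(m + 1) - k * D * L / (2 * a) + root - np.sqrt(2)
    if denom <= 0:
        return float("inf"), False
    return float(2 * np.sqrt(2) * a * n / denom), bool(valid)


def estimate_D(run: OptimizerRun, t_star=None) -> float:
    """Tight empirical estimate of the D budget from a finished run:
    ``max_m d_max(t*, t_m)``, with t* defaulting to the mean of the final
    10 canonical iterates."""
    if len(run.iterates) == 0:
        raise ValueError("empty run")
    if t_star is None:
        tail = run.iterates[-min(10, len(run.iterates)):]
        t_star = tail.mean(axis=0)
    t_star = np.asarray(t_star, dtype=float)
    return max(d_asym(t_star, tm, "max") for tm in run.iterates)
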