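"""Tropical location-problem objectives and their subgradient oracles.

A min-tropical location problem minimizes ``f = g(h_1, ..., h_K)`` over the
tropical projective torus, where each ``h_k`` measures closeness to one data
point and ``g`` is coordinatewise increasing.  All objectives here expose

* ``value(t)``       — the objective at ``t``;
* ``subgrad(t)``     — an element of the Clarke subdifferential, built from
  lowest-index argmax/argmin selectors so that it provably satisfies the
  gradient contract: a strictly negative component at coordinate ``j`` occurs
  only when ``j`` attains ``min_i (t_i - x_ki)`` for some sample ``k``;
* ``sample_value`` / ``sample_subgrad`` — the single-sample loss used by
  stochastic methods.

The Fermat–Weber objective also admits an exact optimum via a linear
program, used as the error reference in benchmarks.
"""

from __future__ import annotations

import abc
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .core import as_point_set, canonicalize, d_tr

__all__ = [
    "LocationObjective",
    "FermatWeber",
    "FrechetMean",
    "TropicalLinearRegression",
    "WassersteinProjection",
    "parse_partition",
    "check_assumption1",
    "fermat_weber_optimum",
    "reference_optimum",
]


class LocationObjective(abc.ABC):
    """Base class: a dataset plus value and subgradient oracles.

    ``kernels`` is the (K, N) matrix of kernel points against which the
    argmin membership of the gradient contract is tested (the data itself,
    or the reduced points z_k for Wasserstein projections).
    """

    name: str
    data: np.ndarray  # (K, N) canonical rows

    def __init__(self, data):
        self.data = as_point_set(data)
        if self.data.shape[0] < 1:
            raise ValueError("objective needs at least one data point")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    @property
    def kernels(self) -> np.ndarray:
        return self.data

    @abc.abstractmethod
    def value(self, t) -> float: ...

    @abc.abstractmethod
    def subgrad(self, t) -> np.ndarray: ...

    def sample_value(self, t, k: int) -> float:
        raise NotImplementedError

    def sample_subgrad(self, t, k: int) -> np.ndarray:
        raise NotImplementedError


def _selector(diff: np.ndarray) -> np.ndarray:
    """Subgradient of d_tr(x, t) in t, for diff = t - x.

    Returns e_argmax - e_argmin with lowest-index tie-breaking; the -1 sits
    at an argmin of t - x, as the gradient contract requires.
    """
    g = np.zeros_like(diff)
    g[int(np.argmax(diff))] += 1.0
    g[int(np.argmin(diff))] -= 1.0
    return g


class FermatWeber(LocationObjective):
    """Mean tropical distance to the data; its minimizers generalize the
    median.  Classically convex as well as min- and max-tropically convex."""

    name = "fermat_weber"

    def value(self, t) -> float:
        t = np.asarray(t, dtype=float)
        diff = t[None, :] - self.data
        return float((diff.max(axis=1) - diff.min(axis=1)).mean())

    def subgrad(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        diff = t[None, :] - self.data
        g = np.zeros_like(t)
        np.add.at(g, np.argmax(diff, axis=1), 1.0)
        np.add.at(g, np.argmin(diff, axis=1), -1.0)
        return g / self.n_samples

    def sample_value(self, t, k: int) -> float:
        return d_tr(t, self.data[k])

    def sample_subgrad(self, t, k: int) -> np.ndarray:
        return _selector(np.asarray(t, dtype=float) - self.data[k])


class FrechetMean(LocationObjective):
    """Root mean squared tropical distance; minimizers are Fréchet means."""

    name = "frechet"

    def value(self, t) -> float:
        t = np.asarray(t, dtype=float)
        diff = t[None, :] - self.data
        d = diff.max(axis=1) - diff.min(axis=1)
        return float(np.sqrt((d**2).mean()))

    def subgrad(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        f = self.value(t)
        if f <= 0.0:
            # global minimum: 0 is a valid Clarke element
            return np.zeros_like(t)
        diff = t[None, :] - self.data
        d = diff.max(axis=1) - diff.min(axis=1)
        g = np.zeros_like(t)
        np.add.at(g, np.argmax(diff, axis=1), d)
        np.add.at(g, np.argmin(diff, axis=1), -d)
        return g / (self.n_samples * f)

    def sample_value(self, t, k: int) -> float:
        return d_tr(t, self.data[k]) ** 2

    def sample_subgrad(self, t, k: int) -> np.ndarray:
        diff = np.asarray(t, dtype=float) - self.data[k]
        d = float(diff.max() - diff.min())
        return 2.0 * d * _selector(diff)


def _two_smallest(v: np.ndarray) -> tuple[int, int]:
    """Indices of the smallest and second-smallest entries (lowest-index
    ties, multiset semantics)."""
    order = np.argsort(v, kind="stable")
    return int(order[0]), int(order[1])


class TropicalLinearRegression(LocationObjective):
    """Best-fit tropical hyperplane: minimize the maximal tropical distance
    from the data to the hyperplane with apex t.

    ``f(t) = max_k [2ndmin_i (t - x_k)_i - min_i (t - x_k)_i]`` — a
    min-tropical location problem with tropically convex sub-level sets,
    but not classically convex.
    """

    name = "linreg"

    def _margins(self, t: np.ndarray) -> np.ndarray:
        diff = t[None, :] - self.data
        s = np.sort(diff, axis=1)
        return s[:, 1] - s[:, 0]

    def value(self, t) -> float:
        return float(self._margins(np.asarray(t, dtype=float)).max())

    def subgrad(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k_star = int(np.argmax(self._margins(t)))
        return self.sample_subgrad(t, k_star)

    def sample_value(self, t, k: int) -> float:
        diff = np.asarray(t, dtype=float) - self.data[k]
        s = np.sort(diff)
        return float(s[1] - s[0])

    def sample_subgrad(self, t, k: int) -> np.ndarray:
        diff = np.asarray(t, dtype=float) - self.data[k]
        i1, i2 = _two_smallest(diff)
        g = np.zeros_like(diff)
        g[i2] += 1.0
        g[i1] -= 1.0
        return g


def parse_partition(spec: str, n: int) -> list[np.ndarray]:
    """Parse a partition string like ``"1,2|3,4|5,6"`` (1-based, pipes
    between blocks) into a list of index arrays covering range(n)."""
    blocks = []
    for part in spec.split("|"):
        idx = np.array([int(s) - 1 for s in part.split(",") if s.strip()])
        if idx.size == 0:
            raise ValueError("empty partition block")
        blocks.append(idx)
    _validate_partition(blocks, n)
    return blocks


def _validate_partition(blocks: Sequence[np.ndarray], n: int) -> None:
    flat = np.concatenate([np.asarray(b, dtype=int) for b in blocks])
    if len(flat) != n or set(flat.tolist()) != set(range(n)):
        raise ValueError("blocks must partition {1..N} (disjoint, covering)")


class WassersteinProjection(LocationObjective):
    """Tropical p-Wasserstein projection between paired samples X in R^N/R1
    and Y in R^M/R1, along a coordinate partition J_1..J_M.

    The per-sample loss reduces to ``h_k(t) = max_j (min_{i in J_j}
    (t - z_k)_i - min_a (t - z_k)_a)`` with z_ki = x_ki - y_kj for the block
    j containing i; the objective is the p-mean of the h_k (max for p=inf).
    """

    name = "wasserstein"

    def __init__(self, X, Y, partition, p: float = np.inf):
        X = as_point_set(X)
        Y = as_point_set(Y)
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y must have the same number of samples")
        if p < 1:
            raise ValueError("p must be >= 1 or inf")
        if isinstance(partition, str):
            partition = parse_partition(partition, X.shape[1])
        else:
            partition = [np.asarray(b, dtype=int) for b in partition]
            _validate_partition(partition, X.shape[1])
        if len(partition) != Y.shape[1]:
            raise ValueError("partition must have one block per Y coordinate")
        self.partition = partition
        self.p = float(p)
        self.name = "wasserstein_inf" if np.isinf(p) else f"wasserstein_{p:g}"
        z = np.empty_like(X)
        for j, block in enumerate(partition):
            z[:, block] = X[:, block] - Y[:, [j]]
        super().__init__(z)  # canonical z_k are the kernels

    def _h(self, t: np.ndarray) -> np.ndarray:
        diff = t[None, :] - self.data  # (K, N)
        inner = np.stack(
            [diff[:, block].min(axis=1) for block in self.partition], axis=1
        )  # (K, M)
        return inner.max(axis=1) - diff.min(axis=1)

    def value(self, t) -> float:
        h = self._h(np.asarray(t, dtype=float))
        if np.isinf(self.p):
            return float(h.max())
        return float((np.mean(h**self.p)) ** (1.0 / self.p))

    def _h_subgrad(self, t: np.ndarray, k: int) -> np.ndarray:
        diff = t - self.data[k]
        inner = np.array([diff[b].min() for b in self.partition])
        j_star = int(np.argmax(inner))
        block = self.partition[j_star]
        i_star = int(block[np.argmin(diff[block])])
        a_star = int(np.argmin(diff))
        g = np.zeros_like(t)
        g[i_star] += 1.0
        g[a_star] -= 1.0
        return g

    def subgrad(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        h = self._h(t)
        if np.isinf(self.p):
            k_star = int(np.argmax(h))
            return self._h_subgrad(t, k_star)
        f = self.value(t)
        if f <= 0.0:
            return np.zeros_like(t)
        g = np.zeros_like(t)
        # chain rule for the p-mean: (1/K) h_k^{p-1} / f^{p-1}
        w = h ** (self.p - 1.0) / (self.n_samples * f ** (self.p - 1.0))
        for k in range(self.n_samples):
            if w[k] != 0.0:
                g += w[k] * self._h_subgrad(t, k)
        return g

    def sample_value(self, t, k: int) -> float:
        return float(self._h(np.asarray(t, dtype=float))[k])

    def sample_subgrad(self, t, k: int) -> np.ndarray:
        return self._h_subgrad(np.asarray(t, dtype=float), k)


def check_assumption1(obj: LocationObjective, t, tol: float = 1e-9) -> bool:
    """Gradient contract: every strictly negative subgradient coordinate j
    must attain ``min_i (t_i - x_ki)`` for some kernel point x_k."""
    t = np.asarray(t, dtype=float)
    g = obj.subgrad(t)
    diff = t[None, :] - obj.kernels  # (K, N)
    mins = diff.min(axis=1)
    for j in np.flatnonzero(g < -1e-12):
        if not np.any(diff[:, j] <= mins + tol):
            return False
    return True


def fermat_weber_optimum(X) -> tuple[np.ndarray, float]:
    """Exact tropical Fermat–Weber optimum via a linear program.

    minimize (1/K) sum_k (u_k - l_k)  s.t.  l_k <= t_i - x_ki <= u_k.
    The gauge sum(t) = 0 pins the representative; the optimal value is the
    global minimum of the Fermat–Weber objective.
    """
    X = as_point_set(X)
    K, N = X.shape
    # variables: [t (N), u (K), l (K)]
    n_var = N + 2 * K
    c = np.zeros(n_var)
    c[N : N + K] = 1.0 / K
    c[N + K :] = -1.0 / K
    rows_a, rows_b = [], []
    for k in range(K):
        for i in range(N):
            r = np.zeros(n_var)  # t_i - u_k <= x_ki
            r[i] = 1.0
            r[N + k] = -1.0
            rows_a.append(r)
            rows_b.append(X[k, i])
            r = np.zeros(n_var)  # -t_i + l_k <= -x_ki
            r[i] = -1.0
            r[N + K + k] = 1.0
            rows_a.append(r)
            rows_b.append(-X[k, i])
    a_eq = np.zeros((1, n_var))
    a_eq[0, :N] = 1.0
    res = linprog(
        c,
        A_ub=np.array(rows_a),
        b_ub=np.array(rows_b),
        A_eq=a_eq,
        b_eq=[0.0],
        bounds=[(None, None)] * n_var,
        method="highs",
    )
    if not res.success:  # cannot occur for finite data
        raise RuntimeError(f"Fermat-Weber LP failed: {res.message}")
    return canonicalize(res.x[:N]), float(res.fun)


def reference_optimum(
    obj: LocationObjective,
    candidate_values: Sequence[float] = (),
    t_start=None,
    steps: int = 10000,
    gamma: float = 1.0,
    rng=None,
) -> float:
    """Best-known optimal value, used as the error reference.

    Fermat–Weber problems use the exact LP.  Other objectives take the best
    value over any supplied candidate runs and one long tropical-descent run
    (``steps`` defaults to 10x the benchmark budget) with the decaying step
    rule, started from ``t_start`` (or a Gaussian point).
    """
    if isinstance(obj, FermatWeber):
        return fermat_weber_optimum(obj.data)[1]
    from .optim import run_optimizer  # deferred: avoids an import cycle

    rng = np.random.default_rng(rng)
    if t_start is None:
        t_start = rng.standard_normal(obj.dim)
    run = run_optimizer(obj, t_start, "TD", gamma=gamma, steps=steps, rng=rng)
    best = float(np.min(run.objective))
    for v in candidate_values:
        best = min(best, float(v))
    return best
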