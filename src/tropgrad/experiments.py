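"""Benchmark and application pipelines for tropical gradient methods.

The benchmark protocol mirrors the numerical study the package exists for:
for a given objective, each method is run for 1000 steps from a shared set
of random Gaussian initializations with a learning rate tuned by grid
search, and the distribution of final log errors against a reference
optimum is reported (mean, 10th/90th percentiles, full CDF).

Two applications are included: species-tree estimation from multi-species
coalescent gene trees via tropical centrality statistics followed by
single-linkage projection back to ultrametric tree space, and recovery of
hidden preference factors in a sealed-bid auction model via tropical linear
regression.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import as_point_set
from .objectives import (
    FermatWeber,
    FrechetMean,
    LocationObjective,
    TropicalLinearRegression,
    reference_optimum,
)
from .optim import BoundInputs, OptimizerRun, convergence_bound, estimate_D, run_optimizer
from .treespace import (
    msc_gene_trees,
    normalize_avg_norm,
    single_linkage_ultrametric,
    topology_string,
    tree_data_matrix,
)

__all__ = [
    "log_error",
    "default_gamma_grid",
    "tune_gamma",
    "shared_initializations",
    "ErrorReport",
    "run_benchmark",
    "species_tree_experiment",
    "auction_prices",
    "auction_estimate",
    "rate_diagnostic",
]

_CLIP = 1e-16


def _rng(seed, *tags) -> np.random.Generator:
    """Deterministic child generator from an integer seed and string tags."""
    entropy = []
    for item in (seed, *tags):
        if isinstance(item, str):
            entropy.append(zlib.crc32(item.encode()))
        else:
            entropy.append(int(item) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def log_error(
    f_final: float, f_star: float, mode: str = "relative", offset: float = 0.0
) -> float:
    """Natural-log error of a final objective value against a reference.

    ``relative`` — ln((f_final - f_star) / f_star + offset), requiring
    f_star > 0; ``absolute`` — ln(f_final + offset), the variant used when
    the true optimum is 0 (e.g. linear regression on ultrametric data).
    Differences below the clip 1e-16 (including negative ones, from a
    reference that is itself approximate) are clipped before the log.

    Piecewise-linear objectives are frequently minimized *exactly* by
    tropical descent (the minimum is attained on a full-dimensional cell),
    so with ``offset=0`` the mean log error is dominated by the clip; the
    centrality-statistic benchmark therefore uses ``offset=0.01``, a 1%%
    floor on the relative error.
    """
    if mode == "relative":
        if f_star <= 0:
            raise ValueError("relative log error requires f_star > 0")
        return float(np.log(max(f_final - f_star, _CLIP) / f_star + offset))
    if mode == "absolute":
        return float(np.log(max(f_final, _CLIP) + offset))
    raise ValueError(f"unknown mode {mode!r}")


def default_gamma_grid() -> np.ndarray:
    """Half-decade learning-rate grid 10^-3 .. 10^1."""
    return 10.0 ** np.arange(-3.0, 1.01, 0.5)


def shared_initializations(n_init: int, n_dim: int, seed) -> np.ndarray:
    """The standard-Gaussian initializations shared by every method."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_init, n_dim))


def _final_log_errors(
    obj: LocationObjective,
    method: str,
    gamma: float,
    inits: np.ndarray,
    steps: int,
    f_star: float,
    mode: str,
    seed,
    tag: str,
    offset: float = 0.0,
    convention: str = "min",
) -> np.ndarray:
    errors = np.empty(len(inits))
    for i, t0 in enumerate(inits):
        run = run_optimizer(
            obj, t0, method, gamma=gamma, steps=steps,
            rng=_rng(seed, tag, i), convention=convention,
        )
        errors[i] = log_error(run.final_value, f_star, mode, offset)
    return errors


def tune_gamma(
    obj: LocationObjective,
    method: str,
    f_star: float,
    grid=None,
    n_init: int = 10,
    steps: int = 1000,
    mode: str = "relative",
    offset: float = 0.0,
    seed=0,
    convention: str = "min",
) -> float:
    """Grid-search the learning rate minimizing the mean final log error.

    Tuning initializations and SGD sample draws are seeded disjointly from
    evaluation runs (callers pass a different seed there).
    """
    grid = default_gamma_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty gamma grid")
    inits = shared_initializations(n_init, obj.dim, _rng(seed, "tune"))
    means = []
    for gamma in grid:
        try:
            errs = _final_log_errors(
                obj, method, float(gamma), inits, steps, f_star, mode,
                seed, "tune-run", offset, convention,
            )
            means.append(errs.mean())
        except FloatingPointError:
            means.append(np.inf)
    return float(grid[int(np.argmin(means))])


@dataclass
class ErrorReport:
    """Distribution of final log errors for one method."""

    method: str
    gamma: float
    errors: np.ndarray
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(self.errors.mean())

    @property
    def p10(self) -> float:
        return float(np.percentile(self.errors, 10))

    @property
    def p90(self) -> float:
        return float(np.percentile(self.errors, 90))

    def cdf(self) -> pd.DataFrame:
        x = np.sort(self.errors)
        return pd.DataFrame(
            {"log_error": x, "cdf": np.arange(1, len(x) + 1) / len(x)}
        )


def run_benchmark(
    obj: LocationObjective,
    methods=("CD", "TD"),
    f_star: float | None = None,
    gammas: dict | None = None,
    n_init: int = 50,
    steps: int = 1000,
    mode: str = "relative",
    offset: float = 0.0,
    seed=0,
    tune_n_init: int = 10,
) -> dict[str, ErrorReport]:
    """Run the multi-method benchmark from shared initializations.

    Learning rates are tuned per method unless supplied.  Runs that diverge
    to non-finite values are excluded and counted in ``n_failed``.
    """
    if f_star is None:
        f_star = reference_optimum(obj, rng=_rng(seed, "ref"))
    inits = shared_initializations(n_init, obj.dim, _rng(seed, "eval"))
    reports = {}
    for method in methods:
        gamma = (gammas or {}).get(method)
        if gamma is None:
            gamma = tune_gamma(
                obj, method, f_star, n_init=tune_n_init, steps=steps,
                mode=mode, offset=offset, seed=seed,
            )
        errors, n_failed = [], 0
        for i, t0 in enumerate(inits):
            try:
                run = run_optimizer(
                    obj, t0, method, gamma=gamma, steps=steps,
                    rng=_rng(seed, "eval-run", i),
                )
                errors.append(log_error(run.final_value, f_star, mode, offset))
            except FloatingPointError:
                n_failed += 1
        reports[method] = ErrorReport(
            method=method, gamma=gamma, errors=np.array(errors),
            n_failed=n_failed,
        )
    return reports


def species_tree_experiment(
    species_tree,
    n_genes: int = 100,
    n_init: int = 100,
    statistic: str = "fw",
    methods=("TD",),
    steps: int = 1000,
    gammas: dict | None = None,
    seed=0,
    tune_n_init: int = 10,
    convention: str = "max",
) -> pd.DataFrame:
    """Estimate a species tree from simulated gene trees.

    Simulates ``n_genes`` multi-species-coalescent gene trees, vectorizes
    them, normalizes the dataset to mean tropical norm 1, minimizes the
    chosen centrality statistic (``fw`` Fermat–Weber or ``frechet``) per
    method from ``n_init`` Gaussian initializations, projects each result
    to ultrametric space by single linkage, and tabulates the canonical
    topology strings (one count column per method).
    """
    genes = msc_gene_trees(
        species_tree, n_genes, rng=_rng(seed, "genes")
    )
    X = normalize_avg_norm(tree_data_matrix(genes))
    labels = sorted(tx.label for tx in species_tree.taxon_namespace)
    if statistic == "fw":
        obj: LocationObjective = FermatWeber(X)
    elif statistic == "frechet":
        obj = FrechetMean(X)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    f_star = reference_optimum(obj, rng=_rng(seed, "ref"))
    inits = shared_initializations(n_init, obj.dim, _rng(seed, "eval"))
    counts: dict[str, dict[str, int]] = {}
    for method in methods:
        gamma = (gammas or {}).get(method)
        if gamma is None:
            gamma = tune_gamma(
                obj, method, f_star, n_init=tune_n_init, steps=steps,
                seed=seed, convention=convention,
            )
        for i, t0 in enumerate(inits):
            run = run_optimizer(
                obj, t0, method, gamma=gamma, steps=steps,
                rng=_rng(seed, "eval-run", i), convention=convention,
            )
            _, tree = single_linkage_ultrametric(run.final, labels=labels)
            topo = topology_string(tree)
            counts.setdefault(topo, {})[method] = (
                counts.setdefault(topo, {}).get(method, 0) + 1
            )
    table = pd.DataFrame(counts).T.reindex(columns=list(methods)).fillna(0)
    table = table.astype(int)
    table.index.name = "topology"
    return table.sort_values(list(methods), ascending=False)


def auction_prices(
    n_products: int,
    factors=(1.0, 0.8, 0.6),
    rng=None,
    noise: float = 0.0,
) -> np.ndarray:
    """Generate equilibrium sealed-bid price matrices with hidden factors.

    Firm i's offer for product j is ``p_ij = c_j - log f_i (+ margin)``: for
    each product two random firms tie on the preference-adjusted log price
    (no firm can raise its price and still win) and the rest sit a positive
    margin above.  ``noise`` adds Gaussian jitter to every price, moving the
    data off exact equilibrium.  Returns the (n_firms, n_products) matrix p.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("preference factors must be positive")
    n_firms = factors.shape[0]
    rng = np.random.default_rng(rng)
    p = np.empty((n_firms, n_products))
    logf = np.log(factors)
    for j in range(n_products):
        base = rng.uniform(1.0, 3.0)
        tied = rng.choice(n_firms, size=2, replace=False)
        margin = rng.uniform(0.1, 1.0, size=n_firms)
        margin[tied] = 0.0
        p[:, j] = base - logf + margin
    if noise > 0:
        p += rng.normal(scale=noise, size=p.shape)
    return p


def auction_estimate(
    prices,
    method: str = "TD",
    gamma: float = 1.0,
    steps: int = 1000,
    t0=None,
    seed=0,
) -> np.ndarray:
    """Estimate hidden preference factors from an equilibrium price matrix.

    The K product columns of ``-p`` form the regression dataset in R^N
    (N firms); minimizing the tropical linear regression objective finds the
    apex t of the best-fit hyperplane, and the factor estimate is
    ``f_hat = exp(t - max t)`` so the largest component is 1.
    """
    prices = np.asarray(prices, dtype=float)
    if not np.all(np.isfinite(prices)):
        raise ValueError("prices must be finite")
    X = as_point_set(-prices.T)  # K products as points in R^(n_firms)
    obj = TropicalLinearRegression(X)
    rng = np.random.default_rng(seed)
    if t0 is None:
        t0 = rng.standard_normal(obj.dim)
    run = run_optimizer(obj, t0, method, gamma=gamma, steps=steps, rng=rng)
    t = run.final
    return np.exp(t - t.max())


def rate_diagnostic(
    run: OptimizerRun,
    t_star=None,
    alpha: float = 1.0,
    L: float = 1.0,
) -> pd.DataFrame:
    """Per-step distance to the estimated minimum and the one-sample
    convergence bound eps'_m with its validity flag.

    ``t_star`` defaults to the mean of the final 10 iterates; D is the
    tight empirical budget from the run.  Linear regression has
    ``||grad f||_tr = 2`` almost everywhere, hence the default L = 1.
    """
    from .core import d_tr

    if t_star is None:
        t_star = run.iterates[-min(10, len(run.iterates)):].mean(axis=0)
    t_star = np.asarray(t_star, dtype=float)
    n_dim = run.iterates.shape[1]
    D = estimate_D(run, t_star)
    inputs = BoundInputs(alpha=alpha, N=n_dim, K=1, L=L, D=max(D, 1e-12))
    rows = []
    for m, tm in enumerate(run.iterates):
        eps, valid = convergence_bound(inputs, m, one_sample=True)
        rows.append((m, d_tr(tm, t_star), eps, valid))
    return pd.DataFrame(
        rows, columns=["m", "distance", "eps_prime", "valid"]
    )
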