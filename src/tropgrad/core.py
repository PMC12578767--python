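"""Tropical algebra and geometry on the tropical projective torus R^N / R1.

The tropical projective torus identifies vectors that differ by a multiple of
the all-ones vector.  Every function here works on plain numpy arrays; a
*tropical point* is any real vector of length N >= 2, and its canonical
representative is the translate with coordinate sum zero.  A *point set* is a
(K, N) array whose rows are tropical points.

The tropical (max-plus) semiring has addition ``max`` and multiplication
``+``; tropical scalar multiplication of a point is ordinary translation.
The tropical norm ``max_i x_i - min_i x_i`` induces the generalized Hilbert
projective metric d_tr, the natural metric for vectorized phylogenetic trees.
"""

from __future__ import annotations

from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "canonicalize",
    "as_point_set",
    "trop_norm",
    "d_tr",
    "d_asym",
    "second_extreme",
    "hyperplane_distance",
    "trop_combination",
    "hull_project",
    "hull_diagnostics",
    "segment_point",
    "HullProjection",
    "read_point_set",
    "write_point_set",
]

Convention = Literal["max", "min"]


def canonicalize(v) -> np.ndarray:
    """Return the sum-zero representative of ``v`` in R^N / R1.

    The tropical projective torus is homeomorphic to the hyperplane
    ``sum_i x_i = 0``; subtracting the coordinate mean picks the unique
    representative on it.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.shape[0] < 2:
        raise ValueError("a tropical point needs at least 2 coordinates")
    if not np.all(np.isfinite(v)):
        raise ValueError("tropical point coordinates must be finite")
    return v - v.mean()


def as_point_set(X) -> np.ndarray:
    """Canonicalize a (K, N) array of points row-wise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("points need at least 2 coordinates")
    if not np.all(np.isfinite(X)):
        raise ValueError("point coordinates must be finite")
    return X - X.mean(axis=1, keepdims=True)


def _check_same_dim(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(
            f"dimension mismatch: {x.shape[-1]} vs {y.shape[-1]}"
        )


def trop_norm(x) -> float:
    """Tropical norm ``max_i x_i - min_i x_i`` (invariant under +c·1)."""
    x = np.asarray(x, dtype=float)
    return float(x.max(axis=-1) - x.min(axis=-1))


def d_tr(x, y) -> float:
    """Generalized Hilbert projective metric d_tr(x, y) = ||x - y||_tr."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_same_dim(x, y)
    diff = x - y
    return float(diff.max(axis=-1) - diff.min(axis=-1))


def d_asym(a, b, which: Convention = "min") -> float:
    """Tropical asymmetric distances d_min(a, b) and d_max(a, b).

    These act like a directed l1 norm on the torus and satisfy the identity
    ``N * d_tr(a, b) = d_min(a, b) + d_max(a, b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_same_dim(a, b)
    diff = b - a
    n = diff.shape[-1]
    if which == "min":
        return float(diff.sum() - n * diff.min())
    if which == "max":
        return float(n * diff.max() - diff.sum())
    raise ValueError(f"unknown convention {which!r}")


def second_extreme(v, which: Literal["max", "min"] = "max") -> float:
    """Second-largest (or second-smallest) entry, ties with multiplicity.

    Sorted-order semantics: the second entry of ``v`` sorted descending
    (``which='max'``) or ascending (``which='min'``), so a duplicated
    extreme is its own second extreme, e.g. 2ndmax(2, 2, 0) = 2.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[-1] < 2:
        raise ValueError("second_extreme needs at least 2 entries")
    s = np.sort(v)
    if which == "max":
        return float(s[-2])
    if which == "min":
        return float(s[1])
    raise ValueError(f"unknown convention {which!r}")


def hyperplane_distance(x, t) -> float:
    """Tropical distance from ``x`` to the max-tropical hyperplane with apex t.

    The hyperplane is the locus where ``max_i (x_i - t_i)`` is attained at
    least twice; the distance is the gap between the largest and second
    largest entry of ``x - t`` and vanishes exactly on the hyperplane.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    _check_same_dim(x, t)
    diff = x - t
    return float(diff.max() - second_extreme(diff, "max"))


def trop_combination(X, alphas, convention: Convention = "max") -> np.ndarray:
    """Tropical linear combination ``⊞_k alpha_k ⊙ x_k``, canonicalized.

    Coordinatewise ``max_k (alpha_k + x_ki)`` in the max convention,
    coordinatewise min in the min convention.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    alphas = np.asarray(alphas, dtype=float)
    if alphas.shape[0] != X.shape[0]:
        raise ValueError("need one coefficient per generator")
    shifted = X + alphas[:, None]
    if convention == "max":
        return canonicalize(shifted.max(axis=0))
    if convention == "min":
        return canonicalize(shifted.min(axis=0))
    raise ValueError(f"unknown convention {convention!r}")


class HullProjection(NamedTuple):
    """Metric projection of a query point onto a tropical convex hull."""

    projected: np.ndarray
    lambdas: np.ndarray
    distance: float


def hull_project(t, X, convention: Convention = "max") -> HullProjection:
    """Project ``t`` onto the tropical convex hull of the rows of ``X``.

    For the max convention the closed form is
    ``lambda_k = min_i (t_i - x_ki)`` with projection
    ``⊞_k lambda_k ⊙ x_k``; the distance ``d_tr(t, projection)`` is zero
    exactly when ``t`` lies in tconv_max(X).  The min convention is the
    mirrored construction.
    """
    t = canonicalize(t)
    X = as_point_set(X)
    _check_same_dim(t, X)
    diff = t[None, :] - X  # (K, N)
    if convention == "max":
        lambdas = diff.min(axis=1)
    elif convention == "min":
        lambdas = diff.max(axis=1)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    proj = trop_combination(X, lambdas, convention)
    return HullProjection(proj, lambdas, d_tr(t, proj))


def hull_diagnostics(t, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-coordinate hull-convergence diagnostics (delta_j, Delta_j).

    ``delta_j = min_k sum_i [t_j - x_kj - t_i + x_ki]^+`` and ``Delta_j`` is
    the corresponding sum over samples.  They satisfy ``K delta_j <= Delta_j``
    and bound the distance to the max-tropical hull:
    ``d_tr(t, tconv_max(X)) <= max_j delta_j``.
    """
    t = canonicalize(t)
    X = as_point_set(X)
    _check_same_dim(t, X)
    diff = t[None, :] - X  # (K, N)
    # terms[k, j, i] = [diff[k, j] - diff[k, i]]^+
    terms = np.maximum(diff[:, :, None] - diff[:, None, :], 0.0)
    per_sample = terms.sum(axis=2)  # (K, N)
    return per_sample.min(axis=0), per_sample.sum(axis=0)


def segment_point(a, b, alpha: float, beta: float) -> np.ndarray:
    """Point ``alpha ⊙ a ⊞ beta ⊙ b`` on the tropical line segment ab."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_same_dim(a, b)
    return canonicalize(np.maximum(alpha + a, beta + b))


def read_point_set(path, header: bool | None = None) -> np.ndarray:
    """Read a point set from CSV (rows = samples) and canonicalize rows.

    ``header=None`` auto-detects a header row (non-numeric first line).
    """
    if header is None:
        first = pd.read_csv(path, header=None, nrows=1)
        header = not all(
            np.issubdtype(dt, np.number) for dt in first.dtypes
        )
    df = pd.read_csv(path, header=0 if header else None)
    return as_point_set(df.to_numpy(dtype=float))


def write_point_set(X, path, columns=None) -> None:
    """Write a point set to CSV, one sample per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    df = pd.DataFrame(X, columns=columns)
    df.to_csv(path, index=False, header=columns is not None)
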