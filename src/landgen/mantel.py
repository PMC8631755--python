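"""Mantel and partial Mantel permutation tests for distance matrices.

The test statistic is the Pearson correlation of upper-triangle entries;
significance comes from jointly permuting rows and columns of the second
matrix. The default alternative is one-tailed positive (the
isolation-by-resistance hypothesis); the sampled-permutation p-value
uses the (count + 1)/(n_perm + 1) convention, and when n! <= n_perm the
full permutation distribution is enumerated instead.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd

from .geo import pairwise_distance_km

__all__ = [
    "mantel",
    "partial_mantel",
    "geographic_distance_matrix",
    "read_distance_csv",
    "write_distance_csv",
]


def _check_matrix(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(M, M.T, equal_nan=True):
        raise ValueError(f"{name} is not symmetric")
    return M


def _triu(M: np.ndarray) -> np.ndarray:
    return M[np.triu_indices(M.shape[0], k=1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx < 1e-30 or sy < 1e-30:
        raise ValueError("constant matrix: Mantel r undefined")
    return float((xc * yc).sum() / (sx * sy))


def _perm_stats(A: np.ndarray, B: np.ndarray, n_perm: int, seed: int,
                stat) -> tuple[float, float]:
    """Shared permutation engine: ``stat(A, B)`` maps two square matrices
    to a scalar; B's rows+columns are permuted jointly."""
    n = A.shape[0]
    r_obs = stat(A, B)
    if factorial(n) <= n_perm:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            p = np.array(perm)
            r_p = stat(A, B[np.ix_(p, p)])
            count += r_p >= r_obs - 1e-12
            total += 1
        p_val = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            r_p = stat(A, B[np.ix_(p, p)])
            count += r_p >= r_obs - 1e-12
        p_val = (count + 1) / (n_perm + 1)
    return r_obs, float(p_val)


def mantel(A: np.ndarray, B: np.ndarray, n_perm: int = 999, seed: int = 0,
           tail: str = "greater") -> tuple[float, float]:
    """Mantel test of matrix association.

    Returns (r, p) where r is the Pearson correlation of the
    upper-triangle entries and p the permutation p-value (one-tailed
    positive by default; ``tail="two-sided"`` doubles-or-mirrors on
    |r|).
    """
    A = _check_matrix(A, "A")
    B = _check_matrix(B, "B")
    if A.shape != B.shape:
        raise ValueError("matrix shapes differ")
    if A.shape[0] < 4:
        raise ValueError("need >= 4 labels")
    if tail == "greater":
        stat = lambda a, b: _pearson(_triu(a), _triu(b))
    elif tail == "two-sided":
        stat = lambda a, b: abs(_pearson(_triu(a), _triu(b)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    r, p = _perm_stats(A, B, n_perm, seed, stat)
    if tail == "two-sided":
        r = _pearson(_triu(A), _triu(B))  # report the signed statistic
    return r, p


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """First-order partial correlation of a and b given c.

    Uses r_ab.c = (r_ab - r_ac r_bc) / sqrt((1-r_ac^2)(1-r_bc^2)); a
    0/0 degeneracy (e.g. a identical to c) is resolved to 0 — the
    conditioning matrix then explains the association entirely. A
    constant-after-centering c reduces to the plain correlation.
    """
    cc = c - c.mean()
    if np.sqrt((cc**2).sum()) < 1e-30:
        return _pearson(a, b)
    r_ab = _pearson(a, b)
    r_ac = _pearson(a, c)
    r_bc = _pearson(b, c)
    num = r_ab - r_ac * r_bc
    den = np.sqrt(max(1 - r_ac**2, 0.0) * max(1 - r_bc**2, 0.0))
    if den < 1e-12:
        if abs(num) < 1e-9:
            return 0.0
        raise ValueError("partial correlation undefined: perfect collinearity")
    return float(num / den)


def partial_mantel(A: np.ndarray, B: np.ndarray, C: np.ndarray,
                   n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Partial Mantel test: correlation of A and B with C partialed out,
    one-tailed positive; significance by jointly permuting B's rows and
    columns and recomputing the partial statistic."""
    A = _check_matrix(A, "A")
    B = _check_matrix(B, "B")
    C = _check_matrix(C, "C")
    if not (A.shape == B.shape == C.shape):
        raise ValueError("matrix shapes differ")
    if A.shape[0] < 4:
        raise ValueError("need >= 4 labels")
    b, c = _triu(B), _triu(C)
    bc = b - b.mean()
    cc = c - c.mean()
    if (
        np.sqrt((bc**2).sum()) > 1e-30
        and np.sqrt((cc**2).sum()) > 1e-30
        and abs(_pearson(b, c) ** 2 - 1.0) < 1e-12
    ):
        raise ValueError("C is perfectly collinear with B")
    stat = lambda a, bb: _partial_r(_triu(a), _triu(bb), _triu(C))
    return _perm_stats(A, B, n_perm, seed, stat)


def geographic_distance_matrix(pops) -> tuple[np.ndarray, list[str]]:
    """Great-circle distance matrix (km) between population coordinates."""
    if len(set(pops.ids)) != len(pops.ids):
        raise ValueError("duplicate population labels")
    return pairwise_distance_km(pops.lons, pops.lats), list(pops.ids)


def write_distance_csv(path, M: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path)


def read_distance_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels differ")
    return df.to_numpy(dtype=float), list(df.index)
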