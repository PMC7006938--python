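"""Earth mover's distance helpers for repertoire and concept comparison.

Repertoires are probability distributions over the 2**m states of a set of
binary units; the ground metric is the Hamming distance between states.
Distances are computed exactly by solving the transportation linear
program with scipy's HiGHS backend.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import linprog

__all__ = ["hamming_matrix", "emd_hamming", "transport_cost"]

_ATOL = 1e-12


@lru_cache(maxsize=None)
def hamming_matrix(n_bits: int) -> np.ndarray:
    """Pairwise Hamming distances between all 2**n_bits states."""
    states = np.arange(2**n_bits)
    xor = states[:, None] ^ states[None, :]
    # popcount via uint8 view
    return np.unpackbits(
        xor.astype(np.uint32).view(np.uint8).reshape(xor.shape + (4,)), axis=-1
    ).sum(axis=-1).astype(np.float64)


def transport_cost(
    supply: np.ndarray, demand: np.ndarray, cost: np.ndarray
) -> float:
    """Minimum-cost transport of ``supply`` onto ``demand``.

    Masses must balance (up to numerical noise); the result is the
    optimal objective of the transportation LP.
    """
    supply = np.asarray(supply, dtype=np.float64)
    demand = np.asarray(demand, dtype=np.float64)
    ns, nd = supply.size, demand.size
    if abs(supply.sum() - demand.sum()) > 1e-9:
        raise ValueError("supply and demand masses differ")
    if supply.sum() <= _ATOL:
        return 0.0
    # trivial: identical point sets with identical masses
    if ns == nd and np.allclose(supply, demand, atol=_ATOL) and np.allclose(
        cost.diagonal(), 0.0
    ):
        return 0.0
    c = cost.ravel()
    a_eq = np.zeros((ns + nd, ns * nd))
    for i in range(ns):
        a_eq[i, i * nd : (i + 1) * nd] = 1.0
    for j in range(nd):
        a_eq[ns + j, j::nd] = 1.0
    b_eq = np.concatenate([supply, demand])
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is robust on feasible LPs
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def emd_hamming(p: np.ndarray, q: np.ndarray) -> float:
    """EMD between two distributions over the same m-bit state space."""
    p = np.asarray(p, dtype=np.float64).ravel()
    q = np.asarray(q, dtype=np.float64).ravel()
    if p.size != q.size:
        raise ValueError("distributions live on different state spaces")
    if np.allclose(p, q, atol=_ATOL):
        return 0.0
    n_bits = int(np.log2(p.size))
    return transport_cost(p, q, hamming_matrix(n_bits))
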