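"""Numba kernel for single-spin Metropolis annealing of the spin-glass energy.

The state is a spin vector sigma over k nodes with q = k allowed states.
The coupling matrix B holds W_ij - gamma * p off the diagonal, so the
energy is H = -sum_{i<j, sigma_i == sigma_j} B_ij.  A bookkeeping matrix
M[i, m] = sum_{j != i, sigma_j == m} B_ij makes a proposal evaluation O(1)
and an accepted move O(k).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _anneal_kernel(
    B: np.ndarray,
    seed: int,
    t0: float,
    cooling: float,
    sweeps_per_temperature: int,
    min_temperature: float,
    patience: int,
):
    """Return (best_sigma, best_energy, initial_energy, initial_sigma).

    t0 <= 0 requests auto-calibration: T0 is set so uphill proposals from
    the random initial state are accepted with probability ~0.9.
    """
    k = B.shape[0]
    np.random.seed(seed)
    sigma = np.empty(k, dtype=np.int64)
    for i in range(k):
        sigma[i] = np.random.randint(0, k)
    initial_sigma = sigma.copy()

    M = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                M[i, sigma[j]] += B[i, j]

    energy = 0.0
    for i in range(k):
        energy -= M[i, sigma[i]]
    energy *= 0.5
    initial_energy = energy

    temperature = t0
    if t0 <= 0.0:
        # sample uphill move sizes from the initial state
        total = 0.0
        count = 0
        for _ in range(256):
            i = np.random.randint(0, k)
            s_new = np.random.randint(0, k)
            d = -(M[i, s_new] - M[i, sigma[i]])
            if d > 0.0:
                total += d
                count += 1
        if count > 0:
            # exp(-dH/T0) = 0.9  =>  T0 = mean(dH) / ln(1/0.9)
            temperature = (total / count) / 0.10536051565782628
        else:
            temperature = 1.0

    best_energy = energy
    best_sigma = sigma.copy()
    stale = 0
    n_updates = sweeps_per_temperature * k

    while temperature > min_temperature and stale < patience:
        improved = False
        for _ in range(n_updates):
            i = np.random.randint(0, k)
            s_new = np.random.randint(0, k)
            s_old = sigma[i]
            if s_new == s_old:
                continue
            d = -(M[i, s_new] - M[i, s_old])
            if d <= 0.0 or np.random.random() < np.exp(-d / temperature):
                for j in range(k):
                    if j != i:
                        M[j, s_old] -= B[j, i]
                        M[j, s_new] += B[j, i]
                sigma[i] = s_new
                energy += d
                if energy < best_energy - 1e-12:
                    best_energy = energy
                    best_sigma[:] = sigma
                    improved = True
        if improved:
            stale = 0
        else:
            stale += 1
        temperature *= cooling

    return best_sigma, best_energy, initial_energy, initial_sigma
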