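"""Independent brute-force oracles for the spatial statistics.

Deliberately naive: dense matrices, explicit Python loops, no shared code
with the package implementation.
"""

import itertools
import math

import numpy as np


def moran_bruteforce(x, W_dense) -> float:
    """Global Moran's I by explicit triple-loop summation."""
    n = len(x)
    xbar = sum(x) / n
    num = 0.0
    S0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W_dense[i][j] * (x[i] - xbar) * (x[j] - xbar)
            S0 += W_dense[i][j]
    den = sum((xi - xbar) ** 2 for xi in x)
    return n / S0 * num / den


def local_moran_bruteforce(x, W_dense):
    """Per-unit local Moran's I with population-sd z-scores."""
    n = len(x)
    xbar = sum(x) / n
    sigma = math.sqrt(sum((xi - xbar) ** 2 for xi in x) / n)
    z = [(xi - xbar) / sigma for xi in x]
    out = []
    for i in range(n):
        lag = sum(W_dense[i][j] * z[j] for j in range(n))
        out.append(z[i] * lag)
    return out


def exhaustive_permutation_morans(x, W_dense):
    """Moran's I over every permutation of x (use only for tiny n)."""
    return [moran_bruteforce([x[p] for p in perm], W_dense)
            for perm in itertools.permutations(range(len(x)))]


def random_weights(rng, n, row_standardize):
    """Random sparse-ish binary neighbour structure as a dense list-of-lists."""
    k = int(rng.integers(1, min(6, n - 1) + 1))
    W = [[0.0] * n for _ in range(n)]
    for i in range(n):
        choices = rng.choice([j for j in range(n) if j != i], size=k, replace=False)
        for j in choices:
            W[i][int(j)] = 1.0
    if row_standardize:
        for i in range(n):
            s = sum(W[i])
            if s:
                W[i] = [w / s for w in W[i]]
    return np.array(W)
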