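"""Independent brute-force oracles used across the test suite.

Each function here recomputes a quantity by a different route than the
implementation: exhaustive enumeration, all-pairs counting, or exact
rational arithmetic. They stay deliberately naive.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np

from gdassess.genomic_io import HET, MISSING
from gdassess.roh import AZ, HW
from gdassess.synthetic import HaplotypeSample


def brute_force_pi(sample: HaplotypeSample) -> float:
    """Average pairwise Hamming distance across all haplotype pairs."""
    n = sample.n_haplotypes
    haps = np.zeros((n, len(sample.positions)), dtype=int)
    for s, carriers in enumerate(sample.carriers):
        for h in carriers:
            haps[h, s] = 1
    diffs = [np.sum(haps[i] != haps[j]) for i, j in combinations(range(n), 2)]
    return float(np.mean(diffs)) if diffs else 0.0


def tajimas_d_exact(S: int, pi_abs: float, n: int) -> float:
    """Tajima's D from constants built one by one in exact rationals."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_abs - S / float(a1)) / math.sqrt(float(var))


def brute_force_viterbi(
    observations: np.ndarray,
    positions: np.ndarray,
    p_het_az: float,
    het_probs_hw: np.ndarray,
    transition_per_bp: float,
) -> tuple[np.ndarray, float]:
    """Enumerate every 2^m state path; return the best path and its log-prob."""
    m = len(observations)
    assert m <= 14, "enumeration oracle is for tiny instances only"
    emis = np.zeros((m, 2))
    for t, obs in enumerate(observations):
        if obs == MISSING:
            continue
        if obs == HET:
            emis[t, AZ] = math.log(p_het_az)
            emis[t, HW] = math.log(het_probs_hw[t])
        else:
            emis[t, AZ] = math.log1p(-p_het_az)
            emis[t, HW] = math.log1p(-het_probs_hw[t])
    gaps = np.diff(np.asarray(positions, dtype=np.int64))
    log_stay = gaps * math.log1p(-transition_per_bp)
    log_switch = np.log(-np.expm1(log_stay))

    codes = np.arange(2**m, dtype=np.int64)
    paths = (codes[:, None] >> np.arange(m)) & 1  # (2^m, m) of {0=AZ, 1=HW}
    scores = math.log(0.5) + emis[np.arange(m), paths].sum(axis=1)
    same = paths[:, 1:] == paths[:, :-1]
    scores += np.where(same, log_stay, log_switch).sum(axis=1)
    best = int(np.argmax(scores))
    return paths[best].astype(np.int8), float(scores[best])


def per_base_membership(intervals, scaffold: str, length: int) -> np.ndarray:
    """Boolean per-base occupancy array for one scaffold."""
    arr = np.zeros(length, dtype=bool)
    for chrom, start, end in intervals:
        if chrom == scaffold:
            arr[start:end] = True
    return arr
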