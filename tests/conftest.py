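"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from mtbottleneck import bottleneck_sim as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def enumerate_partition(n_wt: int, n_mut: int, p1: float = 0.5):
    """Brute-force enumeration of all daughter-1 outcomes, one molecule a unit.

    Walks every assignment of the n_wt + n_mut molecules to the two daughters
    (2^n equiprobable outcomes when p1 = 0.5) and returns a dict
    (w1, m1) -> probability.  Independent of any binomial shortcut.
    """
    n = n_wt + n_mut
    probs: dict[tuple[int, int], float] = {}
    for assignment in itertools.product([0, 1], repeat=n):
        p = 1.0
        w1 = m1 = 0
        for i, to_d1 in enumerate(assignment):
            p *= p1 if to_d1 else (1.0 - p1)
            if to_d1:
                if i < n_wt:
                    w1 += 1
                else:
                    m1 += 1
        probs[(w1, m1)] = probs.get((w1, m1), 0.0) + p
    return probs


def enumeration_daughter_h_moments(n_wt: int, n_mut: int, p1: float = 0.5):
    """Exact E[h] and Var(h) of a non-empty daughter from the enumeration."""
    probs = enumerate_partition(n_wt, n_mut, p1)
    mass = e1 = e2 = 0.0
    for (w1, m1), p in probs.items():
        if w1 + m1 == 0:
            continue
        h = m1 / (w1 + m1)
        mass += p
        e1 += p * h
        e2 += p * h * h
    e1 /= mass
    e2 /= mass
    return e1, max(e2 - e1 * e1, 0.0)


def reference_bh_stepup(pvalues, q):
    """Hand-coded Benjamini-Hochberg step-up used as the cross-check."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject[order[:k_max]] = True
    # adjusted p: running minimum from the largest rank downwards
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return reject, adj


@pytest.fixture
def tiny_cell_records() -> pd.DataFrame:
    """Small tidy cell table covering two days of one sorted population."""
    rng = np.random.default_rng(7)
    rows = []
    for day, (mean, var, n) in {
        "D4": (0.296, 0.020, 46),
        "D6": (0.296, 0.041, 58),
    }.items():
        h = sim.sample_heteroplasmy(mean, var, n, rng=rng)
        copies = sim.sample_copy_numbers(1240 if day == "D4" else 249, 300, n, rng=rng)
        for i in range(n):
            rows.append(
                {
                    "cell_id": f"{day}_c{i:03d}",
                    "line": "ND1",
                    "protocol": "modified-3pct",
                    "day": day,
                    "gate": "BV+",
                    "heteroplasmy": h[i],
                    "copies": copies[i],
                }
            )
    return pd.DataFrame(rows)
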