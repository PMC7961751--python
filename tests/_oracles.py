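"""Independent brute-force oracles the fast implementations are checked against.

Each oracle deliberately shares no code with the implementation it checks:
the forward algorithm is checked by explicit path enumeration, the midrank
AUC by counting all positive/negative pairs, and the greedy negative-slot
packing by an exhaustive dynamic program over every feasible placement.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_loglik(params, sequence: np.ndarray) -> float:
    """log p(X | theta) by summing over all K^T state paths."""
    X = np.asarray(sequence, dtype=float).T  # (T, D)
    T = X.shape[0]
    K = params.n_states
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = params.initial[path[0]]
        for a, b in zip(path, path[1:]):
            p *= params.transition[a, b]
        for t, k in enumerate(path):
            for d in range(X.shape[1]):
                var = params.variances[k, d]
                p *= math.exp(-((X[t, d] - params.means[k, d]) ** 2) / (2 * var)) / math.sqrt(
                    2 * math.pi * var
                )
        total += p
    return math.log(total)


def pair_count_auc(pos_scores, neg_scores) -> float:
    """AUC by exhaustive pair counting; ties count one half."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def max_slot_packing(
    n_frames: int,
    feasible,
    slot_frames: int,
    slot_gap_frames: int,
) -> int:
    """Maximum number of slots over every feasible placement (exhaustive DP).

    ``feasible(a)`` says whether a slot may start at frame ``a`` (bounds,
    head discard, peak gap, artifacts); consecutive chosen slots must be
    separated by ``slot_gap_frames``.  f(p) = best count using starts >= p.
    """
    last = n_frames - slot_frames
    f = np.zeros(last + 2 + slot_frames + slot_gap_frames, dtype=int)
    for a in range(last, -1, -1):
        f[a] = f[a + 1]
        if feasible(a):
            f[a] = max(f[a], 1 + f[a + slot_frames + slot_gap_frames])
    return int(f[0])
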