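"""Independent brute-force oracle for the surrogate-parent HMM.

Pure-python enumeration of every surrogate-pair path, written directly from
the model definition (slot transmission emissions, per-slot exponential
switch probabilities, uniform redraw).  Kept free of any package internals
so it can certify the Viterbi implementation.
"""

import numpy as np


def transmit_prob(genotype: int) -> float:
    return 0.5 if genotype < 0 else genotype / 2.0


def emission(tgt_geno: int, ga: int, gb: int, error_rate: float) -> float:
    if tgt_geno < 0:
        return 1.0
    pa, pb = transmit_prob(ga), transmit_prob(gb)
    true_probs = [
        (1 - pa) * (1 - pb),
        pa * (1 - pb) + (1 - pa) * pb,
        pa * pb,
    ]
    return sum(
        true_probs[t] * ((1 - error_rate) if t == tgt_geno else error_rate / 2.0)
        for t in range(3)
    )


def brute_force_best_path(tgt, cand, cm, error_rate, switch_rate):
    """Exhaustive maximum over all ordered surrogate-pair paths.

    Returns (best log-probability, best path as a tuple of (left, right)
    candidate indices, number of maximisers within 1e-9).
    """
    n, m = cand.shape
    states = [(a, b) for a in range(n) for b in range(n)]
    n_states = len(states)

    log_emis = np.full((m, n_states), -np.inf)
    for j in range(m):
        for k, (a, b) in enumerate(states):
            e = emission(tgt[j], cand[a, j], cand[b, j], error_rate)
            if e > 0:
                log_emis[j, k] = np.log(e)

    log_keep = np.empty(m - 1)
    log_move = np.empty(m - 1)
    for j in range(m - 1):
        d = (cm[j + 1] - cm[j]) / 100.0
        s = 1.0 - np.exp(-switch_rate * d)
        log_keep[j] = np.log((1.0 - s) + s / n)
        log_move[j] = np.log(s / n) if s > 0 else -np.inf

    # state-pair transition matrices (slots switch independently)
    same = np.array(
        [[(int(a == c), int(b == d)) for (c, d) in states] for (a, b) in states]
    )  # (S, S, 2)

    # enumerate all S^m paths: scores kept as (prefixes, last state)
    with np.errstate(invalid="ignore"):
        scores = (np.log(1.0 / n_states) + log_emis[0])[None, :]
        for j in range(1, m):
            trans = np.where(same, log_keep[j - 1], log_move[j - 1]).sum(axis=2)
            scores = (scores[:, :, None] + trans[None, :, :] + log_emis[j][None, None, :])
            scores = scores.reshape(-1, n_states)
    flat = scores.reshape(-1)
    flat = np.nan_to_num(flat, nan=-np.inf)
    best_idx = int(np.argmax(flat))  # first maximiser = lexicographically least
    best_lp = float(flat[best_idx])

    def decode(idx):
        digits = []
        for _ in range(m):
            digits.append(idx % n_states)
            idx //= n_states
        return tuple(states[k] for k in reversed(digits))

    maximisers = np.flatnonzero(flat > best_lp - 1e-9)
    unordered = {
        tuple(frozenset(pair) for pair in decode(int(i))) for i in maximisers[:1000]
    }
    unordered_unique = len(unordered) == 1 and len(maximisers) <= 1000
    return best_lp, decode(best_idx), unordered_unique
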