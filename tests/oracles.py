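"""Independent linear-algebra oracle for the single-molecule dynamics.

Builds the explicit generator of the continuous-time Markov chain a
single molecule follows (one free state + one state per (start, strand))
and solves for the stationary distribution directly.  This never calls
the event-driven simulator, so it is an independent check of it.
"""

import numpy as np


def single_molecule_generator(tau: np.ndarray, k_assoc: float,
                              move_probs, hop_range: int) -> np.ndarray:
    """Generator matrix Q; state 0 = free, then strand-major bound states.

    tau : (n_strands, n_starts) mean waiting times.
    Transition rules mirror the simulator: binding uniform over
    (start, strand); slide left/right to adjacent start (rejected at the
    DNA ends -> no transition); hop uniform over +-[1, hop_range]
    (off-end rejected); unbind to free.
    """
    n_strands, n_starts = tau.shape
    p_left, p_right, p_hop, p_unbind = move_probs
    n_states = 1 + n_strands * n_starts
    Q = np.zeros((n_states, n_states))

    # binding: total rate k, uniform over all bound states
    per_target = k_assoc / (n_strands * n_starts)
    for j in range(1, n_states):
        Q[0, j] = per_target

    for s in range(n_strands):
        for p in range(n_starts):
            i = 1 + s * n_starts + p
            rate = 1.0 / tau[s, p]
            if p > 0:
                Q[i, i - 1] += rate * p_left
            if p < n_starts - 1:
                Q[i, i + 1] += rate * p_right
            if p_hop > 0:
                per_disp = rate * p_hop / (2 * hop_range)
                for d in range(1, hop_range + 1):
                    if p - d >= 0:
                        Q[i, i - d] += per_disp
                    if p + d <= n_starts - 1:
                        Q[i, i + d] += per_disp
            Q[i, 0] += rate * p_unbind

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1 by least squares on the augmented system."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    assert np.all(pi > -1e-12)
    return np.clip(pi, 0.0, None) / pi.sum()


def single_molecule_stationary(tau: np.ndarray, k_assoc: float, move_probs,
                               hop_range: int):
    """(pi_free, pi_bound[(strand, start)]) for the single-molecule chain."""
    Q = single_molecule_generator(tau, k_assoc, move_probs, hop_range)
    pi = stationary_distribution(Q)
    n_strands, n_starts = tau.shape
    return pi[0], pi[1:].reshape(n_strands, n_starts)
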