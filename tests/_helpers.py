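"""Independent oracles used across the test suite.

Everything here deliberately avoids the package's pruning/two-pass code
paths: likelihoods and marginals are computed by exhaustive enumeration
over internal-node state assignments, and CTMC paths by naive forward
(Gillespie) simulation, so the fast implementations are checked against
genuinely independent computations.
"""

from __future__ import annotations

import itertools

import numpy as np

from mycostate import Chronogram, StateSpace, TipData


def tip_state_indices(tree: Chronogram, data: TipData) -> dict[int, int | None]:
    out: dict[int, int | None] = {}
    for k, lab in zip(tree.tip_indices, tree.tip_labels):
        s = data.assignments[lab]
        out[k] = None if s is None else data.space.index(s)
    return out


def brute_force_likelihood(tree: Chronogram, data: TipData,
                           P: np.ndarray, pi: np.ndarray) -> float:
    """Sum the joint probability over every assignment of states to every
    node (tips restricted to their observation), in plain double loops."""
    S = len(pi)
    tips = tip_state_indices(tree, data)
    choices = []
    for k in range(tree.n_nodes):
        if k in tips and tips[k] is not None:
            choices.append([tips[k]])
        else:
            choices.append(list(range(S)))
    total = 0.0
    for assign in itertools.product(*choices):
        p = pi[assign[tree.root_index]]
        for k in range(tree.n_nodes):
            par = tree.parent[k]
            if par >= 0:
                p *= P[k][assign[par], assign[k]]
        total += p
    return total


def brute_force_node_marginals(tree: Chronogram, data: TipData,
                               P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Posterior state marginals at every node by full enumeration."""
    S = len(pi)
    tips = tip_state_indices(tree, data)
    choices = []
    for k in range(tree.n_nodes):
        if k in tips and tips[k] is not None:
            choices.append([tips[k]])
        else:
            choices.append(list(range(S)))
    marg = np.zeros((tree.n_nodes, S))
    total = 0.0
    for assign in itertools.product(*choices):
        p = pi[assign[tree.root_index]]
        for k in range(tree.n_nodes):
            par = tree.parent[k]
            if par >= 0:
                p *= P[k][assign[par], assign[k]]
        total += p
        for k, s in enumerate(assign):
            marg[k, s] += p
    return marg / total


def forward_path(Q: np.ndarray, a: int, t: float,
                 rng: np.random.Generator) -> tuple[int, int]:
    """Unconditional forward simulation on one branch; returns the end
    state and the number of transitions."""
    S = Q.shape[0]
    s, elapsed, n = a, 0.0, 0
    while True:
        out = -Q[s, s]
        if out <= 0:
            break
        wait = rng.exponential(1.0 / out)
        if elapsed + wait >= t:
            break
        elapsed += wait
        w = Q[s].copy()
        w[s] = 0.0
        s = int(rng.choice(S, p=w / w.sum()))
        n += 1
    return s, n


def rejection_counts(Q: np.ndarray, a: int, b: int, t: float,
                     rng: np.random.Generator, n_keep: int) -> np.ndarray:
    """Transition counts of endpoint-conditioned paths obtained the naive
    way: forward-simulate and keep paths that end in ``b``."""
    kept = []
    while len(kept) < n_keep:
        end, n = forward_path(Q, a, t, rng)
        if end == b:
            kept.append(n)
    return np.array(kept)


def random_tip_data(tree: Chronogram, space: StateSpace,
                    rng: np.random.Generator) -> TipData:
    return TipData(
        {lab: space.states[rng.integers(space.n_states)] for lab in tree.tip_labels},
        space,
    )
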