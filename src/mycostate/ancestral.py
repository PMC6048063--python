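"""Marginal ancestral-state reconstruction.

For each rate-model draw, node marginals come from the standard two-pass
(inside/outside) algorithm: the inside pass is Felsenstein pruning, the
outside pass propagates the root prior down the tree, and the marginal
posterior at a node is the normalized elementwise product of the two.
Averaging the per-draw marginals over the post-burn-in rate posterior
integrates out rate uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctmc import RateModel, RootPrior, TransitionKernel, build_Q, prune_partials
from .inference import PosteriorTrace
from .phylo_io import Chronogram, TipData
from .statespace import StateSpace

__all__ = ["AncestralReconstruction", "marginal_asr", "branch_states"]

Move = tuple[int, int]


@dataclass
class AncestralReconstruction:
    """Per-node marginal posterior state probabilities.

    ``node_probs[k]`` is the distribution over states for node ``k`` in
    the tree's postorder indexing (tips included; the root respects the
    root prior, in particular a fixed-state prior yields a point mass).
    """

    tree: Chronogram
    space: StateSpace
    node_probs: np.ndarray  # (n_nodes, n_states)
    n_rate_samples: int

    def distribution(self, node: int) -> dict[str, float]:
        return dict(zip(self.space.labels, self.node_probs[node]))

    @property
    def root_distribution(self) -> dict[str, float]:
        return self.distribution(self.tree.root_index)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.node_probs, columns=list(self.space.labels))
        df.insert(0, "node", np.arange(self.tree.n_nodes))
        df.insert(1, "label", [l or "" for l in self.tree.label])
        df.insert(2, "age_Myr", self.tree.age)
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def annotated_newick(self) -> str:
        """Newick with BEAST-style metacomments carrying state posteriors."""
        probs = self.node_probs
        labels = self.space.labels

        def comment(k: int) -> str:
            inner = ",".join(f"p_{lbl}={probs[k, s]:.6g}" for s, lbl in enumerate(labels))
            return "[&" + inner + "]"

        def render(k: int) -> str:
            if not self.tree.children[k]:
                name = (self.tree.label[k] or "").replace(" ", "_")
                return f"{name}{comment(k)}:{self.tree.branch_length[k]:.10g}"
            inner = ",".join(render(c) for c in self.tree.children[k])
            if k == self.tree.root_index:
                return f"({inner}){comment(k)}"
            return f"({inner}){comment(k)}:{self.tree.branch_length[k]:.10g}"

        return render(self.tree.root_index) + ";"


def _node_marginals_one(tree: Chronogram, tip_partials: np.ndarray,
                        Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    kernel = TransitionKernel(Q)
    inside, _, P = prune_partials(tree, tip_partials, kernel)
    n_nodes, S = inside.shape
    outside = np.zeros((n_nodes, S))
    outside[tree.root_index] = pi
    # messages M[c] = P_c @ inside_c, toward the parent
    M = np.einsum("nij,nj->ni", P, inside)
    for p in tree.preorder():
        kids = tree.children[p]
        if not kids:
            continue
        for c in kids:
            # leave-one-out product over siblings, in parent-state space
            loo = outside[p].copy()
            for s in kids:
                if s != c:
                    loo = loo * M[s]
            vec = loo @ P[c]
            tot = vec.sum()
            outside[c] = vec / tot if tot > 0 else vec
    marg = inside * outside
    totals = marg.sum(axis=1, keepdims=True)
    bad = totals[:, 0] <= 0
    if bad.any():
        raise ValueError("zero marginal likelihood at some node; data impossible under model")
    return marg / totals


def _rate_draws(models, space, max_samples: int) -> list[Mapping[Move, float]]:
    if isinstance(models, RateModel):
        if models.space != space:
            raise ValueError("rate model state space differs from the data's")
        return [models.rates]
    if isinstance(models, PosteriorTrace):
        if models.space != space:
            raise ValueError("trace state space differs from the data's")
        return [dict(d) for d in models.thin(max_samples)]
    return [dict(d) for d in models]  # sequence of move->rate mappings


def marginal_asr(tree: Chronogram, data: TipData,
                 models: "RateModel | PosteriorTrace | Sequence[Mapping[Move, float]]",
                 root: RootPrior | None = None,
                 max_samples: int = 100) -> AncestralReconstruction:
    """Marginal state posteriors at every node, averaged over rate draws.

    ``models`` may be a single rate model, a posterior trace (thinned to
    at most ``max_samples`` evenly spaced draws), or an explicit sequence
    of per-move rate mappings.  Averaging per-draw marginals is the
    correct marginalization because expectation is linear.
    """
    root = root or RootPrior()
    space = data.space
    draws = _rate_draws(models, space, max_samples)
    if not draws:
        raise ValueError("no rate draws supplied")
    tip_partials = data.partial_matrix(tree)
    acc = np.zeros((tree.n_nodes, space.n_states))
    for rates in draws:
        full = {mv: float(rates.get(mv, 0.0)) for mv in space.moves}
        Q = build_Q(RateModel(space, full))
        acc += _node_marginals_one(tree, tip_partials, Q, root.vector(space, Q))
    probs = acc / len(draws)
    return AncestralReconstruction(tree, space, probs, len(draws))


@dataclass
class BranchStates:
    """Most-probable state of each branch (= its child node), Fig-1 style."""

    assignment: dict[int, int]  # node index -> state index
    ties: frozenset[int]        # nodes whose arg-max was tied
    space: StateSpace

    def labels(self) -> dict[int, str]:
        return {k: self.space.labels[s] for k, s in self.assignment.items()}


def branch_states(asr: AncestralReconstruction) -> BranchStates:
    """Arg-max state per node; exact ties resolve to the lower canonical
    state index and are flagged.  Each branch is identified by its child
    node, so the root (which has no branch) is included only as a node."""
    assignment: dict[int, int] = {}
    ties = set()
    for k in range(asr.tree.n_nodes):
        p = asr.node_probs[k]
        best = int(np.argmax(p))
        if np.sum(p == p[best]) > 1:
            ties.add(k)
        assignment[k] = best
    return BranchStates(assignment, frozenset(ties), asr.space)
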