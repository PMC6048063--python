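"""Synthetic chronograms and repertoire data.

Trees are grown under a Yule (pure-birth) process with a uniform birth
rate and are exactly ultrametric; repertoires then evolve down the tree
by event-driven (Gillespie) simulation under a known constrained Q, so
every downstream stage — likelihood, MCMC, marginal reconstruction,
mapping, hypothesis tests — can be validated against a known truth
without any real data deposit.

``make_paper_like_fixture`` emulates the *shape* of a real comparative
dataset: 732 tips on a ~475-Myr chronogram with clade-structured
repertoires over the states NM, M, G, G+M, B, A+B, G+B and A+B+G and
exactly 45 non-mycorrhizal tips.  Its generating rates are an invention
for integration testing, not estimates of anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .ctmc import RateModel, build_Q
from .mapping import MappedHistory
from .phylo_io import Chronogram, TipData
from .statespace import GroupCatalog, RepertoireState, StateSpace

__all__ = [
    "SimulationSpec",
    "simulate_tree",
    "simulate_characters",
    "make_paper_like_fixture",
]


@dataclass
class SimulationSpec:
    """Settings for one synthetic dataset.

    ``birth_rate`` is the Yule speciation rate per lineage per Myr;
    the default 0.03 puts a 50-tip tree's root age near 120 Myr so that
    rates around the default prior mean (0.01 events/Myr) produce a
    handful of transitions per tree — the regime the analysis assumes.
    """

    n_tips: int = 50
    birth_rate: float = 0.03
    root_age_rescale: float | None = None
    true_model: RateModel | None = None
    true_root_state: RepertoireState | None = None
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")


def simulate_tree(spec: SimulationSpec,
                  rng: np.random.Generator | None = None) -> Chronogram:
    """Grow a pure-birth chronogram to ``n_tips`` extant lineages.

    The root splits immediately into two lineages; thereafter each
    speciation waits an Exp(k * birth_rate) time and splits a uniformly
    chosen lineage.  After the last split an additional Exp(n * birth_rate)
    interval is appended so tip branches have realistic terminal lengths.
    When ``root_age_rescale`` is set all branch lengths are scaled so the
    root age equals it exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lam = spec.birth_rate
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    root = tree.seed_node
    # active lineages as (dendropy node, birth time of its branch)
    t = 0.0
    active = []
    for _ in range(2):
        ch = dendropy.Node()
        root.add_child(ch)
        active.append((ch, t))
    while len(active) < spec.n_tips:
        t += rng.exponential(1.0 / (lam * len(active)))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.edge.length = t - born
        for _ in range(2):
            ch = dendropy.Node()
            node.add_child(ch)
            active.append((ch, t))
    t += rng.exponential(1.0 / (lam * len(active)))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxon_ns.new_taxon(label=f"t{i + 1}")
    if spec.root_age_rescale is not None:
        f = spec.root_age_rescale / t
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= f
    return Chronogram(tree)


def simulate_characters(
    tree: Chronogram,
    true_model: RateModel,
    true_root_state: RepertoireState,
    seed: int | np.random.Generator = 0,
    missing_fraction: float = 0.0,
) -> tuple[TipData, MappedHistory]:
    """Evolve repertoires down the tree by exact Gillespie simulation.

    The root takes ``true_root_state``; along each branch the chain waits
    Exp(-Q[s,s]) and jumps to a neighbor with probability proportional to
    its rate, so every simulated event is a single allowed gain or loss.
    Returns the observed tip data (with ``missing_fraction`` of tips
    recoded as uncertain) and the full true history for recovery tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    space = true_model.space
    if true_root_state not in space:
        raise ValueError(f"root state {true_root_state.label!r} is not in the state space")
    Q = build_Q(true_model)
    S = space.n_states
    node_states = np.full(tree.n_nodes, -1, dtype=int)
    node_states[tree.root_index] = space.index(true_root_state)
    segments: dict[int, list[tuple[int, float]]] = {}
    events: list[tuple[float, int, int, int]] = []
    for p in tree.preorder():
        for c in tree.children[p]:
            s = int(node_states[p])
            remaining = float(tree.branch_length[c])
            segs: list[tuple[int, float]] = []
            elapsed = 0.0
            while True:
                out = -Q[s, s]
                wait = rng.exponential(1.0 / out) if out > 0 else np.inf
                if wait >= remaining:
                    segs.append((s, remaining))
                    break
                rates = Q[s].copy()
                rates[s] = 0.0
                nxt = int(rng.choice(S, p=rates / rates.sum()))
                segs.append((s, wait))
                elapsed += wait
                events.append((float(tree.age[p]) - elapsed, s, nxt, c))
                remaining -= wait
                s = nxt
            node_states[c] = s
            segments[c] = segs
    history = MappedHistory(space, node_states, segments, events)
    assignments: dict[str, RepertoireState | None] = {}
    for k, taxon in zip(tree.tip_indices, tree.tip_labels):
        assignments[taxon] = space.states[node_states[k]]
    if missing_fraction > 0:
        n_miss = int(round(missing_fraction * tree.n_tips))
        for taxon in rng.choice(list(tree.tip_labels), size=n_miss, replace=False):
            assignments[str(taxon)] = None
    return TipData(assignments, space), history


def default_true_model(space: StateSpace, gain_rate: float = 0.01,
                       loss_rate: float = 0.005) -> RateModel:
    """A simple generating model: gains at one rate, losses at half that
    (events/Myr) — the scale the exponential rate prior assumes."""
    rates = {}
    for (i, j) in space.moves:
        gain = space.states[j].mask.bit_count() > space.states[i].mask.bit_count()
        rates[(i, j)] = gain_rate if gain else loss_rate
    return RateModel(space, rates)


#: States observed in nature for the paper-like fixture: NM, M, G, G+M,
#: B, A+B, G+B, A+B+G (catalog order A, B, G, M).
_FIXTURE_LABELS = ("NM", "M", "G", "G+M", "B", "A+B", "G+B", "A+B+G")


def make_paper_like_fixture(seed: int = 0) -> tuple[Chronogram, TipData, MappedHistory]:
    """A 732-tip, 475-Myr chronogram with clade-structured repertoires.

    Qualitative shape: association enters from a non-mycorrhizal root via
    Mucoromycotina, early lineages are rich in M and G+M, most derived
    lineages settle into G, and Basidiomycota/Ascomycota repertoires (B,
    A+B, G+B, occasionally A+B+G) arise in nested clades; exactly 45 tips
    are non-mycorrhizal, enforced by recoding after simulation.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng([seed, 732])
    catalog = GroupCatalog()
    states = [RepertoireState.from_label(lbl, catalog) for lbl in _FIXTURE_LABELS]
    space = StateSpace(states)
    spec = SimulationSpec(n_tips=732, birth_rate=0.02, root_age_rescale=475.0, seed=seed)
    tree = simulate_tree(spec, rng)

    def mv(a: str, b: str) -> tuple[int, int]:
        return (space.index_of_label(a), space.index_of_label(b))

    # documented invention: an entry path NM->M->G+M->G, a slower B/A path,
    # and rare losses back to NM
    rates = {m: 0.0002 for m in space.moves}
    rates[mv("NM", "M")] = 0.015
    rates[mv("M", "G+M")] = 0.012
    rates[mv("G+M", "G")] = 0.008
    rates[mv("G", "G+M")] = 0.004
    rates[mv("NM", "G")] = 0.0005
    rates[mv("G", "NM")] = 0.0015
    rates[mv("M", "NM")] = 0.001
    rates[mv("NM", "B")] = 0.0008
    rates[mv("B", "A+B")] = 0.006
    rates[mv("B", "G+B")] = 0.004
    rates[mv("G", "G+B")] = 0.0015
    rates[mv("G+B", "A+B+G")] = 0.003
    true_model = RateModel(space, rates)
    nm = RepertoireState(0, catalog)
    data, history = simulate_characters(tree, true_model, nm, rng)

    # enforce exactly 45 non-mycorrhizal tips by recoding
    taxa = list(tree.tip_labels)
    nm_taxa = [tx for tx in taxa if data.assignments[tx] is not None
               and data.assignments[tx].is_empty]
    g_state = RepertoireState.from_label("G", catalog)
    if len(nm_taxa) > 45:
        for tx in rng.choice(nm_taxa, size=len(nm_taxa) - 45, replace=False):
            data.assignments[str(tx)] = g_state
    elif len(nm_taxa) < 45:
        pool = [tx for tx in taxa if tx not in set(nm_taxa)]
        for tx in rng.choice(pool, size=45 - len(nm_taxa), replace=False):
            data.assignments[str(tx)] = nm
    return tree, data, history
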