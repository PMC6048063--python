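"""Chronogram and tip-state I/O.

Trees are read with dendropy (Newick or NEXUS) and converted into a flat,
array-backed :class:`Chronogram` used by the likelihood, mapping and
through-time machinery.  The time axis runs rootward: extant tips sit at
age 0 and node ages increase toward the root, in million years (Myr), so
a branch spans the age interval ``[child_age, parent_age)``.

Tip states come from a TSV with columns ``taxon`` and ``groups``, where
``groups`` is a ``+``-separated list of catalog names (or abbreviations),
the literal ``none`` for non-mycorrhizal, or ``?`` for unknown — the
latter becomes uniform uncertainty over all states downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .statespace import RepertoireState, StateSpace

__all__ = [
    "Chronogram",
    "TipData",
    "UltrametricityWarning",
    "read_tree",
    "write_tree",
    "read_tip_data",
    "write_tip_data",
    "write_provenance",
]


class UltrametricityWarning(UserWarning):
    """Root-to-tip path lengths differ by more than the tolerance."""


class Chronogram:
    """Rooted time-calibrated tree with node ages in Myr.

    Nodes are indexed in postorder (root last).  For node ``k``:

    - ``parent[k]``: postorder index of the parent (-1 for the root)
    - ``branch_length[k]``: length of the branch above ``k`` in Myr
    - ``age[k]``: node age (0 at extant tips, root age at the root)
    - ``children[k]``: list of child indices (empty for tips)
    - ``label[k]``: taxon name for tips, optional label otherwise
    """

    def __init__(self, tree: dendropy.Tree, *, ultrametric_tol: float = 1e-6,
                 require_ultrametric: bool = False):
        if tree.seed_node is None or len(tree.seed_node.child_nodes()) < 2:
            raise ValueError("tree must be rooted with at least two root children")
        if getattr(tree, "is_rooted", True) is False:
            raise ValueError("tree is explicitly unrooted; a rooted chronogram is required")
        self._dendropy = tree
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        idx = {id(nd): k for k, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.branch_length = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.label: list[str | None] = [None] * self.n_nodes
        depth = np.zeros(self.n_nodes)
        for k, nd in enumerate(nodes):
            if nd.taxon is not None:
                self.label[k] = nd.taxon.label
            elif nd.label:
                self.label[k] = nd.label
            if nd.parent_node is not None:
                p = idx[id(nd.parent_node)]
                self.parent[k] = p
                self.children[p].append(k)
                bl = nd.edge.length
                if bl is None:
                    bl = 0.0
                if bl < 0:
                    raise ValueError(f"negative branch length {bl} above node {self.label[k] or k}")
                self.branch_length[k] = float(bl)
        # root is last in postorder; compute depths root-down
        for k in reversed(range(self.n_nodes)):
            if self.parent[k] >= 0:
                depth[k] = depth[self.parent[k]] + self.branch_length[k]
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        tips = np.flatnonzero(self.is_tip)
        tip_labels = [self.label[k] for k in tips]
        if any(lbl is None for lbl in tip_labels):
            raise ValueError("every tip must carry a taxon label")
        if len(set(tip_labels)) != len(tip_labels):
            dups = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        self.root_age = float(depth[tips].max())
        self.age = self.root_age - depth
        # snap float dust at the tips to exactly 0 so age-interval queries
        # (lineage counts, time bins) see contemporaneous tips at age 0
        tip_ages = self.age[tips]
        snap = np.abs(tip_ages) <= ultrametric_tol * max(self.root_age, 1e-300)
        self.age[tips[snap]] = 0.0
        rel = np.abs(self.age[tips]) / max(self.root_age, 1e-300)
        if rel.max() > ultrametric_tol:
            msg = (f"tree is not ultrametric: tip ages deviate up to "
                   f"{self.age[tips].max():.6g} Myr ({rel.max():.3g} relative)")
            if require_ultrametric:
                raise ValueError(msg)
            warnings.warn(msg, UltrametricityWarning)
        self.tip_indices = tips
        self.tip_labels: tuple[str, ...] = tuple(tip_labels)  # type: ignore[arg-type]
        self.root_index = self.n_nodes - 1

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def total_length(self) -> float:
        return float(self.branch_length.sum())

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def as_dendropy(self) -> dendropy.Tree:
        return self._dendropy

    @classmethod
    def from_newick(cls, text: str, **kwargs) -> "Chronogram":
        tree = _parse(data=text, schema="newick")
        return cls(tree, **kwargs)

    def to_newick(self) -> str:
        return self._dendropy.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree(path: str | Path, format: str = "newick", *, ultrametric_tol: float = 1e-6,
              require_ultrametric: bool = False) -> Chronogram:
    """Read a rooted chronogram from Newick or NEXUS.

    Node ages are computed from branch lengths assuming contemporaneous
    tips at age 0; polytomies are preserved.  Ultrametricity violations
    beyond ``ultrametric_tol`` (relative) warn by default, or raise when
    ``require_ultrametric``.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {format!r}")
    tree = _parse(path=str(path), schema=format)
    return Chronogram(tree, ultrametric_tol=ultrametric_tol,
                      require_ultrametric=require_ultrametric)


def _parse(**kwargs) -> dendropy.Tree:
    # Plain Newick/NEXUS without a rooting comment is taken as rooted (the
    # usual convention for chronograms); an explicit [&U] still raises.
    try:
        return dendropy.Tree.get(rooting="default-rooted", **kwargs)
    except dendropy.utility.error.DataParseError as e:
        if "Duplicate taxon" in str(e):
            raise ValueError(f"duplicate tip labels in tree: {e}") from e
        raise


def write_tree(tree: Chronogram, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


UNCERTAIN = None  # sentinel stored for '?' tips


@dataclass
class TipData:
    """Tip-state assignments: taxon -> RepertoireState, or None for '?'.

    ``partials`` converts assignments into per-tip partial-likelihood
    vectors over a state space: an indicator vector for an observed
    repertoire and all-ones for an uncertain tip.
    """

    assignments: dict[str, RepertoireState | None]
    space: StateSpace

    def __post_init__(self) -> None:
        for taxon, state in self.assignments.items():
            if state is not None and state not in self.space:
                raise ValueError(
                    f"taxon {taxon!r} has repertoire {state.label!r} outside the state space; "
                    "rebuild the space from the full observation set"
                )

    def validate_against(self, tree: Chronogram) -> None:
        tree_tips = set(tree.tip_labels)
        data_taxa = set(self.assignments)
        missing = sorted(tree_tips - data_taxa)
        if missing:
            raise ValueError(f"tree tips missing from tip data: {missing}")
        extra = sorted(data_taxa - tree_tips)
        if extra:
            raise ValueError(f"tip data taxa not on the tree: {extra}")

    def partials(self, taxon: str) -> np.ndarray:
        state = self.assignments[taxon]
        if state is None:
            return np.ones(self.space.n_states)
        vec = np.zeros(self.space.n_states)
        vec[self.space.index(state)] = 1.0
        return vec

    def partial_matrix(self, tree: Chronogram) -> np.ndarray:
        """(n_nodes, n_states) matrix of tip partials (rows for internal nodes are ones)."""
        out = np.ones((tree.n_nodes, self.space.n_states))
        for k, taxon in zip(tree.tip_indices, tree.tip_labels):
            out[k] = self.partials(taxon)
        return out

    def state_counts(self) -> pd.Series:
        labels = ["?" if s is None else s.label for s in self.assignments.values()]
        return pd.Series(labels).value_counts()


def read_tip_data(path: str | Path, space: StateSpace, tree: Chronogram | None = None) -> TipData:
    """Read a taxon/groups TSV into tip-state assignments over ``space``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "taxon" not in cols or "groups" not in cols:
        raise ValueError("tip table must have columns 'taxon' and 'groups'")
    assignments: dict[str, RepertoireState | None] = {}
    for _, row in df.iterrows():
        taxon = str(row[cols["taxon"]]).strip()
        raw = str(row[cols["groups"]]).strip()
        if taxon in assignments:
            raise ValueError(f"duplicate taxon {taxon!r} in tip table")
        if raw == "?":
            assignments[taxon] = None
        else:
            assignments[taxon] = RepertoireState.from_label(raw, space.catalog)
    data = TipData(assignments, space)
    if tree is not None:
        data.validate_against(tree)
    return data


def write_tip_data(data: TipData, path: str | Path) -> None:
    rows = [
        (taxon, "?" if state is None else ("none" if state.is_empty else "+".join(state.groups)))
        for taxon, state in data.assignments.items()
    ]
    pd.DataFrame(rows, columns=["taxon", "groups"]).to_csv(path, sep="\t", index=False)


def write_provenance(path: str | Path, **info) -> None:
    """Write a JSON sidecar recording catalog, state space, seeds, config."""
    Path(path).write_text(json.dumps(info, indent=2, default=str) + "\n")
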