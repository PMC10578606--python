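"""Dollo-parsimony gain/loss inference for W-linked gene components.

The W-specific genes of *Xenopus laevis* (*dm-w*, *scan-w*, *ccdc69-w*) each
arose once, by duplication or insertion, and can subsequently only be lost —
so presence/absence patterns of their exons across species are modelled under
Dollo parsimony: a single gain on one node of a rooted species tree followed
by any number of irreversible losses on descendant edges. Capture-sequencing
calls provide the tip states (present / absent / unknown); the species tree
is an input, not estimated here.

Tree handling is backed by dendropy; node identifiers are stable strings
(tip name, internal label when present, else a preorder ``nN`` id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "NewickParseError",
    "Tree",
    "DolloReconstruction",
    "parse_newick",
    "normalize_states",
    "read_states_csv",
    "states_for_locus",
    "dollo_min_losses",
    "dollo_optimal_gain",
]

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

_STATE_ALIASES: dict[object, str] = {
    "present": PRESENT, "1": PRESENT, 1: PRESENT, True: PRESENT, "p": PRESENT,
    "absent": ABSENT, "0": ABSENT, 0: ABSENT, False: ABSENT, "a": ABSENT,
    "unknown": UNKNOWN, "?": UNKNOWN, "na": UNKNOWN, "": UNKNOWN, None: UNKNOWN,
}


class NewickParseError(ValueError):
    """Raised for malformed newick input (unbalanced parentheses, duplicate tips...)."""


class Tree:
    """A rooted tree with stable string node ids.

    Tips are identified by their taxon label; internal nodes by their label in
    the newick string when present, otherwise by a preorder id ``n0, n1, ...``.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        self._by_id: dict[str, dendropy.Node] = {}
        self._id_of: dict[dendropy.Node, str] = {}
        k = 0
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise NewickParseError("tree has an unnamed tip")
                nid = node.taxon.label
            elif node.label:
                nid = node.label
            else:
                nid = f"n{k}"
                k += 1
            if nid in self._by_id:
                raise NewickParseError(f"duplicate node id {nid!r} in tree")
            self._by_id[nid] = node
            self._id_of[node] = nid

    # -- structure queries -------------------------------------------------

    @property
    def root(self) -> str:
        return self._id_of[self._dtree.seed_node]

    def node_ids(self) -> list[str]:
        return [self._id_of[n] for n in self._dtree.preorder_node_iter()]

    def tip_names(self) -> list[str]:
        return [self._id_of[n] for n in self._dtree.leaf_node_iter()]

    def is_tip(self, node_id: str) -> bool:
        return self._node(node_id).is_leaf()

    def parent(self, node_id: str) -> "str | None":
        p = self._node(node_id).parent_node
        return None if p is None else self._id_of[p]

    def children(self, node_id: str) -> list[str]:
        return [self._id_of[c] for c in self._node(node_id).child_nodes()]

    def branch_length(self, node_id: str) -> "float | None":
        return self._node(node_id).edge.length

    def subtree_tips(self, node_id: str) -> list[str]:
        node = self._node(node_id)
        if node.is_leaf():
            return [self._id_of[node]]
        return [self._id_of[leaf] for leaf in node.leaf_iter()]

    def preorder(self, node_id: "str | None" = None) -> list[str]:
        start = self._dtree.seed_node if node_id is None else self._node(node_id)
        return [self._id_of[n] for n in start.preorder_iter()]

    def is_ancestor(self, ancestor_id: str, node_id: str) -> bool:
        """True if ``ancestor_id`` lies on the root path of ``node_id`` (or equals it)."""
        anc = self._node(ancestor_id)
        node = self._node(node_id)
        while node is not None:
            if node is anc:
                return True
            node = node.parent_node
        return False

    def mrca(self, tip_names: Iterable[str]) -> str:
        names = list(tip_names)
        if not names:
            raise ValueError("mrca of an empty tip set is undefined")
        for name in names:
            node = self._node(name)
            if not node.is_leaf():
                raise ValueError(f"{name!r} is not a tip")
        if len(names) == 1:
            return names[0]
        mrca = self._dtree.mrca(taxa=[self._node(n).taxon for n in names])
        return self._id_of[mrca]

    def path_to_root(self, node_id: str) -> list[str]:
        out = []
        node = self._node(node_id)
        while node is not None:
            out.append(self._id_of[node])
            node = node.parent_node
        return out

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def _node(self, node_id: str) -> dendropy.Node:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def __len__(self) -> int:
        return len(self._by_id)


def parse_newick(text: str) -> Tree:
    """Parse a rooted newick tree with named tips.

    Branch lengths are preserved when present. Malformed input (unbalanced
    parentheses, duplicate tip names) raises :class:`NewickParseError` with
    the underlying reader message, which includes the offending position.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several reader error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter() if leaf.taxon]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise NewickParseError(f"duplicate tip names: {sorted(dupes)}")
    return Tree(dtree)


def normalize_states(states: Mapping[str, object]) -> dict[str, str]:
    """Normalise tip states to {present, absent, unknown}.

    Accepts 1/0/'?' (the CSV encoding), booleans, and the literal words.
    """
    out: dict[str, str] = {}
    for tip, raw in states.items():
        key = raw.strip().lower() if isinstance(raw, str) else raw
        if key not in _STATE_ALIASES:
            raise ValueError(f"unrecognised state {raw!r} for tip {tip!r}")
        out[tip] = _STATE_ALIASES[key]
    return out


def read_states_csv(path) -> pd.DataFrame:
    """Read a long-format presence/absence table (columns species, locus, state)."""
    df = pd.read_csv(path, dtype=str)
    required = {"species", "locus", "state"}
    if not required.issubset(df.columns):
        raise ValueError(f"states CSV must have columns {sorted(required)}")
    return df


def states_for_locus(df: pd.DataFrame, locus: str) -> dict[str, str]:
    sub = df[df["locus"] == locus]
    if sub.empty:
        raise ValueError(f"no rows for locus {locus!r}")
    return normalize_states(dict(zip(sub["species"], sub["state"])))


@dataclass(frozen=True)
class DolloReconstruction:
    """A single-gain, multiple-loss reconstruction for one locus.

    ``loss_edges`` identifies each loss by the child node of the edge it falls
    on; ``tips_explained`` is False when the proposed gain node is not an
    ancestor of every present tip (so the pattern cannot be explained by this
    gain). ``tied_gain_nodes`` lists all gain placements achieving the minimal
    loss count when produced by :func:`dollo_optimal_gain`.
    """

    gain_node: str
    loss_edges: tuple[str, ...]
    n_losses: int
    tips_explained: bool
    tied_gain_nodes: tuple[str, ...] = ()
    loss_clades: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        """Total event count: the single gain plus every loss."""
        return 1 + self.n_losses


def _validate_states(tree: Tree, states: Mapping[str, str]) -> dict[str, str]:
    states = normalize_states(states)
    tips = set(tree.tip_names())
    unknown_tips = set(states) - tips
    if unknown_tips:
        raise ValueError(f"states reference tips not in the tree: {sorted(unknown_tips)}")
    # Tips without a row are unconstrained.
    full = {t: states.get(t, UNKNOWN) for t in tips}
    if not any(s == PRESENT for s in full.values()):
        raise ValueError("at least one tip must be 'present'")
    return full


def dollo_min_losses(
    tree: Tree, states: Mapping[str, str], gain_node: str
) -> DolloReconstruction:
    """Minimal loss set for a fixed gain node under Dollo parsimony.

    The locus is gained on ``gain_node`` and must be lost on a set of edges
    below it such that every absent tip inside the gain clade sits below
    exactly one loss and no present tip does. Unknown tips impose no
    constraint (a maximal all-unknown subtree needs no loss). If the gain node
    is not an ancestor of every present tip the pattern is unexplainable from
    there and ``tips_explained=False`` is returned rather than an exception.
    """
    full = _validate_states(tree, states)
    tree._node(gain_node)  # raises KeyError for unknown ids

    present = {t for t, s in full.items() if s == PRESENT}
    if not all(tree.is_ancestor(gain_node, t) for t in present):
        return DolloReconstruction(
            gain_node=gain_node, loss_edges=(), n_losses=0, tips_explained=False
        )

    # Postorder flags over the gain clade: does the subtree contain a present
    # (resp. absent) tip?
    has_present: dict[str, bool] = {}
    has_absent: dict[str, bool] = {}
    for nid in reversed(tree.preorder(gain_node)):
        if tree.is_tip(nid):
            has_present[nid] = full[nid] == PRESENT
            has_absent[nid] = full[nid] == ABSENT
        else:
            kids = tree.children(nid)
            has_present[nid] = any(has_present[c] for c in kids)
            has_absent[nid] = any(has_absent[c] for c in kids)

    # A loss goes on the edge above each maximal present-free subtree that
    # contains at least one absent tip.
    losses: list[str] = []
    stack = [gain_node]
    while stack:
        nid = stack.pop()
        for child in tree.children(nid):
            if has_present[child]:
                stack.append(child)
            elif has_absent[child]:
                losses.append(child)
            # all-unknown subtrees retain the locus at no cost

    loss_clades = {c: tuple(tree.subtree_tips(c)) for c in losses}
    return DolloReconstruction(
        gain_node=gain_node,
        loss_edges=tuple(losses),
        n_losses=len(losses),
        tips_explained=True,
        loss_clades=loss_clades,
    )


def dollo_optimal_gain(tree: Tree, states: Mapping[str, str]) -> DolloReconstruction:
    """Most parsimonious gain placement under Dollo parsimony.

    Admissible gain nodes are the ancestors of every present tip: the MRCA of
    the present tips and each node on its path to the root. The reconstruction
    with the fewest losses is returned; ties are broken toward the shallowest
    (most recent) admissible node and all tied placements are reported in
    ``tied_gain_nodes``.
    """
    full = _validate_states(tree, states)
    present = [t for t, s in full.items() if s == PRESENT]
    mrca = tree.mrca(present)

    candidates = tree.path_to_root(mrca)  # shallowest first
    recs = [dollo_min_losses(tree, full, c) for c in candidates]
    best_n = min(r.n_losses for r in recs)
    tied = tuple(r.gain_node for r in recs if r.n_losses == best_n)
    best = next(r for r in recs if r.n_losses == best_n)
    return DolloReconstruction(
        gain_node=best.gain_node,
        loss_edges=best.loss_edges,
        n_losses=best.n_losses,
        tips_explained=True,
        tied_gain_nodes=tied,
        loss_clades=best.loss_clades,
    )
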