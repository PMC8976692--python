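"""Fitch unordered-parsimony ancestral state reconstruction.

Categorical characters (ecotype, variety, geographic origin...) are traced
on a rooted tree: the Fitch downpass yields the minimum number of unordered
state changes; a unit-cost Sankoff pass yields the full MPR sets (the states
each node takes in at least one most-parsimonious reconstruction) and one
deterministic most-parsimonious assignment, from which per-edge transitions
are read off.  An UNKNOWN tip state means "any state", exactly as missing
data is treated in Mesquite-style character tracing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import ValidationError
from .geno_io import UNKNOWN

logger = logging.getLogger(__name__)

_INF = float("inf")


@dataclass
class CharacterData:
    """Tip label → state (or UNKNOWN), over an ordered state alphabet."""

    states: dict[str, str]
    alphabet: list[str]

    def __post_init__(self) -> None:
        if len(self.alphabet) < 2:
            raise ValidationError("alphabet must contain >= 2 states")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValidationError("alphabet states must be unique")
        bad = {s for s in self.states.values() if s != UNKNOWN and s not in self.alphabet}
        if bad:
            raise ValidationError(f"tip states {sorted(bad)} not in alphabet")


@dataclass
class Reconstruction:
    """MPR sets, the Fitch change count, and one arbitrary MP assignment."""

    node_sets: dict  # dendropy.Node -> frozenset of states
    min_changes: int
    assignment: dict  # dendropy.Node -> state (one most-parsimonious labelling)
    tree: dendropy.Tree  # the (possibly polytomy-resolved) working tree


@dataclass(frozen=True)
class Transition:
    """One inferred state change along an edge."""

    child: str  # tip label, or internal node id "node<i>" (preorder index)
    parent_state: str
    child_state: str


def _prepare(tree: dendropy.Tree, chars: CharacterData) -> dendropy.Tree:
    if not tree.is_rooted:
        raise ValidationError("character reconstruction requires a rooted tree")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(chars.states)
    if missing:
        raise ValidationError(f"tips without character state: {sorted(missing)[:5]}")
    if any(len(n.child_nodes()) > 2 for n in tree.preorder_internal_node_iter()):
        logger.info("resolving polytomies arbitrarily with zero-length edges")
        work = tree.clone(depth=1)
        work.resolve_polytomies(update_bipartitions=False)
        return work
    return tree


def _tip_set(label: str, chars: CharacterData) -> frozenset:
    s = chars.states[label]
    return frozenset(chars.alphabet) if s == UNKNOWN else frozenset((s,))


def fitch_count(tree: dendropy.Tree, chars: CharacterData
                ) -> tuple[int, dict]:
    """Fitch downpass: minimum number of unordered changes + per-node sets.

    Polytomies are resolved arbitrarily (zero-length edges) before the pass;
    UNKNOWN tips carry the full alphabet and can never increase the count.
    """
    work = _prepare(tree, chars)
    sets: dict = {}
    count = 0
    for node in work.postorder_node_iter():
        if node.is_leaf():
            sets[node] = _tip_set(node.taxon.label, chars)
            continue
        children = node.child_nodes()
        acc = sets[children[0]]
        for child in children[1:]:
            inter = acc & sets[child]
            if inter:
                acc = inter
            else:
                acc = acc | sets[child]
                count += 1
        sets[node] = acc
    return count, sets


def _sankoff_down(work: dendropy.Tree, chars: CharacterData) -> dict:
    k = len(chars.alphabet)
    index = {s: i for i, s in enumerate(chars.alphabet)}
    down: dict = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            allowed = _tip_set(node.taxon.label, chars)
            cost = np.full(k, _INF)
            for s in allowed:
                cost[index[s]] = 0.0
            down[node] = cost
            continue
        cost = np.zeros(k)
        for child in node.child_nodes():
            c = down[child]
            best_switch = c.min() + 1.0
            cost += np.minimum(c, best_switch)
        down[node] = cost
    return down


def mpr_sets(tree: dendropy.Tree, chars: CharacterData) -> Reconstruction:
    """All most-parsimonious states per node, plus one concrete assignment.

    The MPR set at a node contains every state achieving the global minimum
    change count in at least one reconstruction (computed by unit-cost
    Sankoff down/up passes).  The single assignment is arbitrary but
    deterministic: the parent's state is kept when it is optimal, otherwise
    the first optimal state in alphabet order.
    """
    work = _prepare(tree, chars)
    k = len(chars.alphabet)
    down = _sankoff_down(work, chars)
    root = work.seed_node
    total = float(down[root].min())
    up: dict = {root: np.zeros(k)}
    for node in work.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        child_contrib = []
        for child in children:
            c = down[child]
            child_contrib.append(np.minimum(c, c.min() + 1.0))
        for ci, child in enumerate(children):
            # parent's cost context excluding this child
            other = up[node].copy()
            for cj, contrib in enumerate(child_contrib):
                if cj != ci:
                    other = other + contrib
            # up[child][s] = min_t other[t] + (t != s)
            up[child] = np.minimum(other, other.min() + 1.0)
    node_sets: dict = {}
    for node, d in down.items():
        tot = d + up[node]
        best = tot.min()
        node_sets[node] = frozenset(
            s for i, s in enumerate(chars.alphabet) if tot[i] <= best + 1e-9
        )
    # one deterministic most-parsimonious assignment
    assignment: dict = {}
    for node in work.preorder_node_iter():
        d = down[node]
        if node is root:
            cost = d
            parent_state = None
        else:
            parent_state = assignment[node.parent_node]
            pi = chars.alphabet.index(parent_state)
            cost = d + (np.arange(k) != pi)
        best = cost.min()
        if parent_state is not None and cost[chars.alphabet.index(parent_state)] <= best:
            assignment[node] = parent_state
        else:
            assignment[node] = chars.alphabet[int(np.argmin(cost))]
    return Reconstruction(node_sets, int(round(total)), assignment, work)


def trace_history(tree: dendropy.Tree, chars: CharacterData
                  ) -> tuple[Reconstruction, list[Transition]]:
    """Edges whose parent/child states differ in the chosen MP assignment."""
    rec = mpr_sets(tree, chars)
    names: dict = {}
    for i, node in enumerate(rec.tree.preorder_node_iter()):
        names[node] = node.taxon.label if node.is_leaf() and node.taxon else f"node{i}"
    transitions = []
    for node in rec.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        a, b = rec.assignment[parent], rec.assignment[node]
        if a != b:
            transitions.append(Transition(names[node], a, b))
    return rec, transitions
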