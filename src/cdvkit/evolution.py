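"""Maximum-parsimony ancestral reconstruction of domain presence/absence.

Each character is a binary domain presence state (family-qualified, e.g.
``CdvB:MIM2``) observed at the leaves of a rooted tree. The bottom-up pass
uses Hartigan's generalization of Fitch's method — at each node the state
set is the set of states attained by the maximal number of children, and the
change count grows by (number of children − that maximum). On binary nodes
this is exactly Fitch's intersection/union rule; on polytomies it still
returns the true minimum number of changes, which the naive
intersection-if-nonempty rule does not.

Nodes whose most-parsimonious state set holds both states are reported
``ambiguous`` unless a resolution policy is applied:

* ``none`` — keep ambiguity (no ACCTRAN/DELTRAN-style commitment is made);
* ``dollo_single_gain`` — Dollo parsimony: a single gain at the most recent
  common ancestor of the presence leaves, losses elsewhere;
* ``presence_bias`` — resolve root ambiguity to *present* for characters
  flagged by auxiliary evidence (e.g. domains whose genes co-cluster across
  phyla), the reproducible stand-in for resolving ties with gene-cluster and
  architecture arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .types import PresenceMatrix, RootedTree, TreeNode

__all__ = [
    "AMBIGUOUS",
    "AncestralReconstruction",
    "fitch",
    "fitch_all",
    "resolve_root",
    "map_events",
    "ancestral_architecture",
]

AMBIGUOUS = "ambiguous"
State = int | Literal["ambiguous"]

# Branch label used for a gain placed on the root's (virtual) stem under the
# Dollo policy: presence at the root still represents one origination event.
ORIGIN = "origin"


@dataclass
class AncestralReconstruction:
    tree: RootedTree
    # per character: node label -> 0 | 1 | "ambiguous"
    node_states: dict[str, dict[str, State]]
    parsimony_score: dict[str, int]
    policy: str = "none"

    @property
    def characters(self) -> list[str]:
        return list(self.node_states)

    def state(self, character: str, node: str) -> State:
        return self.node_states[character][node]

    def is_resolved(self, character: Optional[str] = None) -> bool:
        chars = [character] if character else self.characters
        return all(
            s != AMBIGUOUS
            for c in chars
            for s in self.node_states[c].values()
        )


def _hartigan_sets(
    tree: RootedTree, leaf_states: dict[str, int]
) -> tuple[dict[str, frozenset[int]], int]:
    """Bottom-up pass: per-node MP state sets and the parsimony score."""
    sets: dict[str, frozenset[int]] = {}
    score = 0
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in leaf_states:
                raise KeyError(f"leaf {node.label!r} missing from matrix")
            sets[node.label] = frozenset({leaf_states[node.label]})
            continue
        counts = {0: 0, 1: 0}
        for child in node.children:
            for s in sets[child.label]:
                counts[s] += 1
        best = max(counts.values())
        sets[node.label] = frozenset(s for s, c in counts.items() if c == best)
        score += len(node.children) - best
    return sets, score


def fitch(
    tree: RootedTree, matrix: PresenceMatrix, character: str
) -> AncestralReconstruction:
    """Most-parsimonious reconstruction of one binary character.

    Leaves take their observed states; internal nodes get 0, 1 or
    ``ambiguous`` (both states occur in some most-parsimonious labelling of
    that node given the pass). Polytomies are handled exactly.
    """
    leaf_labels = set(tree.leaf_labels())
    if not leaf_labels <= set(matrix.taxa):
        missing = sorted(leaf_labels - set(matrix.taxa))
        raise KeyError(f"leaves missing from matrix: {missing}")
    leaf_states = {t: matrix.state(t, character) for t in matrix.taxa if t in leaf_labels}
    sets, score = _hartigan_sets(tree, leaf_states)
    states: dict[str, State] = {
        label: (next(iter(s)) if len(s) == 1 else AMBIGUOUS)
        for label, s in sets.items()
    }
    return AncestralReconstruction(
        tree=tree,
        node_states={character: states},
        parsimony_score={character: score},
    )


def fitch_all(tree: RootedTree, matrix: PresenceMatrix) -> AncestralReconstruction:
    """Reconstruct every character of the matrix (independent characters)."""
    node_states: dict[str, dict[str, State]] = {}
    scores: dict[str, int] = {}
    for ch in matrix.characters:
        rec = fitch(tree, matrix, ch)
        node_states[ch] = rec.node_states[ch]
        scores[ch] = rec.parsimony_score[ch]
    return AncestralReconstruction(tree, node_states, scores)


def _propagate(
    tree: RootedTree,
    sets: dict[str, frozenset[int]],
    root_state: int,
) -> dict[str, State]:
    """Top-down refinement into one concrete MP labelling.

    A child inherits the parent state whenever its MP set allows it; with
    binary states a set not containing the parent state is necessarily a
    singleton, so the labelling is fully determined by the root choice.
    """
    out: dict[str, State] = {tree.root.label: root_state}
    for parent, child in tree.branches():
        p_state = out[parent.label]
        child_set = sets[child.label]
        out[child.label] = p_state if p_state in child_set else next(iter(child_set))
    return out


def _sets_from_states(
    recon: AncestralReconstruction, character: str
) -> dict[str, frozenset[int]]:
    return {
        label: (frozenset({0, 1}) if s == AMBIGUOUS else frozenset({s}))
        for label, s in recon.node_states[character].items()
    }


def resolve_root(
    recon: AncestralReconstruction,
    policy: str = "none",
    flagged_characters: Iterable[str] = (),
) -> AncestralReconstruction:
    """Apply a root-resolution policy to a reconstruction.

    ``presence_bias`` resolves a *flagged* character's ambiguous root to
    present (1) and propagates one most-parsimonious labelling downward;
    unflagged ambiguous characters resolve to absent. ``dollo_single_gain``
    relabels the whole tree under the single-gain constraint. ``none``
    returns the reconstruction unchanged.
    """
    if policy == "none":
        return recon
    if policy not in ("dollo_single_gain", "presence_bias"):
        raise ValueError(f"unknown policy {policy!r}")
    flagged = set(flagged_characters)
    tree = recon.tree
    node_states: dict[str, dict[str, State]] = {}
    scores = dict(recon.parsimony_score)

    for ch in recon.characters:
        if policy == "presence_bias":
            sets = _sets_from_states(recon, ch)
            root_set = sets[tree.root.label]
            if len(root_set) == 2:
                root_state = 1 if ch in flagged else 0
            else:
                (root_state,) = root_set
            node_states[ch] = _propagate(tree, sets, root_state)
        else:  # dollo_single_gain
            present_leaves = [
                leaf.label
                for leaf in tree.leaves()
                if recon.node_states[ch][leaf.label] == 1
            ]
            states: dict[str, State] = {}
            if not present_leaves:
                states = {n.label: 0 for n in tree.preorder()}
            else:
                lca = _lca(tree, present_leaves)
                below: dict[str, bool] = {}
                for node in tree.postorder():
                    if node.is_leaf:
                        below[node.label] = node.label in present_leaves
                    else:
                        below[node.label] = any(
                            below[c.label] for c in node.children
                        )
                inside = set()
                stack = [lca]
                while stack:
                    n = stack.pop()
                    inside.add(n.label)
                    stack.extend(n.children)
                for node in tree.preorder():
                    if node.label not in inside:
                        states[node.label] = 0
                    else:
                        states[node.label] = 1 if below[node.label] else 0
            node_states[ch] = states
            scores[ch] = sum(
                1
                for parent, child in tree.branches()
                if states[parent.label] != states[child.label]
            ) + (1 if states[tree.root.label] == 1 else 0)
    return AncestralReconstruction(tree, node_states, scores, policy=policy)


def _lca(tree: RootedTree, labels: list[str]) -> TreeNode:
    paths = []
    for label in labels:
        node = tree.node(label)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        paths.append(list(reversed(path)))
    lca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidates = {id(p[depth]) for p in paths}
        if len(candidates) == 1:
            lca = paths[0][depth]
        else:
            break
    return lca


@dataclass(frozen=True)
class Event:
    branch: tuple[str, str]  # (parent, child); parent == ORIGIN for root gains
    character: str
    kind: str  # "gain" | "loss"


def map_events(recon: AncestralReconstruction) -> list[Event]:
    """Read gain/loss events off a fully resolved reconstruction.

    An event sits on branch (u, v) iff state(u) != state(v): 0→1 is a gain,
    1→0 a loss. Under the Dollo policy a character present at the root
    additionally carries its unique gain on the root's origin branch.
    Ambiguous nodes are an error (resolve first).
    """
    bad = [
        (ch, label)
        for ch in recon.characters
        for label, s in recon.node_states[ch].items()
        if s == AMBIGUOUS
    ]
    if bad:
        listing = ", ".join(f"{ch}@{label}" for ch, label in bad[:5])
        raise ValueError(f"ambiguous states remain (e.g. {listing}); apply a policy")
    events: list[Event] = []
    root = recon.tree.root.label
    for ch in recon.characters:
        states = recon.node_states[ch]
        if recon.policy == "dollo_single_gain" and states[root] == 1:
            events.append(Event((ORIGIN, root), ch, "gain"))
        for parent, child in recon.tree.branches():
            u, v = states[parent.label], states[child.label]
            if u != v:
                events.append(
                    Event((parent.label, child.label), ch, "gain" if v == 1 else "loss")
                )
    return events


def ancestral_architecture(
    recon: AncestralReconstruction, node: str
) -> dict[str, set[str]]:
    """Domain content at an internal node, grouped by family qualifier.

    Characters named ``Family:Domain`` group under their family; unqualified
    characters group under ``""``. Requires a resolved reconstruction.
    """
    if node not in {n.label for n in recon.tree.preorder()}:
        raise KeyError(f"unknown node {node!r}")
    out: dict[str, set[str]] = {}
    for ch in recon.characters:
        state = recon.node_states[ch][node]
        if state == AMBIGUOUS:
            raise ValueError(f"character {ch!r} unresolved at {node!r}")
        if state == 1:
            family, _, domain = ch.rpartition(":")
            out.setdefault(family, set()).add(domain)
    return out
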