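"""Duplication labeling and site-residue history on gene trees.

Internal nodes of a gene tree are labeled duplication/speciation by the
species-overlap criterion: a node is a duplication iff the species sets of
its child subtrees intersect. The residue at the Sec-homologous site is
then reconstructed by Fitch parsimony over the residue alphabet, and each
state-changing edge is emitted in the field's event vocabulary:

* ``SC`` — conversion of Sec to Cys (U -> C);
* ``SO`` — conversion of Sec to something other than Cys (U -> r, r not C);
* ``GD`` — gene duplication (from the species-overlap labels);
* ``SUB`` — any residue change whose parent state is not U (outside the
  published vocabulary, kept so that total change events always equal the
  parsimony score).

The root/tie preference (U, then C, then alphabetical) encodes the
inference that the ancestral metazoan SPS gene carried Sec; a flag turns
it off for neutral analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


def _preference_order(prefer_sec: bool) -> list[str]:
    rest = sorted(set("ACDEFGHIKLMNPQRSTVWY") - {"U", "C"})
    if prefer_sec:
        return ["U", "C"] + rest
    return sorted(set("ACDEFGHIKLMNPQRSTVWYU"))


@dataclass(frozen=True)
class EventAnnotation:
    node_id: str  # child node of the edge (or the node itself for GD)
    event: str  # GD | SC | SO | SUB
    from_state: str = ""
    to_state: str = ""


def _node_id(node: dendropy.Node, counter: list[int]) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    return f"node{counter[0]}"


def label_duplications(
    gene_tree: dendropy.Tree,
    species_of: dict[str, str],
    intron_veto: set[str] | frozenset[str] = frozenset(),
) -> dict[str, str]:
    """Species-overlap duplication labels for every internal node.

    Returns node-id -> 'duplication' | 'speciation'. ``intron_veto`` names
    internal nodes whose duplication label is overruled by external
    intron-structure evidence (the evidence itself is supplied, never
    inferred here).
    """
    counter = [0]
    ids: dict[int, str] = {}
    species_sets: dict[int, set[str]] = {}
    labels: dict[str, str] = {}
    for node in gene_tree.postorder_node_iter():
        ids[id(node)] = _node_id(node, counter)
        if node.is_leaf():
            leaf = node.taxon.label
            if leaf not in species_of:
                raise ValueError(f"leaf {leaf!r} has no species mapping")
            species_sets[id(node)] = {species_of[leaf]}
        else:
            child_sets = [species_sets[id(c)] for c in node.child_nodes()]
            overlap = any(
                child_sets[i] & child_sets[j]
                for i in range(len(child_sets))
                for j in range(i + 1, len(child_sets))
            )
            nid = ids[id(node)]
            if overlap and nid in intron_veto:
                overlap = False
            labels[nid] = "duplication" if overlap else "speciation"
            species_sets[id(node)] = set().union(*child_sets)
    return labels


@dataclass
class SiteHistory:
    ancestral_states: dict[str, str]  # node id -> residue
    events: list[EventAnnotation]
    parsimony_score: int


def reconstruct_site_history(
    gene_tree: dendropy.Tree,
    leaf_states: dict[str, str],
    duplication_labels: dict[str, str] | None = None,
    prefer_sec: bool = True,
    external_events: list[EventAnnotation] | None = None,
) -> SiteHistory:
    """Fitch parsimony history of the site residue on a gene tree.

    Leaves with state 'x' (unknown) are treated as missing data and do not
    constrain the reconstruction. Each edge whose parent and child states
    differ emits one event (SC, SO or SUB); GD events are copied from the
    duplication labels when given. ``external_events`` (e.g. GL, GDR, AE
    annotations from retrotransposition or exon evidence the parsimony
    engine cannot see) are appended verbatim.
    """
    pref = _preference_order(prefer_sec)
    alphabet = sorted(
        set(pref) | {s for s in leaf_states.values() if s != "x"}
    )
    informative = [s for s in leaf_states.values() if s != "x"]
    if not informative:
        raise ValueError("all leaves have unknown state 'x'")
    full = set(alphabet)

    counter = [0]
    ids: dict[int, str] = {}
    sets: dict[int, set[str]] = {}
    score = 0
    for node in gene_tree.postorder_node_iter():
        ids[id(node)] = _node_id(node, counter)
        if node.is_leaf():
            state = leaf_states.get(node.taxon.label)
            if state is None:
                raise ValueError(f"leaf {node.taxon.label!r} has no residue state")
            sets[id(node)] = set(full) if state == "x" else {state}
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            votes: dict[str, int] = {}
            for cs in child_sets:
                for s in cs:
                    votes[s] = votes.get(s, 0) + 1
            k = max(votes.values())
            sets[id(node)] = {s for s, v in votes.items() if v == k}
            score += len(child_sets) - k

    rank = {s: i for i, s in enumerate(pref)}
    states: dict[str, str] = {}
    chosen: dict[int, str] = {}
    events: list[EventAnnotation] = []
    for node in gene_tree.preorder_node_iter():
        cand = sets[id(node)]
        if node.parent_node is None:
            state = min(cand, key=lambda s: rank.get(s, len(rank)))
        else:
            parent = chosen[id(node.parent_node)]
            state = (
                parent
                if parent in cand
                else min(cand, key=lambda s: rank.get(s, len(rank)))
            )
            if state != parent:
                if parent == "U" and state == "C":
                    ev = "SC"
                elif parent == "U":
                    ev = "SO"
                else:
                    ev = "SUB"
                events.append(EventAnnotation(ids[id(node)], ev, parent, state))
        chosen[id(node)] = state
        states[ids[id(node)]] = state

    if duplication_labels:
        for nid, lab in duplication_labels.items():
            if lab == "duplication":
                events.append(EventAnnotation(nid, "GD"))
    if external_events:
        events.extend(external_events)
    return SiteHistory(states, events, score)
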