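"""Branch-wise Ka/Ks after gene duplication, by ancestral reconstruction.

The approach is a counting-method pipeline: codon states at internal tree
nodes are reconstructed by parsimony (Fitch/Hartigan over the 61 sense
codons plus the recodable TGA), then the Nei–Gojobori (1986) method is
applied to each (parent, child) branch: synonymous/nonsynonymous site and
difference counts, proportions, and Jukes–Cantor-corrected rates

    Ka = -(3/4) ln(1 - 4 pN / 3),   Ks likewise from pS,

with omega = Ka/Ks per branch. Clade-level contrasts (e.g. SPS1 vs SPS2
after duplication) pool raw counts before taking the ratio.

Mutants creating a stop codon are counted as nonsynonymous when tallying
sites, which preserves N + S = 3 per codon exactly; a flag switches to the
dialect that drops them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median

import dendropy
import numpy as np

from .codons import (
    CODON_STATES,
    HARD_STOPS,
    pathway_differences,
    syn_sites,
)

_STATE_IDX = {c: i for i, c in enumerate(CODON_STATES)}

# top-down tie preference: TGA (Sec) first, then the Cys codons, then
# lexicographic — encoding a Sec-bearing ancestor as the default inference.
_PREFERENCE = ["TGA", "TGC", "TGT"] + [
    c for c in CODON_STATES if c not in ("TGA", "TGC", "TGT")
]
_PREF_RANK = np.empty(len(CODON_STATES), dtype=int)
for rank, codon in enumerate(_PREFERENCE):
    _PREF_RANK[_STATE_IDX[codon]] = rank


class SaturationError(ValueError):
    """pN or pS at/above 3/4: Jukes–Cantor correction undefined."""


@dataclass
class CodonAlignment:
    """An in-frame codon alignment with an optional excluded-column mask."""

    ids: list[str]
    sequences: list[str]
    mask: set[int] = field(default_factory=set)  # codon columns to skip

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError("ragged codon alignment")
        (length,) = lens or {0}
        if length % 3 != 0:
            raise ValueError("alignment length not a multiple of 3")
        for sid, seq in zip(self.ids, self.sequences):
            for col in range(length // 3):
                codon = seq[3 * col : 3 * col + 3]
                if codon in HARD_STOPS:
                    raise ValueError(
                        f"{sid}: internal stop {codon} at codon column {col}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def codons_of(self, sid: str) -> list[str]:
        seq = self.sequences[self.ids.index(sid)]
        return [seq[3 * i : 3 * i + 3] for i in range(self.n_codons)]


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4; saturated")
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class PairwiseKaKs:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float

    @property
    def omega(self) -> float | None:
        return self.Ka / self.Ks if self.Ks > 0 else None


def ng86_pairwise(
    seq_a: str,
    seq_b: str,
    mask: set[int] | frozenset[int] = frozenset(),
    stop_mutants_nonsyn: bool = True,
) -> PairwiseKaKs:
    """Nei–Gojobori counting between two in-frame codon sequences.

    Site counts are averaged over the two sequences; differences average
    over all mutational pathways between differing codons, excluding
    pathways through stops (re-admitted, with stop steps nonsynonymous,
    when all are excluded). Codon columns in ``mask`` are skipped.
    ``stop_mutants_nonsyn`` selects the stop-mutant site dialect.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("length mismatch")
    if len(seq_a) % 3 != 0:
        raise ValueError("length not a multiple of 3")
    N = S = Nd = Sd = 0.0
    for col in range(len(seq_a) // 3):
        if col in mask:
            continue
        ca = seq_a[3 * col : 3 * col + 3]
        cb = seq_b[3 * col : 3 * col + 3]
        sa, na = syn_sites(ca, stop_mutants_nonsyn)
        sb, nb = syn_sites(cb, stop_mutants_nonsyn)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    return PairwiseKaKs(N, S, Nd, Sd, pN, pS, _jc(pN), _jc(pS))


# ---------------------------------------------------------------------------
# ancestral codon reconstruction


@dataclass
class AncestralReconstruction:
    """Codon states at every node of a rooted tree, plus the Fitch score."""

    tree: dendropy.Tree
    states: dict[str, list[str]]  # node id -> codon sequence (list of codons)
    score: int
    node_ids: list[str]


def _node_id(node: dendropy.Node, counter: list[int]) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    return f"node{counter[0]}"


def fitch_ancestral_codons(
    aln: CodonAlignment, tree: dendropy.Tree
) -> AncestralReconstruction:
    """Parsimony reconstruction of codon states at internal nodes.

    Bottom-up Hartigan counting over the 62-codon state space (equivalent
    to Fitch on binary trees, exact on multifurcations); the top-down pass
    keeps the parent state when admissible and otherwise prefers TGA, then
    the Cys codons, then the lexicographically smallest codon. TAA/TAG in
    any column is rejected.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = leaves - set(aln.ids)
    if missing:
        raise ValueError(f"leaves without alignment rows: {sorted(missing)}")

    ncol = aln.n_codons
    nstate = len(CODON_STATES)
    counter = [0]
    ids: dict[int, str] = {}
    pref = _PREF_RANK

    # bottom-up: per node a (ncol, nstate) admissible-state matrix
    admissible: dict[int, np.ndarray] = {}
    score = 0
    for node in tree.postorder_node_iter():
        ids[id(node)] = _node_id(node, counter)
        if node.is_leaf():
            codons = aln.codons_of(node.taxon.label)
            mat = np.zeros((ncol, nstate), dtype=bool)
            for col, codon in enumerate(codons):
                if codon in HARD_STOPS:
                    raise ValueError(
                        f"hard stop {codon} at codon column {col} "
                        f"in leaf {node.taxon.label}"
                    )
                mat[col, _STATE_IDX[codon]] = True
            admissible[id(node)] = mat
        else:
            children = node.child_nodes()
            votes = np.zeros((ncol, nstate), dtype=np.int32)
            for ch in children:
                votes += admissible[id(ch)]
            k = votes.max(axis=1)
            admissible[id(node)] = votes == k[:, None]
            score += int((len(children) - k).sum())

    # top-down assignment
    states: dict[str, list[str]] = {}
    assigned: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        mat = admissible[id(node)]
        if node.parent_node is None:
            # argmin over per-state preference ranks: deterministic since
            # ranks are a permutation of the state indices
            ranks = np.where(mat, pref[None, :], nstate + 1)
            choice = np.argmin(ranks, axis=1)
        else:
            parent_choice = assigned[id(node.parent_node)]
            keep = mat[np.arange(ncol), parent_choice]
            ranks = np.where(mat, pref[None, :], nstate + 1)
            fallback = np.argmin(ranks, axis=1)
            choice = np.where(keep, parent_choice, fallback)
        assigned[id(node)] = choice
        states[ids[id(node)]] = [CODON_STATES[i] for i in choice]

    node_ids = [ids[id(n)] for n in tree.preorder_node_iter()]
    return AncestralReconstruction(tree, states, score, node_ids)


# argmin over _PREF_RANK-masked matrix picks the preferred state because
# np.argmin returns the first minimum and ranks are unique per state.


@dataclass(frozen=True)
class BranchSelection:
    branch_id: str  # child-node id; the branch is (parent(child), child)
    parent_id: str
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float | None
    Ks: float | None
    omega: float | None
    saturated: bool = False


def branch_ka_ks(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    ancestors: AncestralReconstruction | None = None,
    mask: set[int] | None = None,
) -> list[BranchSelection]:
    """NG86 applied to every (parent, child) branch of the tree.

    ``mask`` defaults to the alignment's excluded columns (typically the
    Sec-site column). Saturated branches are reported, not fatal.
    """
    if ancestors is None:
        ancestors = fitch_ancestral_codons(aln, tree)
    mask = aln.mask if mask is None else mask
    counter = [0]
    out = []
    idmap: dict[int, str] = {}
    # postorder numbering matches the id assignment used during reconstruction
    for node in tree.postorder_node_iter():
        idmap[id(node)] = _node_id(node, counter)
    known = set(ancestors.states)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        cid = idmap[id(node)]
        pid = idmap[id(node.parent_node)]
        if cid not in known or pid not in known:
            raise ValueError("tree/ancestor node id mismatch")
        child_seq = "".join(ancestors.states[cid])
        parent_seq = "".join(ancestors.states[pid])
        try:
            pw = ng86_pairwise(parent_seq, child_seq, frozenset(mask))
            out.append(
                BranchSelection(
                    cid, pid, pw.N, pw.S, pw.Nd, pw.Sd, pw.pN, pw.pS,
                    pw.Ka, pw.Ks, pw.omega,
                )
            )
        except SaturationError:
            out.append(
                BranchSelection(
                    cid, pid, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                    None, None, None, saturated=True,
                )
            )
    return out


def aggregate_omega(
    branch_results: list[BranchSelection],
    clade_assignment: dict[str, str],
) -> dict[str, dict]:
    """Per-clade Ka/Ks summaries (e.g. SPS1 vs SPS2 vs pre-duplication).

    The pooled estimator sums raw counts across branches before forming
    proportions, then applies the Jukes–Cantor correction, making it robust
    to branches with few substitutions.
    """
    unassigned = [b.branch_id for b in branch_results if b.branch_id not in clade_assignment]
    if unassigned:
        raise ValueError(f"branches without clade assignment: {unassigned}")
    groups: dict[str, list[BranchSelection]] = {}
    for b in branch_results:
        groups.setdefault(clade_assignment[b.branch_id], []).append(b)
    out: dict[str, dict] = {}
    for name, branches in groups.items():
        if not branches:
            raise ValueError(f"empty clade group {name!r}")
        omegas = [b.omega for b in branches if b.omega is not None]
        N = sum(b.N for b in branches)
        S = sum(b.S for b in branches)
        Nd = sum(b.Nd for b in branches)
        Sd = sum(b.Sd for b in branches)
        pN = Nd / N if N > 0 else 0.0
        pS = Sd / S if S > 0 else 0.0
        try:
            ka, ks = _jc(pN), _jc(pS)
            pooled = ka / ks if ks > 0 else None
        except SaturationError:
            pooled = None
        out[name] = {
            "n_branches": len(branches),
            "mean_omega": sum(omegas) / len(omegas) if omegas else None,
            "median_omega": median(omegas) if omegas else None,
            "pooled_omega": pooled,
            "Nd": Nd,
            "Sd": Sd,
            "N": N,
            "S": S,
        }
    return out
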