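"""NG86 counting, parsimony ancestors and branch Ka/Ks against oracles."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from spsevol.codons import SENSE_CODONS, STOP_CODONS, pathway_differences, syn_sites
from spsevol.io import tree_from_string
from spsevol.selection import (
    CodonAlignment,
    SaturationError,
    aggregate_omega,
    branch_ka_ks,
    fitch_ancestral_codons,
    ng86_pairwise,
)
from spsevol.simulate import simulate_codon_evolution


def _aa(codon: str) -> str:
    """Independent genetic-code lookup through Biopython."""
    return str(Seq(codon).translate())


class TestSiteCounts:
    def test_ttt_site_counts(self):
        # of the 9 single-nt mutants of TTT (Phe), only TTC is synonymous
        s, n = syn_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_site_counts_sum_to_three_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            s, n = syn_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            assert s >= 0 and n >= 0

    def test_site_counts_match_independent_enumeration(self):
        # oracle: count synonymous mutants with Biopython's translator
        for codon in SENSE_CODONS[::5]:
            expected = 0.0
            for pos in range(3):
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    mut = codon[:pos] + nt + codon[pos + 1 :]
                    if mut not in STOP_CODONS and _aa(mut) == _aa(codon):
                        expected += 1 / 3
            assert syn_sites(codon)[0] == pytest.approx(expected)


class TestPathwayDifferences:
    @pytest.mark.parametrize(
        "a,b,sd,nd",
        [
            ("TTT", "TTC", 1.0, 0.0),  # Phe->Phe
            ("TTT", "TTA", 0.0, 1.0),  # Phe->Leu
            ("TTT", "CTC", 1.0, 1.0),  # both orders: one syn + one nonsyn
            ("AAA", "AAA", 0.0, 0.0),
        ],
    )
    def test_known_codon_pairs(self, a, b, sd, nd):
        assert pathway_differences(a, b) == pytest.approx((sd, nd))

    def test_differences_sum_to_hamming_distance(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = rng.choice(SENSE_CODONS, size=2)
            d = sum(x != y for x, y in zip(a, b))
            sd, nd = pathway_differences(a, b)
            assert sd + nd == pytest.approx(d)

    def test_ng86_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = "".join(rng.choice(SENSE_CODONS, size=30))
            b = "".join(rng.choice(SENSE_CODONS, size=30))
            try:
                ab, ba = ng86_pairwise(a, b), ng86_pairwise(b, a)
            except SaturationError:
                continue
            assert ab.Nd == pytest.approx(ba.Nd)
            assert ab.Sd == pytest.approx(ba.Sd)
            assert ab.N == pytest.approx(ba.N)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            ng86_pairwise("AAA" * 50, "CCC" * 50)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            ng86_pairwise("AAA", "AAAAAA")


def _exhaustive_fitch_score(tree, leaf_states: dict[str, str]) -> int:
    """Brute force: minimize changes over all internal labelings drawn
    from the states observed at the leaves."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    observed = sorted(set(leaf_states.values()))
    idx = {id(n): i for i, n in enumerate(nodes)}
    edges = [
        (idx[id(n.parent_node)], idx[id(n)]) for n in nodes if n.parent_node is not None
    ]
    best = None
    for combo in itertools.product(observed, repeat=len(internal)):
        assign = {}
        for n in nodes:
            if n.is_leaf():
                assign[idx[id(n)]] = leaf_states[n.taxon.label]
        for n, s in zip(internal, combo):
            assign[idx[id(n)]] = s
        changes = sum(assign[p] != assign[c] for p, c in edges)
        best = changes if best is None else min(best, changes)
    return best


def _random_topology(rng, leaves):
    parts = list(leaves)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return parts[0] + ";"


class TestFitchAncestors:
    def test_identical_leaves_score_zero(self):
        tree = tree_from_string("((A,B),(C,D));")
        aln = CodonAlignment(list("ABCD"), ["ATGAAA"] * 4)
        rec = fitch_ancestral_codons(aln, tree)
        assert rec.score == 0
        assert all(s == ["ATG", "AAA"] for s in rec.states.values())

    def test_sec_site_example(self):
        # one Cys leaf among Sec leaves: root reconstructs TGA, one change
        tree = tree_from_string("((A,B),(C,D));")
        aln = CodonAlignment(list("ABCD"), ["TGA", "TGA", "TGC", "TGA"])
        rec = fitch_ancestral_codons(aln, tree)
        assert rec.score == 1
        root_id = [k for k in rec.states if k.startswith("node")][-1]
        assert rec.states[root_id] == ["TGA"]
        assert rec.states["C"] == ["TGC"]

    def test_score_matches_exhaustive_minimum_on_small_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n_leaves = int(rng.integers(4, 7))
            leaves = [f"L{i}" for i in range(n_leaves)]
            tree = tree_from_string(_random_topology(rng, leaves))
            pool = list(rng.choice(SENSE_CODONS, size=4))
            n_cod = 5
            seqs = [
                "".join(pool[int(k)] for k in rng.integers(0, len(pool), n_cod))
                for _ in leaves
            ]
            aln = CodonAlignment(leaves, seqs)
            rec = fitch_ancestral_codons(aln, tree)
            expected = sum(
                _exhaustive_fitch_score(
                    tree, {l: s[3 * c : 3 * c + 3] for l, s in zip(leaves, seqs)}
                )
                for c in range(n_cod)
            )
            assert rec.score == expected

    def test_unknown_leaf_raises(self):
        tree = tree_from_string("((A,B),(C,E));")
        aln = CodonAlignment(list("ABCD"), ["TGA"] * 4)
        with pytest.raises(ValueError, match="without alignment"):
            fitch_ancestral_codons(aln, tree)

    def test_hard_stop_in_alignment_raises(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(["A", "B"], ["TAA", "TGC"])


class TestBranchKaKs:
    def test_identical_sequences_give_zero_rates(self):
        tree = tree_from_string("(A,B);")
        aln = CodonAlignment(["A", "B"], ["ATGAAATTT"] * 2)
        for b in branch_ka_ks(aln, tree):
            assert b.Ka == 0.0 and b.Ks == 0.0 and b.omega is None

    def test_neutral_simulation_recovers_omega_one(self):
        tree = tree_from_string("(A:0.4,B:0.4);")
        aln, _ = simulate_codon_evolution(tree, 1.0, kappa=1.0, n_codons=2000, seed=7)
        branches = branch_ka_ks(aln, tree, fitch_ancestral_codons(aln, tree))
        agg = aggregate_omega(branches, {b.branch_id: "all" for b in branches})
        assert 0.85 <= agg["all"]["pooled_omega"] <= 1.15

    def test_sec_column_mask_is_respected(self):
        tree = tree_from_string("(A,B);")
        aln = CodonAlignment(["A", "B"], ["TGAAAA", "TGCAAA"], mask={0})
        for b in branch_ka_ks(aln, tree):
            assert b.Nd == 0.0 and b.Sd == 0.0
            assert b.N + b.S == pytest.approx(3.0)  # only the unmasked codon


class TestAggregateOmega:
    def test_single_group_mean_equals_branch_mean(self):
        tree = tree_from_string("(A:0.3,B:0.3);")
        aln, _ = simulate_codon_evolution(tree, 0.5, kappa=2.0, n_codons=500, seed=9)
        branches = branch_ka_ks(aln, tree, fitch_ancestral_codons(aln, tree))
        agg = aggregate_omega(branches, {b.branch_id: "g" for b in branches})
        omegas = [b.omega for b in branches if b.omega is not None]
        assert agg["g"]["mean_omega"] == pytest.approx(sum(omegas) / len(omegas))
        assert agg["g"]["n_branches"] == len(branches)

    def test_unassigned_branch_raises(self):
        tree = tree_from_string("(A:0.3,B:0.3);")
        aln, _ = simulate_codon_evolution(tree, 0.5, kappa=2.0, n_codons=100, seed=9)
        branches = branch_ka_ks(aln, tree, fitch_ancestral_codons(aln, tree))
        with pytest.raises(ValueError, match="without clade"):
            aggregate_omega(branches, {})


class TestStopMutantDialect:
    def test_alternative_dialect_drops_stop_mutants_from_sites(self):
        # TGG (Trp) has two stop-reachable mutants (TAG, TGA)
        s_default, n_default = syn_sites("TGG", True)
        s_alt, n_alt = syn_sites("TGG", False)
        assert s_default + n_default == pytest.approx(3.0)
        assert s_alt + n_alt == pytest.approx(3.0 - 2 / 3)
        pw = ng86_pairwise("TGGCTTCTC", "TGGCTGCTC", stop_mutants_nonsyn=False)
        assert pw.N + pw.S < 9.0
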