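"""Planted-truth recovery experiments.

Every generator in :mod:`spsevol.simulate` records its ground truth; the
functions here run the corresponding analysis stage on freshly generated
data and measure how much of the truth is recovered. They power both the
validation test suite and ``scripts/acceptance.py``.

Problem sizes default to desk scale: 16-leaf trees with 400 codons for
selection analysis, 60 genomes for classification, 50-100 replicates for
the scanners — large enough for stable rates, small enough to run in
seconds to minutes on one core.
"""

from __future__ import annotations

import numpy as np

from .fusions import cluster_extensions, scan_gene_for_fusion
from .history import label_duplications  # noqa: F401  (re-export convenience)
from .io import tree_from_string
from .profiles import (
    Profile,
    align_to_profile,
    call_site_residue,
    classify_genome,
    classify_sps,
    load_packaged_profile,
)
from .selection import aggregate_omega, branch_ka_ks, fitch_ancestral_codons
from .simulate import (
    PlantSpec,
    apply_noise,
    generate_marker_panel,
    generate_recoding_window,
    generate_sps_gene,
    label_tree_nodes,
    simulate_codon_evolution,
)
from .structure import classify_recoding_element, fold_window, scan_hexamer
from .traits import call_traits, summarize_panel


def balanced_tree_newick(n_leaves: int, branch_length: float, prefix: str = "L") -> str:
    """Newick for a balanced binary tree with uniform branch lengths."""

    def rec(labels: list[str]) -> str:
        if len(labels) == 1:
            return f"{labels[0]}:{branch_length}"
        h = len(labels) // 2
        return f"({rec(labels[:h])},{rec(labels[h:])}):{branch_length}"

    labs = [f"{prefix}{i}" for i in range(n_leaves)]
    h = n_leaves // 2
    return f"({rec(labs[:h])},{rec(labs[h:])});"


# ---------------------------------------------------------------------------
# selection analysis


def omega_recovery(
    omegas: tuple[float, ...] = (0.15, 0.5, 1.0),
    kappa: float = 2.0,
    n_codons: int = 400,
    n_leaves: int = 16,
    n_replicates: int = 10,
    branch_length: float = 0.2,
    seed: int = 0,
) -> dict[float, float]:
    """Median relative error of clade-pooled omega, per true omega."""
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    for omega in omegas:
        errs = []
        for _ in range(n_replicates):
            tree = tree_from_string(balanced_tree_newick(n_leaves, branch_length))
            aln, _ = simulate_codon_evolution(
                tree, omega, kappa, n_codons, rng.integers(2**31)
            )
            branches = branch_ka_ks(aln, tree, fitch_ancestral_codons(aln, tree))
            agg = aggregate_omega(branches, {b.branch_id: "all" for b in branches})
            est = agg["all"]["pooled_omega"]
            errs.append(abs(est - omega) / omega)
        out[omega] = float(np.median(errs))
    return out


def omega_contrast(
    omega_sps1: float = 0.15,
    omega_sps2: float = 0.6,
    omega_pre: float = 0.15,
    kappa: float = 2.0,
    n_codons: int = 400,
    n_replicates: int = 10,
    branch_length: float = 0.2,
    seed: int = 0,
) -> dict:
    """Post-duplication selection contrast on a duplication tree.

    Two 8-leaf paralog clades (SPS1 under strong purifying selection,
    SPS2 relaxed) plus a 4-leaf unduplicated outgroup; reports how often
    pooled omega orders SPS2 > SPS1 across replicates.
    """
    rng = np.random.default_rng(seed)

    def clade(prefix: str, n: int) -> str:
        def rec(labels: list[str]) -> str:
            if len(labels) == 1:
                return f"{labels[0]}:{branch_length}"
            h = len(labels) // 2
            return f"({rec(labels[:h])},{rec(labels[h:])}):{branch_length}"

        return rec([f"{prefix}{i}" for i in range(n)])

    nwk = (
        f"(({clade('sps1_', 8)},{clade('sps2_', 8)}):{branch_length},"
        f"{clade('out_', 4)});"
    )
    results = []
    n_ordered = 0
    for _ in range(n_replicates):
        tree = tree_from_string(nwk)
        label_tree_nodes(tree)
        assign: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            key = node.taxon.label if node.taxon else node.label
            leaves = {l.taxon.label.split("_")[0] for l in node.leaf_iter()}
            if leaves == {"sps1"}:
                assign[key] = "SPS1"
            elif leaves == {"sps2"}:
                assign[key] = "SPS2"
            else:
                assign[key] = "pre-duplication"
        omega_map = {
            k: {"SPS1": omega_sps1, "SPS2": omega_sps2, "pre-duplication": omega_pre}[v]
            for k, v in assign.items()
        }
        aln, _ = simulate_codon_evolution(
            tree, omega_map, kappa, n_codons, rng.integers(2**31)
        )
        branches = branch_ka_ks(aln, tree, fitch_ancestral_codons(aln, tree))
        agg = aggregate_omega(branches, assign)
        w1 = agg["SPS1"]["pooled_omega"]
        w2 = agg["SPS2"]["pooled_omega"]
        results.append({"SPS1": w1, "SPS2": w2,
                        "pre": agg["pre-duplication"]["pooled_omega"]})
        n_ordered += w2 > w1
    return {
        "replicates": results,
        "n_ordered": n_ordered,
        "n_replicates": n_replicates,
        "mean_sps1": float(np.mean([r["SPS1"] for r in results])),
        "mean_sps2": float(np.mean([r["SPS2"] for r in results])),
        "mean_pre": float(np.mean([r["pre"] for r in results])),
    }


# ---------------------------------------------------------------------------
# site classification

ALL_CLASS_SPECS = (
    PlantSpec("U", secis_flag=True),
    PlantSpec("U", secis_flag=False),
    PlantSpec("C"),
    PlantSpec("T"),
    PlantSpec("G"),
    PlantSpec("L"),
    PlantSpec("R"),
)


def classification_recovery(
    n_genomes: int = 60,
    noise: float = 0.0,
    seed: int = 0,
    profile: Profile | None = None,
) -> dict:
    """Planted-class recovery over genomes covering every SPS class.

    Each synthetic genome carries one planted gene; specs cycle through
    all classes. Noise is iid amino-acid substitution outside the site.
    Returns gene-class and genome-capability agreement fractions.
    """
    profile = profile or load_packaged_profile()
    rng = np.random.default_rng(seed)
    gene_ok = cap_ok = 0
    for i in range(n_genomes):
        spec = ALL_CLASS_SPECS[i % len(ALL_CLASS_SPECS)]
        gene = generate_sps_gene(
            profile, spec, rng.integers(2**31), gene_id=f"g{i}"
        )
        protein = (
            apply_noise(gene, noise, rng.integers(2**31)) if noise > 0 else gene.protein
        )
        aln = align_to_profile(protein, profile)
        site = call_site_residue(aln, profile, gene.gene_id)
        got = classify_sps(site, gene.secis_flag)
        expected = spec.expected_class()
        gene_ok += got == expected
        truly_capable = expected in ("SPS2-Sec", "SPS2-Cys")
        cap = classify_genome([got], selenoproteome_size=1 if truly_capable else 0)
        cap_ok += cap.sec_capable == truly_capable
    return {
        "n": n_genomes,
        "gene_class_agreement": gene_ok / n_genomes,
        "genome_capability_agreement": cap_ok / n_genomes,
    }


# ---------------------------------------------------------------------------
# readthrough signals


def hexamer_recovery(
    n_cases: int = 50, seed: int = 0, profile: Profile | None = None
) -> dict:
    """Hexamer scan on planted motifs and motif-free controls."""
    profile = profile or load_packaged_profile()
    rng = np.random.default_rng(seed)
    found = 0
    false_pos = 0
    n_controls = 0
    for i in range(n_cases):
        gene = generate_sps_gene(
            profile, PlantSpec("U", hexamer=True), rng.integers(2**31)
        )
        hits = scan_hexamer(gene.cds, gene.site_codon * 3, gene.gene_id)
        found += bool(hits and hits[0].adjacent)
    while n_controls < n_cases:
        gene = generate_sps_gene(
            profile, PlantSpec("U", hexamer=False), rng.integers(2**31)
        )
        # a motif-free control: skip the rare draw that lands the motif by chance
        window = gene.cds[gene.site_codon * 3 + 3 : gene.site_codon * 3 + 3 + 14]
        if "GGGTGC" in window or "GGGTGT" in window:
            continue
        n_controls += 1
        false_pos += bool(scan_hexamer(gene.cds, gene.site_codon * 3, gene.gene_id))
    return {
        "n": n_cases,
        "recall": found / n_cases,
        "false_positives": false_pos,
    }


def structure_recovery(n_cases: int = 100, seed: int = 0) -> dict:
    """Classification accuracy on planted SRE / HRE / empty windows."""
    rng = np.random.default_rng(seed)
    correct = {"SRE": 0, "HRE": 0, "none": 0}
    each = n_cases // 2
    for kind in ("SRE", "HRE"):
        for _ in range(each):
            window, uga = generate_recoding_window(kind, rng.integers(2**31))
            pred = fold_window(window, uga_index=uga)
            got = classify_recoding_element(pred, uga_index=uga)
            correct[kind] += got == kind
    for _ in range(each):
        window, uga = generate_recoding_window("none", rng.integers(2**31))
        pred = fold_window(window, uga_index=uga)
        correct["none"] += classify_recoding_element(pred, uga_index=uga) == "none"
    return {
        "n_per_kind": each,
        "sre_accuracy": correct["SRE"] / each,
        "hre_accuracy": correct["HRE"] / each,
        "control_accuracy": correct["none"] / each,
        "planted_accuracy": (correct["SRE"] + correct["HRE"]) / (2 * each),
    }


# ---------------------------------------------------------------------------
# fusions


def fusion_recovery(
    n_replicates: int = 50,
    fusion_len: int = 150,
    tolerance: int = 10,
    seed: int = 0,
    profile: Profile | None = None,
) -> dict:
    """Boundary accuracy for planted N-terminal fusions."""
    profile = profile or load_packaged_profile()
    rng = np.random.default_rng(seed)
    within = detected = 0
    for i in range(n_replicates):
        gene = generate_sps_gene(
            profile,
            PlantSpec("U", fusion_side="N", fusion_len=fusion_len),
            rng.integers(2**31),
            gene_id=f"fus{i}",
        )
        reports = scan_gene_for_fusion(gene.contig, gene.annotation, profile)
        n_side = [r for r in reports if r.side == "N"]
        if n_side:
            detected += 1
            within += abs(n_side[0].extension_len - fusion_len) <= tolerance
    return {
        "n": n_replicates,
        "detected": detected / n_replicates,
        "boundary_within_tolerance": within / n_replicates,
    }


def _mutate_protein(domain: str, rate: float, rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(
        aas[int(rng.integers(20))] if rng.random() < rate else a for a in domain
    )


def fusion_cluster_recovery(
    sizes: tuple[int, int] = (5, 3),
    fusion_len: int = 150,
    seed: int = 0,
    profile: Profile | None = None,
) -> dict:
    """Two planted domain families must come back as exactly two clusters."""
    profile = profile or load_packaged_profile()
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    families = [
        "".join(aas[int(rng.integers(20))] for _ in range(fusion_len))
        for _ in sizes
    ]
    reports = []
    g = 0
    for fam, size in zip(families, sizes):
        for _ in range(size):
            domain = _mutate_protein(fam, 0.10, rng)
            gene = generate_sps_gene(
                profile,
                PlantSpec("U", fusion_side="N", fusion_len=fusion_len),
                rng.integers(2**31),
                gene_id=f"fam{g:02d}",
                fusion_domain=domain,
            )
            g += 1
            reports.extend(scan_gene_for_fusion(gene.contig, gene.annotation, profile))
    clustered = cluster_extensions(reports)
    cluster_sizes = {}
    for r in clustered:
        cluster_sizes[r.cluster_id] = cluster_sizes.get(r.cluster_id, 0) + 1
    return {
        "n_reports": len(clustered),
        "n_clusters": len(cluster_sizes),
        "cluster_sizes": sorted(cluster_sizes.values(), reverse=True),
    }


# ---------------------------------------------------------------------------
# marker panels


def panel_recovery(n_seeds: int = 20, n_genomes: int = 223, seed: int = 0) -> dict:
    """Exact recovery of planted trait frequencies and labels over seeds."""
    rng = np.random.default_rng(seed)
    label_errors = 0
    summaries = []
    for _ in range(n_seeds):
        matrix, truth = generate_marker_panel(
            n_genomes=n_genomes, seed=rng.integers(2**31)
        )
        calls = call_traits(matrix)
        for c in calls:
            expected = truth[c.genome_id]
            got = (
                "both" if c.sec and c.seu
                else "sec" if c.sec
                else "seu" if c.seu
                else "orphan" if c.orphan_selD
                else "none"
            )
            label_errors += got != expected
        summaries.append(summarize_panel(calls, matrix))
    keys = summaries[0].keys()
    mean = {k: float(np.mean([s[k] for s in summaries])) for k in keys}
    spread = {k: float(np.ptp([s[k] for s in summaries])) for k in keys}
    return {
        "n_seeds": n_seeds,
        "label_errors": label_errors,
        "mean_summary": mean,
        "max_spread": max(v for k, v in spread.items() if k != "n"),
    }
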