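"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* codon alignments evolved on a tree under per-branch omega (Ka/Ks) and a
  transition:transversion ratio kappa, with a complete event log;
* genomes carrying planted SPS genes: controlled residue at the
  Sec-homologous site, optional SECIS annotation, readthrough hexamer,
  stem-loop around the UGA, and N-/C-terminal fusion domains bounded by
  in-frame stops;
* genome x marker panels with controlled Sec/SeU trait overlap.

Defaults encode the study conditions of the prokaryotic survey this
package models: 223 genomes, Sec trait 18%, SeU trait 16%, both 10%,
orphan SelD 2%, Sec-residue SelD 19% of carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .codons import (
    GENETIC_CODE,
    NUCS,
    SENSE_CODONS,
    STOP_CODONS,
    synonymous,
    translate_cds,
)
from .io import GeneAnnotation, GenomeRecord
from .profiles import Profile
from .selection import CodonAlignment

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _codon not in STOP_CODONS:
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()
_AA_TO_CODONS["U"] = ["TGA"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# codon evolution on a tree


@dataclass(frozen=True)
class SimEvent:
    branch: str
    codon_col: int
    from_codon: str
    to_codon: str
    synonymous: bool


@dataclass
class SimTruth:
    root_sequence: str
    events: list[SimEvent]
    omega_by_branch: dict[str, float]
    node_sequences: dict[str, str] = field(default_factory=dict)


def label_tree_nodes(tree: dendropy.Tree) -> dendropy.Tree:
    """Give unlabeled internal nodes stable postorder labels n1, n2, ..."""
    counter = 0
    for node in tree.postorder_node_iter():
        if node.taxon is None and not node.label:
            counter += 1
            node.label = f"n{counter}"
    return tree


def _branch_key(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def simulate_codon_evolution(
    tree: dendropy.Tree,
    omega_by_branch: dict[str, float] | float,
    kappa: float,
    n_codons: int,
    seed,
) -> tuple[CodonAlignment, SimTruth]:
    """Evolve a codon sequence along a rooted tree.

    Branch lengths are expected candidate point-mutation events per codon
    (pre-acceptance). Candidates arise with transition:transversion ratio
    kappa and are accepted with probability 1 if synonymous, omega if
    nonsynonymous, 0 if they create a stop. ``omega_by_branch`` maps the
    child-node label of each branch to its omega (or is a single float).
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    rng = _rng(seed)
    label_tree_nodes(tree)
    branch_keys = [
        _branch_key(n) for n in tree.preorder_node_iter() if n.parent_node is not None
    ]
    if isinstance(omega_by_branch, (int, float)):
        omega_by_branch = {k: float(omega_by_branch) for k in branch_keys}
    for key in branch_keys:
        if key not in omega_by_branch:
            raise ValueError(f"branch {key!r} has no omega entry")
        if omega_by_branch[key] < 0:
            raise ValueError(f"omega < 0 on branch {key!r}")

    root_codons = list(rng.choice(SENSE_CODONS, size=n_codons))
    truth = SimTruth("".join(root_codons), [], dict(omega_by_branch))
    seqs: dict[int, list[str]] = {id(tree.seed_node): root_codons}
    truth.node_sequences[_branch_key(tree.seed_node)] = "".join(root_codons)

    p_transition = kappa / (kappa + 2.0)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        key = _branch_key(node)
        omega = omega_by_branch[key]
        t = node.edge.length or 0.0
        codons = list(seqs[id(node.parent_node)])
        n_events = rng.poisson(t * n_codons) if t > 0 else 0
        for _ in range(n_events):
            col = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            old = codons[col]
            ref = old[pos]
            mutant_nt = _draw_mutant(ref, p_transition, rng)
            new = old[:pos] + mutant_nt + old[pos + 1 :]
            if new in STOP_CODONS:
                continue
            syn = synonymous(old, new)
            if syn or rng.random() < omega:
                codons[col] = new
                truth.events.append(SimEvent(key, col, old, new, syn))
        seqs[id(node)] = codons
        truth.node_sequences[key] = "".join(codons)

    ids = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    aligned = [truth.node_sequences[i] for i in ids]
    return CodonAlignment(ids, aligned), truth


_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_mutant(ref: str, p_transition: float, rng: np.random.Generator) -> str:
    if rng.random() < p_transition:
        return _TRANSITION_OF[ref]
    tv = [n for n in NUCS if n != ref and n != _TRANSITION_OF[ref]]
    return tv[int(rng.integers(2))]


def replay_events(truth: SimTruth, tree: dendropy.Tree) -> dict[str, str]:
    """Re-apply the event log from the root; returns leaf sequences."""
    per_branch: dict[str, list[SimEvent]] = {}
    for ev in truth.events:
        per_branch.setdefault(ev.branch, []).append(ev)
    out: dict[str, str] = {}
    seqs = {id(tree.seed_node): truth.root_sequence}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        codons = [
            seqs[id(node.parent_node)][i : i + 3]
            for i in range(0, len(truth.root_sequence), 3)
        ]
        for ev in per_branch.get(_branch_key(node), []):
            if codons[ev.codon_col] != ev.from_codon:
                raise ValueError("event log does not replay cleanly")
            codons[ev.codon_col] = ev.to_codon
        seqs[id(node)] = "".join(codons)
        if node.is_leaf():
            out[node.taxon.label] = seqs[id(node)]
    return out


# ---------------------------------------------------------------------------
# planted SPS genes


@dataclass(frozen=True)
class PlantSpec:
    """What to plant in a synthetic SPS gene."""

    site_residue: str = "U"  # one of U C T G L R
    secis_flag: bool = False
    hexamer: bool = False
    hairpin: bool = False
    fusion_side: str = "none"  # none | N | C
    fusion_len: int = 0

    def __post_init__(self) -> None:
        if self.site_residue not in "UCTGLR":
            raise ValueError(f"unsupported site residue {self.site_residue!r}")
        if self.fusion_len < 0:
            raise ValueError("fusion_len must be >= 0")
        if self.fusion_side not in ("none", "N", "C"):
            raise ValueError(f"bad fusion_side {self.fusion_side!r}")
        if (self.hexamer or self.hairpin) and self.site_residue != "U":
            raise ValueError("hexamer/hairpin require site_residue 'U'")

    def expected_class(self) -> str:
        if self.site_residue == "U":
            return "SPS2-Sec" if self.secis_flag else "SPS1-UGA"
        if self.site_residue == "C":
            return "SPS2-Cys"
        return f"SPS1-{self.site_residue}"


@dataclass
class GeneModel:
    """A planted gene located on its synthetic contig."""

    gene_id: str
    contig: GenomeRecord
    annotation: GeneAnnotation
    cds: str  # core CDS, coding strand, no stop codon
    protein: str
    site_codon: int  # codon index of the Sec-homologous site within cds
    secis_flag: bool
    spec: PlantSpec


def _reverse_translate(protein: str, rng: np.random.Generator) -> list[str]:
    return [
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
        for aa in protein
    ]


def _gc_arm(length: int, rng: np.random.Generator) -> str:
    """Random G/C string with no homopolymer run of 3 (limits off-target
    stacking against the flanking sequence)."""
    out: list[str] = []
    while len(out) < length:
        c = "G" if rng.random() < 0.5 else "C"
        if len(out) >= 2 and out[-1] == out[-2] == c:
            c = "G" if c == "C" else "C"
        out.append(c)
    return "".join(out)


def _random_codons(n: int, rng: np.random.Generator) -> list[str]:
    return list(rng.choice(SENSE_CODONS, size=n)) if n else []


def generate_sps_gene(
    profile: Profile,
    spec: PlantSpec,
    seed,
    gene_id: str = "sps1",
    contig_id: str | None = None,
    strand: str = "+",
    flank_codons: int = 30,
    fusion_domain: str | None = None,
) -> GeneModel:
    """Emit a synthetic SPS gene embedded in genomic context.

    The CDS translates to the profile consensus with the requested residue
    at the Sec column. Optional plants: the GGG-TG[C/T] hexamer
    immediately after the TGA; a >=8 bp complementary stem within +/-30 nt
    of the TGA; a terminal fusion domain in frame with no intervening
    stop. The annotated interval covers the core gene only, bounded by
    in-frame stops so ORF extension has defined truth.
    """
    rng = _rng(seed)
    consensus = profile.consensus()
    site = profile.sec_column
    protein = consensus[:site] + spec.site_residue + consensus[site + 1 :]
    codons = _reverse_translate(protein, rng)

    if spec.hexamer:
        codons[site + 1] = "GGG"
        codons[site + 2] = "TGC" if rng.random() < 0.5 else "TGT"
    if spec.hairpin:
        arm = _gc_arm(9, rng)  # 9 bp stem; G/C only, so never a stop codon
        right_at = site + 3 if spec.hexamer else site + 2
        for k in range(3):
            codons[site - 4 + k] = arm[3 * k : 3 * k + 3]
            codons[right_at + k] = revcomp(arm)[3 * k : 3 * k + 3]

    core = "".join(codons)

    if spec.fusion_side != "none" and spec.fusion_len > 0:
        if fusion_domain is None:
            aas = [a for a in _AA_TO_CODONS if a != "U"]
            fusion_domain = "".join(
                aas[int(rng.integers(len(aas)))] for _ in range(spec.fusion_len)
            )
        domain_cds = "".join(_reverse_translate(fusion_domain, rng))
    else:
        domain_cds = ""

    up_flank = "".join(_random_codons(flank_codons, rng))
    down_flank = "".join(_random_codons(flank_codons, rng))

    parts = [up_flank, "TAA"]
    if spec.fusion_side == "N":
        parts.append(domain_cds)
    start = sum(len(p) for p in parts)
    parts.append(core)
    end = start + len(core)
    if spec.fusion_side == "C":
        parts.append(domain_cds)
    parts.extend(["TAA", down_flank])
    contig_seq = "".join(parts)

    contig_id = contig_id or f"contig_{gene_id}"
    if strand == "-":
        length = len(contig_seq)
        contig_seq = revcomp(contig_seq)
        start, end = length - end, length - start
    annotation = GeneAnnotation(gene_id, contig_id, start, end, strand)
    contig = GenomeRecord(contig_id, contig_seq)
    return GeneModel(
        gene_id, contig, annotation, core,
        translate_cds(core), site, spec.secis_flag, spec,
    )


def apply_noise(
    gene: GeneModel, rate: float, seed, protect_site: bool = True
) -> str:
    """Protein of a gene with iid amino-acid substitution noise applied
    outside the Sec-homologous site; returns the noisy protein."""
    rng = _rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    prot = list(gene.protein)
    for i in range(len(prot)):
        if protect_site and i == gene.site_codon:
            continue
        if rng.random() < rate:
            prot[i] = aas[int(rng.integers(len(aas)))]
    return "".join(prot)


# ---------------------------------------------------------------------------
# recoding-signal windows (for the structure scanner)


def generate_recoding_window(
    kind: str, seed, half_window: int = 60
) -> tuple[str, int]:
    """A nucleotide window centred on a TGA with a planted element.

    ``kind`` is 'SRE' (one hairpin starting +5 nt after the TGA), 'HRE'
    (three hairpins, the TGA in the apical loop of the middle one) or
    'none'. The background is adenine-only, which cannot base-pair with
    itself or with the G/C stem arms, making the planted element the
    unique maximum-weight structure — a deliberate positive/negative
    control design, not a model of real coding sequence.
    """
    rng = _rng(seed)
    n = 2 * half_window + 3
    win = ["A"] * n
    uga = half_window
    win[uga : uga + 3] = "TGA"

    def put(pos: int, s: str) -> None:
        win[pos : pos + len(s)] = list(s)

    if kind == "SRE":
        arm = _gc_arm(10, rng)
        start = uga + 3 + 5 - 1  # stem begins at offset +5 after the TGA
        put(start, arm)
        put(start + 14, revcomp(arm))  # 4 nt apical loop
    elif kind == "HRE":
        mid = _gc_arm(10, rng)
        put(uga - 10, mid)
        put(uga + 3, revcomp(mid))  # TGA is the 3 nt apical loop
        side1 = _gc_arm(8, rng)
        put(uga - 40, side1)
        put(uga - 28, revcomp(side1))  # 4 nt loop
        side2 = _gc_arm(8, rng)
        put(uga + 20, side2)
        put(uga + 32, revcomp(side2))
    elif kind != "none":
        raise ValueError(f"unknown window kind {kind!r}")
    return "".join(win), uga


# ---------------------------------------------------------------------------
# marker panels


TRAIT_LABELS = ("both", "sec", "seu", "orphan", "none")


def generate_marker_panel(
    n_genomes: int = 223,
    p_sec: float = 0.18,
    p_seu: float = 0.16,
    p_both: float = 0.10,
    seed=0,
    p_orphan: float = 0.02,
    p_sec_residue: float = 0.19,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genome x marker matrix with planted trait labels.

    Counts are nearest-integer rounded from the probabilities (residual to
    "none"), so recalled frequencies match the planted ones exactly.
    Marker columns are filled consistently with the trait rules: Sec =>
    SelD plus at least one of SelA / tRNAsec / selenoproteins; SeU => SelD
    plus ybbB; orphan => SelD alone.
    """
    for name, p in (("p_sec", p_sec), ("p_seu", p_seu), ("p_both", p_both),
                    ("p_orphan", p_orphan)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} outside [0, 1]")
    if p_both > min(p_sec, p_seu):
        raise ValueError("p_both exceeds min(p_sec, p_seu)")
    rng = _rng(seed)
    n_sec = round(n_genomes * p_sec)
    n_seu = round(n_genomes * p_seu)
    n_both = round(n_genomes * p_both)
    n_orphan = round(n_genomes * p_orphan)
    counts = {
        "both": n_both,
        "sec": n_sec - n_both,
        "seu": n_seu - n_both,
        "orphan": n_orphan,
    }
    counts["none"] = n_genomes - sum(counts.values())
    if min(counts.values()) < 0:
        raise ValueError("inconsistent probabilities (negative group count)")

    labels = [lab for lab, k in counts.items() for _ in range(k)]
    rng.shuffle(labels)
    ids = [f"genome_{i:04d}" for i in range(n_genomes)]

    rows = []
    for lab in labels:
        seld = lab != "none"
        sec = lab in ("sec", "both")
        seu = lab in ("seu", "both")
        if sec:
            # SelA accompanies the Sec trait in (almost) every surveyed
            # genome; the default panel plants it in all of them, with
            # tRNAsec and selenoproteome presence varying freely
            sela = True
            trna = bool(rng.integers(2))
            n_proteome = int(rng.integers(0, 6))
        else:
            sela, trna, n_proteome = False, False, 0
        rows.append(
            {
                "SelD_present": seld,
                "SelD_residue": "none",
                "SelA": sela,
                "ybbB": seu,
                "tRNAsec": trna,
                "selenoproteome_size": n_proteome,
            }
        )
    m = pd.DataFrame(rows, index=pd.Index(ids, name="genome_id"))

    carriers = np.flatnonzero(m["SelD_present"].to_numpy())
    n_u = round(len(carriers) * p_sec_residue)
    u_rows = rng.choice(carriers, size=n_u, replace=False) if n_u else []
    residues = np.where(m["SelD_present"], "C", "none").astype(object)
    for r in u_rows:
        residues[r] = "U"
    m["SelD_residue"] = residues
    return m, pd.Series(labels, index=m.index, name="trait")
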