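"""Detection of SPS gene extensions and fusions.

Each annotated gene is extended in frame, both upstream and downstream,
until a stop codon (exclusive) or the contig edge. The extended protein is
aligned to the family profile; terminal stretches not covered by any
profile column are extension candidates, reported when they reach a
minimum length (default 50 aa, the scale of a fused domain rather than a
ragged alignment end). Recurrent extensions across genes are grouped by
single-linkage clustering on global-alignment identity, the in-package
analogue of the published merge-and-cluster step against NR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import Align

from .io import GeneAnnotation, GenomeRecord
from .codons import STOP_CODONS, translate_cds
from .profiles import Profile, ProfileAlignment, align_to_profile

MIN_EXTENSION = 50  # aa
CLUSTER_MIN_IDENTITY = 0.30
CLUSTER_MIN_COVERAGE = 0.80

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ExtendedOrf:
    gene_id: str
    cds: str  # extended CDS, coding strand
    upstream_codons: int  # codons gained upstream of the annotation
    downstream_codons: int


@dataclass(frozen=True)
class FusionReport:
    gene_id: str
    side: str  # N | C
    extension_len: int  # aa
    extension_sequence: str
    cluster_id: int | None = None
    recurrent: bool = False  # cluster has >= 2 members


def extend_orf(genome: GenomeRecord, gene: GeneAnnotation) -> ExtendedOrf:
    """Extend an annotated CDS codon-by-codon to the flanking stops.

    Walks in frame away from the annotation on both sides, stopping before
    the first stop codon (TAA/TAG/TGA) or the contig edge. Minus-strand
    genes are handled by reverse complement; the returned CDS is on the
    coding strand.
    """
    seq = genome.sequence.upper()
    if gene.end > len(seq):
        raise ValueError(f"{gene.gene_id}: coordinates outside contig")
    if gene.strand == "-":
        # mirror the interval onto the reverse complement and recurse
        flipped = GenomeRecord(genome.id, seq.translate(_COMPLEMENT)[::-1])
        mirrored = replace(
            gene,
            start=len(seq) - gene.end,
            end=len(seq) - gene.start,
            strand="+",
        )
        ext = extend_orf(flipped, mirrored)
        return ExtendedOrf(gene.gene_id, ext.cds, ext.upstream_codons, ext.downstream_codons)

    up = 0
    pos = gene.start
    while pos - 3 >= 0:
        codon = seq[pos - 3 : pos]
        if codon in STOP_CODONS:
            break
        up += 1
        pos -= 3
    down = 0
    pos = gene.end
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            break
        down += 1
        pos += 3
    cds = seq[gene.start - 3 * up : gene.end + 3 * down]
    return ExtendedOrf(gene.gene_id, cds, up, down)


def detect_extension(
    extended_protein: str,
    profile: Profile,
    gene_id: str = "",
    min_extension: int = MIN_EXTENSION,
    alignment: ProfileAlignment | None = None,
) -> list[FusionReport]:
    """Terminal stretches of an extended protein not covered by the profile.

    Residues before the first / after the last profile-aligned position
    form the N / C candidates; only candidates of at least
    ``min_extension`` aa are reported.
    """
    if alignment is None:
        alignment = align_to_profile(extended_protein, profile)
    first = alignment.first_aligned_pos()
    last = alignment.last_aligned_pos()
    if first is None:
        return []
    reports = []
    if first >= min_extension:
        reports.append(
            FusionReport(gene_id, "N", first, extended_protein[:first])
        )
    c_len = len(extended_protein) - 1 - last
    if c_len >= min_extension:
        reports.append(
            FusionReport(gene_id, "C", c_len, extended_protein[last + 1 :])
        )
    return reports


def scan_gene_for_fusion(
    genome: GenomeRecord,
    gene: GeneAnnotation,
    profile: Profile,
    min_extension: int = MIN_EXTENSION,
) -> list[FusionReport]:
    """extend_orf + translate + detect_extension for one gene."""
    ext = extend_orf(genome, gene)
    protein = translate_cds(ext.cds)
    return detect_extension(protein, profile, gene.gene_id, min_extension)


def _pair_identity(a: str, b: str) -> tuple[float, float, float]:
    """(identity over aligned columns, coverage of a, coverage of b) under
    a global alignment with end gaps free."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aln = aligner.align(a, b)[0]
    ta, tb = aln.aligned  # blocks of (start, end) per sequence
    matches = 0
    cols = 0
    cov_a = cov_b = 0
    for (sa, ea), (sb, eb) in zip(ta, tb):
        cols += ea - sa
        cov_a += ea - sa
        cov_b += eb - sb
        matches += sum(1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y)
    if cols == 0:
        return 0.0, 0.0, 0.0
    return matches / cols, cov_a / len(a), cov_b / len(b)


def cluster_extensions(reports: list[FusionReport]) -> list[FusionReport]:
    """Single-linkage clustering of extension sequences.

    Two extensions are linked when global-alignment identity >= 0.30 over
    >= 0.80 mutual coverage. Cluster ids start at 1 and are assigned by
    decreasing cluster size, ties broken by the lexicographically smallest
    member gene_id; clusters with >= 2 members are flagged recurrent.
    """
    if not reports:
        return []
    n = len(reports)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident, cov_i, cov_j = _pair_identity(
                reports[i].extension_sequence, reports[j].extension_sequence
            )
            if (
                ident >= CLUSTER_MIN_IDENTITY
                and cov_i >= CLUSTER_MIN_COVERAGE
                and cov_j >= CLUSTER_MIN_COVERAGE
            ):
                parent[find(i)] = find(j)

    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(find(i), []).append(i)
    ordered = sorted(
        members.values(),
        key=lambda idx: (-len(idx), min(reports[i].gene_id for i in idx)),
    )
    out = list(reports)
    for cid, idxs in enumerate(ordered, start=1):
        for i in idxs:
            out[i] = replace(
                out[i], cluster_id=cid, recurrent=len(idxs) >= 2
            )
    return out
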