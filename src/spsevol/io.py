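"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
inclusive coordinates are converted at this boundary. Nucleotide FASTA input
is upper-cased and RNA 'U' is mapped to 'T' on the way in.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("spsevol")

# IUPAC alphabets (upper case, post U->T mapping for nucleotides)
NUCLEOTIDE_ALPHABET = frozenset("ACGTNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYUXBZJO*-")


class FastaError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeRecord:
    """A named DNA sequence (a contig, genome or CDS)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("empty record id")
        if not self.sequence:
            raise FastaError(f"empty sequence for record {self.id!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS feature in 0-based half-open coordinates on its contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    phase: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"{self.gene_id}: invalid phase {self.phase}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def complete(self) -> bool:
        return self.length % 3 == 0


def _validate(seq: str, rec_id: str, alphabet: frozenset) -> None:
    bad = set(seq) - alphabet
    if bad:
        raise FastaError(
            f"record {rec_id!r}: illegal character(s) {sorted(bad)}"
        )


def read_fasta(path, *, alphabet: str = "nucleotide") -> list[GenomeRecord]:
    """Read FASTA into records, rejecting duplicate ids and bad symbols.

    ``alphabet`` is ``"nucleotide"`` (U mapped to T) or ``"protein"``
    ('U' = Sec is a first-class symbol).
    """
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaError(f"duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if alphabet == "nucleotide":
                seq = seq.replace("U", "T")
            _validate(seq, rec.id, allowed)
            records.append(GenomeRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[GenomeRecord | tuple[str, str]], path) -> Path:
    path = Path(path)
    seen: set[str] = set()
    seqrecs = []
    for rec in records:
        rid, seq = (rec.id, rec.sequence) if isinstance(rec, GenomeRecord) else rec
        if rid in seen:
            raise FastaError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")
    return path


def read_gff3(path) -> list[GeneAnnotation]:
    """Read CDS features from GFF3 into 0-based half-open annotations.

    Minus-strand features keep genomic start < end; orientation is handled
    downstream (reverse complement at extraction time).
    """
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            contig, _src, ftype, start, end, _score, strand, phase, attrs = fields
            if ftype != "CDS":
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start > end")
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = _attr_id(attrs) or f"cds_{lineno}"
            out.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=start_i - 1,  # 1-based inclusive -> 0-based half-open
                    end=end_i,
                    strand=strand,
                    phase=int(phase) if phase in "012" else 0,
                )
            )
    return out


def _attr_id(attrs: str) -> str | None:
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv.startswith("ID="):
            return kv[3:]
    return None


def write_gff3(annotations: Sequence[GeneAnnotation], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    [
                        a.contig_id,
                        "spsevol",
                        "CDS",
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        a.strand,
                        str(a.phase),
                        f"ID={a.gene_id}",
                    ]
                )
                + "\n"
            )
    return path


class NewickError(ValueError):
    pass


def read_newick(source) -> dendropy.Tree:
    """Read a rooted tree from a newick file path or string."""
    text = str(source)
    if isinstance(source, Path) or ("(" not in text and Path(text).exists()):
        data = Path(source).read_text()
    else:
        data = text
    if data.count("(") != data.count(")"):
        raise NewickError("unbalanced parentheses in newick input")
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise NewickError(f"duplicate leaf label(s): {e}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"duplicate leaf label(s): {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def tree_from_string(newick: str) -> dendropy.Tree:
    return read_newick(_io.StringIO(newick).getvalue())
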