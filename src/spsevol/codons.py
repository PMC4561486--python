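"""Genetic-code primitives shared across the package.

The standard nuclear code is used throughout, with one deliberate extension:
an in-frame TGA is translated as selenocysteine ('U'), the 21st amino acid,
because in SPS/SelD genes the UGA codon is (potentially) recoded rather than
terminating. TAA/TAG inside a CDS are always treated as hard stops.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable as _CodonTable

NUCS = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
HARD_STOPS = frozenset({"TAA", "TAG"})  # never recoded

_standard = _CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, standard code plus TGA -> 'U' (Sec).
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
GENETIC_CODE["TGA"] = "U"

#: the 61 sense codons of the standard code (TGA excluded).
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
)

#: Fitch state space for codon characters: sense codons plus the recodable TGA.
CODON_STATES: tuple[str, ...] = tuple(sorted(SENSE_CODONS + ("TGA",)))

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def aa_of(codon: str) -> str:
    """Amino acid for a sense codon or TGA ('U'); '*' for TAA/TAG."""
    if codon in HARD_STOPS:
        return "*"
    return GENETIC_CODE[codon]


class PseudogeneError(ValueError):
    """Raised when a CDS contains an internal hard stop (TAA/TAG)."""


def translate_cds(cds: str, *, uga_as_sec: bool = True) -> str:
    """Translate an in-frame CDS.

    In-frame TGA becomes 'U' (Sec); a single terminal stop codon (any of the
    three) is dropped; an internal TAA/TAG raises :class:`PseudogeneError`.
    Codons containing N translate to 'X'.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    cds = cds.upper()
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    out = []
    for i, codon in enumerate(codons):
        if "N" in codon:
            out.append("X")
        elif codon in HARD_STOPS:
            raise PseudogeneError(
                f"internal stop {codon} at codon {i}; pseudogene-like CDS"
            )
        elif codon == "TGA":
            out.append("U" if uga_as_sec else "*")
        else:
            out.append(GENETIC_CODE[codon])
    return "".join(out)


def mutants(codon: str, position: int) -> list[str]:
    """The three single-nucleotide mutants of ``codon`` at ``position``."""
    return [
        codon[:position] + n + codon[position + 1 :]
        for n in NUCS
        if n != codon[position]
    ]


@lru_cache(maxsize=None)
def syn_sites(codon: str, stop_mutants_nonsyn: bool = True) -> tuple[float, float]:
    """Nei–Gojobori (S, N) site counts for one codon.

    Each position contributes the fraction of its three single-nucleotide
    mutants that are synonymous. By default mutants creating a stop count
    as nonsynonymous, which preserves S + N = 3 exactly; the alternative
    dialect (``stop_mutants_nonsyn=False``) drops them from both tallies,
    so S + N < 3 for stop-adjacent codons.
    """
    s = n = 0.0
    aa = aa_of(codon)
    for pos in range(3):
        for m in mutants(codon, pos):
            if m in STOP_CODONS:
                if stop_mutants_nonsyn:
                    n += 1.0 / 3.0
                continue
            if aa_of(m) == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


@lru_cache(maxsize=None)
def pathway_differences(a: str, b: str) -> tuple[float, float]:
    """NG86 (Sd, Nd) between two codons, averaged over mutational pathways.

    Pathways stepping through a stop codon are excluded; when every pathway
    is excluded they are re-admitted with stop-creating steps counted as
    nonsynonymous (keeps Sd + Nd equal to the number of differing positions).
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(include_stop_paths: bool) -> tuple[float, float, int]:
        sd = nd = 0.0
        n_paths = 0
        for order in itertools.permutations(diff):
            cur = a
            steps: list[tuple[str, str]] = []
            blocked = False
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS and not include_stop_paths:
                    blocked = True
                    break
                steps.append((cur, nxt))
                cur = nxt
            if blocked:
                continue
            n_paths += 1
            for x, y in steps:
                if (
                    x not in STOP_CODONS
                    and y not in STOP_CODONS
                    and aa_of(x) == aa_of(y)
                ):
                    sd += 1.0
                else:
                    nd += 1.0
        return sd, nd, n_paths

    sd, nd, n_paths = walk(include_stop_paths=False)
    if n_paths == 0:
        sd, nd, n_paths = walk(include_stop_paths=True)
    return sd / n_paths, nd / n_paths


def synonymous(a: str, b: str) -> bool:
    """True if two non-stop codons encode the same amino acid."""
    return aa_of(a) == aa_of(b)
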