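"""Profile alignment and classification of SPS homologs by the Sec-site residue.

An SPS candidate protein is aligned to a seed profile (an aligned set of SPS
family members with a marked catalytic column, where selenocysteine 'U' or
cysteine sits). The residue of the candidate that maps to that column, plus
the presence/absence of a SECIS annotation, determines the functional class:

* ``SPS2-Sec``  — U at the site, SECIS present (true selenoprotein);
* ``SPS1-UGA``  — U at the site but no SECIS (readthrough candidate);
* ``SPS2-Cys``  — C at the site (selenophosphate synthase, Cys homolog);
* ``SPS1-<r>``  — any other residue r (Thr/Gly/Leu/Arg...), the
  subfunctionalized paralogs;
* ``unclassified`` — the site maps to a gap or the flank identity is too low.

The alignment is an overlap (free-end-gap) dynamic program over per-column
log-odds scores, so terminal fusions dangle off the ends instead of
truncating the column map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .io import read_fasta

#: 21-letter alphabet: the 20 standard amino acids plus selenocysteine.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYU"
_IDX = {a: i for i, a in enumerate(ALPHABET)}

GAP_OPEN = -11.0
GAP_EXTEND = -1.0
FLANK_RADIUS = 10
CONFIDENCE_THRESHOLD = 0.4


class ProfileError(ValueError):
    pass


@dataclass
class Profile:
    """Per-column frequency/log-odds model of an aligned protein family."""

    ids: list[str]
    alignment: list[str]
    sec_column: int
    frequencies: np.ndarray = field(repr=False, default=None)  # (ncols, 21)
    log_odds: np.ndarray = field(repr=False, default=None)

    @property
    def ncols(self) -> int:
        return len(self.alignment[0])

    def consensus(self) -> str:
        """Modal symbol per column (ties broken alphabetically), gaps skipped."""
        return "".join(
            ALPHABET[int(np.argmax(self.frequencies[c]))] for c in range(self.ncols)
        )


def build_profile(aligned: list[tuple[str, str]], sec_column: int) -> Profile:
    """Build a :class:`Profile` from an aligned family.

    Frequencies use an add-one pseudocount over the 21-symbol alphabet
    (gaps are not counted); scores are log-odds against a uniform 1/21
    background.
    """
    if len(aligned) < 2:
        raise ProfileError("need at least 2 aligned sequences")
    ids = [i for i, _ in aligned]
    seqs = [s.upper() for _, s in aligned]
    ncols = len(seqs[0])
    if any(len(s) != ncols for s in seqs):
        raise ProfileError("ragged alignment")
    if not 0 <= sec_column < ncols:
        raise ProfileError(f"sec_column {sec_column} out of range")
    col = [s[sec_column] for s in seqs]
    if all(c == "-" for c in col):
        raise ProfileError("sec_column is all-gap")
    if "U" not in col:
        raise ProfileError("no sequence carries U (Sec) at sec_column")

    counts = np.zeros((ncols, len(ALPHABET)))
    for s in seqs:
        for c, sym in enumerate(s):
            if sym == "-":
                continue
            if sym not in _IDX:
                raise ProfileError(f"illegal profile symbol {sym!r}")
            counts[c, _IDX[sym]] += 1
    freqs = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + len(ALPHABET))
    log_odds = np.log(freqs * len(ALPHABET))
    return Profile(ids, seqs, sec_column, freqs, log_odds)


def load_packaged_profile() -> Profile:
    """The SPS seed profile shipped with the package (synthetic fixture)."""
    data = resources.files("spsevol") / "data"
    recs = read_fasta(str(data / "sps_profile.afa"), alphabet="protein")
    meta = json.loads((data / "sps_profile.json").read_text())
    return build_profile([(r.id, r.sequence) for r in recs], meta["sec_column"])


@dataclass
class ProfileAlignment:
    """Result of aligning one protein to a profile."""

    protein: str
    score: float
    #: profile column -> protein index (or None for a gapped column)
    col_to_pos: list[int | None]

    def first_aligned_pos(self) -> int | None:
        hits = [p for p in self.col_to_pos if p is not None]
        return min(hits) if hits else None

    def last_aligned_pos(self) -> int | None:
        hits = [p for p in self.col_to_pos if p is not None]
        return max(hits) if hits else None


_NEG = -1e30


def align_to_profile(protein: str, profile: Profile) -> ProfileAlignment:
    """Overlap-align a protein to a profile, maximizing column log-odds.

    Free end gaps on both sides; affine internal gaps (open -11, extend -1);
    deterministic traceback preferring diagonal, then up (unmatched profile
    column), then left (protein insertion).
    """
    protein = protein.upper()
    if not protein:
        raise ProfileError("empty protein")
    try:
        enc = np.array([_IDX[a] for a in protein.replace("X", "A")])
    except KeyError as e:
        raise ProfileError(f"symbol outside 21-letter alphabet: {e}") from None
    # X (unknown) scores as the column mean instead of a specific residue
    m, n = profile.ncols, len(protein)
    colmean = profile.log_odds.mean(axis=1)
    S = profile.log_odds[:, enc]  # (m, n) substitution scores
    for j, a in enumerate(protein):
        if a == "X":
            S[:, j] = colmean

    # chain DP: an alignment is a contiguous run of matched pairs with
    # affine internal gaps; everything outside the run (both terminal
    # tails) is free, so a fresh start (score 0) is allowed anywhere.
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)  # profile column skipped (deletion)
    Y = np.full((m + 1, n + 1), _NEG)  # protein insertion

    for i in range(1, m + 1):
        Mi_1, Xi_1, Yi_1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for j in range(1, n + 1):
            Mi[j] = Si[j - 1] + max(0.0, Mi_1[j - 1], Xi_1[j - 1], Yi_1[j - 1])
            Xi[j] = max(Mi_1[j] + GAP_OPEN, Xi_1[j] + GAP_EXTEND)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND)

    best, bi, bj = 0.0, 0, 0  # empty alignment fallback
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if M[i, j] > best:
                best, bi, bj = M[i, j], i, j

    col_to_pos: list[int | None] = [None] * m
    i, j, state = bi, bj, "M"
    while i > 0 and j > 0:
        if state == "M":
            col_to_pos[i - 1] = j - 1
            target = M[i, j] - S[i - 1, j - 1]
            # tie order: diagonal(M) > up(X) > left(Y) > fresh start
            if abs(M[i - 1, j - 1] - target) < 1e-9:
                state = "M"
            elif abs(X[i - 1, j - 1] - target) < 1e-9:
                state = "X"
            elif abs(Y[i - 1, j - 1] - target) < 1e-9:
                state = "Y"
            else:  # target == 0: start of the chain
                break
            i, j = i - 1, j - 1
        elif state == "X":
            if abs(M[i - 1, j] + GAP_OPEN - X[i, j]) < 1e-9:
                state = "M"
            else:
                state = "X"
            i -= 1
        else:  # Y
            if abs(M[i, j - 1] + GAP_OPEN - Y[i, j]) < 1e-9:
                state = "M"
            else:
                state = "Y"
            j -= 1
    return ProfileAlignment(protein, float(best), col_to_pos)


@dataclass(frozen=True)
class SiteCall:
    """Residue observed at the Sec-homologous column of one gene."""

    gene_id: str
    residue: str  # one-letter aa, 'U', or 'x' when the site maps to a gap
    flank_identity: float
    confident: bool


def call_site_residue(
    alignment: ProfileAlignment, profile: Profile, gene_id: str = ""
) -> SiteCall:
    """Read the residue mapped to the profile's Sec column.

    ``flank_identity`` is the fraction of the up-to-20 columns within ±10 of
    the site whose mapped residue equals the profile's modal symbol; columns
    mapping to a gap count as mismatches. A call is confident when this
    fraction reaches 0.4.
    """
    sec = profile.sec_column
    pos = alignment.col_to_pos[sec]
    residue = "x" if pos is None else alignment.protein[pos]

    consensus = profile.consensus()
    lo = max(0, sec - FLANK_RADIUS)
    hi = min(profile.ncols, sec + FLANK_RADIUS + 1)
    window = [c for c in range(lo, hi) if c != sec]
    ident = 0
    for c in window:
        p = alignment.col_to_pos[c]
        if p is not None and alignment.protein[p] == consensus[c]:
            ident += 1
    flank_identity = ident / len(window) if window else 0.0
    confident = flank_identity >= CONFIDENCE_THRESHOLD
    return SiteCall(gene_id, residue, flank_identity, confident)


def classify_sps(site: SiteCall, secis_flag: bool) -> str:
    """Map a site call plus SECIS annotation to the SPS functional class."""
    if not site.confident or site.residue == "x":
        return "unclassified"
    r = site.residue
    if r == "U":
        return "SPS2-Sec" if secis_flag else "SPS1-UGA"
    if r == "C":
        return "SPS2-Cys"
    return f"SPS1-{r}"


@dataclass(frozen=True)
class GenomeCapability:
    sec_capable: bool
    consistent: bool


def classify_genome(
    gene_classes: list[str], selenoproteome_size: int = 0
) -> GenomeCapability:
    """Genome-level Sec capability: present iff the genome keeps an SPS2.

    A consistency flag records whether the capability call agrees with an
    independently observed selenoproteome size.
    """
    capable = any(c in ("SPS2-Sec", "SPS2-Cys") for c in gene_classes)
    consistent = capable == (selenoproteome_size > 0)
    return GenomeCapability(capable, consistent)
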