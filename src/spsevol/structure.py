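"""Readthrough-signal detection around in-frame UGA codons.

Three signals are scanned for, all described for selenoprotein and
SPS1-UGA genes:

* the GGG-UG[C/U] hexanucleotide immediately (or nearly) downstream of the
  UGA, a motif overrepresented next to leaky viral stop codons;
* stem-loop structures (SRE: one or two stems just downstream of the UGA;
  HRE: a three-stem clover with the UGA at the apex of the middle stem;
  bSECIS-like: a single stem fully 3' of the UGA in prokaryotic mode);
* alignment-level consensus structures with compensatory (covarying) pairs.

Folding is maximum-weighted-pairing dynamic programming (GC=3, AU=2, GU=1,
minimum hairpin loop 3 nt) on the DNA alphabet with T == U — a deliberately
simple, exhaustively testable scoring, not a thermodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PAIR_WEIGHT = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}
MIN_LOOP = 3
MIN_STEM_PAIRS = 3
DEFAULT_WINDOW = 60  # nt on each side of the UGA
HEXAMER_VARIANTS = ("GGGTGC", "GGGTGT")


def pair_weight(a: str, b: str) -> float:
    return PAIR_WEIGHT.get((a, b), 0.0)


@dataclass(frozen=True)
class HexamerHit:
    gene_id: str
    offset: int  # nt after the UGA; +1 = immediately adjacent
    variant: str
    adjacent: bool


def scan_hexamer(
    cds: str, uga_position: int, gene_id: str = "", max_offset: int = 9
) -> list[HexamerHit]:
    """Exact-match scan for GGG-TG[C/T] downstream of an in-frame TGA.

    ``uga_position`` is the 0-based index of the T of the TGA. Hits start
    at offsets +1..+9 after the codon; offset +1 is flagged adjacent.
    """
    cds = cds.upper().replace("U", "T")
    if cds[uga_position : uga_position + 3] != "TGA":
        raise ValueError(f"position {uga_position} is not a TGA codon")
    hits = []
    after = uga_position + 3
    for offset in range(1, max_offset + 1):
        start = after + offset - 1
        candidate = cds[start : start + 6]
        if candidate in HEXAMER_VARIANTS:
            hits.append(HexamerHit(gene_id, offset, candidate, offset == 1))
    return hits


@dataclass
class StructurePrediction:
    window_start: int  # window offset relative to the sequence scanned
    sequence: str
    pairs: list[tuple[int, int]]  # window-local, i < j, non-crossing
    dot_bracket: str
    score: float
    stems: list[list[tuple[int, int]]]
    n_stems: int
    uga_context: str  # in_apical_loop | in_stem | unpaired_outside


def fold_window(
    window: str, uga_index: int | None = None, window_start: int = 0
) -> StructurePrediction:
    """Maximum-weighted-pair fold of a sequence window.

    Deterministic traceback: prefer leaving the left end unpaired, then
    pairing it with the smallest admissible partner. ``uga_index`` is the
    window-local index of the T of an in-frame TGA, used to derive the
    UGA's structural context.
    """
    seq = window.upper().replace("U", "T")
    n = len(seq)
    if not 1 <= n <= 200:
        raise ValueError(f"window length {n} outside [1, 200]")

    W = np.zeros((n + 2, n + 2))
    pw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            pw[i, j] = pair_weight(seq[i], seq[j])
    idx = np.arange(n)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j]
            ks = idx[i + MIN_LOOP + 1 : j + 1]
            if ks.size:
                vals = pw[i, ks] + W[i + 1, ks - 1] + W[ks + 1, j]
                vals = np.where(pw[i, ks] > 0, vals, -1.0)
                best = max(best, vals.max(initial=-1.0))
            W[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if W[i, j] == W[i + 1, j]:  # prefer leaving i unpaired
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):  # smallest admissible k
            if pw[i, k] > 0 and abs(
                W[i, j] - (pw[i, k] + W[i + 1, k - 1] + W[k + 1, j])
            ) < 1e-9:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break

    pairs.sort()
    score = float(W[0, n - 1]) if n > 1 else 0.0
    stems = find_stems(pairs)
    context = uga_context(pairs, stems, uga_index) if uga_index is not None else (
        "unpaired_outside"
    )
    return StructurePrediction(
        window_start, seq, pairs, dot_bracket(pairs, n), score,
        stems, len(stems), context,
    )


def dot_bracket(pairs: list[tuple[int, int]], n: int) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def find_stems(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Maximal runs of >=3 stacked pairs ((i,j),(i+1,j-1),...)."""
    pairset = dict(pairs)
    stems = []
    used: set[tuple[int, int]] = set()
    for i, j in sorted(pairs):
        if (i, j) in used:
            continue
        run = [(i, j)]
        while pairset.get(run[-1][0] + 1) == run[-1][1] - 1:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        used.update(run)
        if len(run) >= MIN_STEM_PAIRS:
            stems.append(run)
    return stems


def uga_context(
    pairs: list[tuple[int, int]],
    stems: list[list[tuple[int, int]]],
    uga_index: int,
) -> str:
    """Structural context of the TGA codon at window-local ``uga_index``."""
    uga = set(range(uga_index, uga_index + 3))
    paired = {i for p in pairs for i in p}
    # apical loop: strictly inside the innermost pair of a stem, unpaired
    for stem in stems:
        inner_i, inner_j = stem[-1]
        loop = set(range(inner_i + 1, inner_j))
        if any(p in loop and p not in paired for p in uga):
            return "in_apical_loop"
    stem_positions = {i for stem in stems for p in stem for i in p}
    if any(p in stem_positions for p in uga):
        return "in_stem"
    if any(p in paired for p in uga):
        return "in_stem"
    return "unpaired_outside"


def classify_recoding_element(
    pred: StructurePrediction,
    hexamer_hits: list[HexamerHit] | None = None,
    secis_flag: bool = False,
    uga_index: int | None = None,
    mode: str = "eukaryotic",
) -> str:
    """Classify a folded UGA-centred window as HRE, SRE, bSECIS-like or none.

    * HRE: >=3 stems with the UGA in an apical loop or the apical half of
      the stem containing it (the clover configuration);
    * SRE: 1-2 stems, at least one beginning within 12 nt downstream of
      the UGA;
    * bSECIS-like: a single stem entirely 3' of the UGA, prokaryotic mode
      only.

    ``hexamer_hits`` and ``secis_flag`` are carried in the report but do
    not gate the structural classification.
    """
    if uga_index is None:
        uga_index = len(pred.sequence) // 2
    uga_end = uga_index + 3

    if pred.n_stems == 0:
        return "none"

    if pred.n_stems >= 3 and _uga_apical(pred, uga_index):
        return "HRE"

    downstream_start = [
        s for s in pred.stems if uga_end <= s[0][0] <= uga_end + 12
    ]
    fully_downstream = [s for s in pred.stems if s[0][0] >= uga_end]
    if mode == "prokaryotic" and pred.n_stems == 1 and len(fully_downstream) == 1:
        return "bSECIS-like"
    if 1 <= pred.n_stems <= 2 and downstream_start:
        return "SRE"
    return "none"


def _uga_apical(pred: StructurePrediction, uga_index: int) -> bool:
    """UGA in an apical loop, or paired within the apical half of its stem."""
    uga = set(range(uga_index, uga_index + 3))
    paired = {i for p in pred.pairs for i in p}
    for stem in pred.stems:
        inner_i, inner_j = stem[-1]
        loop = set(range(inner_i + 1, inner_j))
        if any(p in loop and p not in paired for p in uga):
            return True
        # apical half: inner half of the stem's stacked run
        half = stem[len(stem) // 2 :]
        half_pos = {i for p in half for i in p}
        if any(p in half_pos for p in uga):
            return True
    return False


# ---------------------------------------------------------------------------
# consensus folding over aligned windows


@dataclass
class ConsensusStructure:
    pairs: list[tuple[int, int]]  # alignment-column pairs
    pairability: list[float]  # fraction of gapless rows complementary, per pair
    covariation: int
    dot_bracket: str


def consensus_fold(
    rows: list[str], min_pairability: float = 0.8
) -> ConsensusStructure:
    """Fold the pairability-weighted consensus of aligned windows.

    A column pair is admissible when the two nucleotides are complementary
    (GU included) in at least ``min_pairability`` of the rows that are
    gapless at both columns; its weight is the mean pair weight over those
    complementary rows. Covariation counts consensus pairs supported by at
    least one row whose pair differs from the modal pair at both positions
    while remaining complementary.
    """
    if len(rows) < 4:
        raise ValueError("need at least 4 aligned sequences")
    rows = [r.upper().replace("U", "T") for r in rows]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged alignment")
    for c in range(ncol):
        gap_frac = sum(r[c] == "-" for r in rows) / len(rows)
        if gap_frac > 0.5:
            raise ValueError(f"column {c} exceeds 50% gaps")

    pairability = np.zeros((ncol, ncol))
    weight = np.zeros((ncol, ncol))
    for i in range(ncol):
        for j in range(i + MIN_LOOP + 1, ncol):
            gapless = [r for r in rows if r[i] != "-" and r[j] != "-"]
            if not gapless:
                continue
            wts = [pair_weight(r[i], r[j]) for r in gapless]
            comp = [w for w in wts if w > 0]
            pairability[i, j] = len(comp) / len(gapless)
            if comp:
                weight[i, j] = sum(comp) / len(comp)

    # Nussinov on admissible column pairs
    n = ncol
    W = np.zeros((n + 2, n + 2))
    admissible = pairability >= min_pairability
    idx = np.arange(n)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j]
            ks = idx[i + MIN_LOOP + 1 : j + 1]
            if ks.size:
                vals = weight[i, ks] + W[i + 1, ks - 1] + W[ks + 1, j]
                vals = np.where(admissible[i, ks], vals, -1.0)
                best = max(best, vals.max(initial=-1.0))
            W[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if W[i, j] == W[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if admissible[i, k] and abs(
                W[i, j] - (weight[i, k] + W[i + 1, k - 1] + W[k + 1, j])
            ) < 1e-9:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
    pairs.sort()

    covar = 0
    for i, j in pairs:
        gapless = [(r[i], r[j]) for r in rows if r[i] != "-" and r[j] != "-"]
        comp = [(a, b) for a, b in gapless if pair_weight(a, b) > 0]
        if not comp:
            continue
        modal = max(set(comp), key=comp.count)
        if any(a != modal[0] and b != modal[1] for a, b in comp):
            covar += 1

    return ConsensusStructure(
        pairs,
        [float(pairability[i, j]) for i, j in pairs],
        covar,
        dot_bracket(pairs, ncol),
    )
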