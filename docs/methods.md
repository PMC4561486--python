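# Methods

This note documents the models and procedures implemented in `spsevol`,
the parameter choices that matter, and what the synthetic-data experiments
do and do not demonstrate.

## Site classification

SPS homologs are classified by the residue aligned to the catalytic
(Sec-UGA) column of a seed profile.

**Profile model.** An aligned family is summarized per column as frequency
vectors over a 21-symbol alphabet — the 20 standard amino acids plus
selenocysteine `U` as its own symbol (`U` is never silently equated to
`C`; the U/C distinction is precisely the functional signal). Frequencies
use an add-one pseudocount over the 21 symbols, gaps uncounted; scores
are log-odds against a uniform 1/21 background. The packaged seed profile
(`data/sps_profile.afa`, 10 sequences × 120 columns, Sec column 60) is a
hand-built synthetic fixture whose members carry `U` or `C` at the marked
column; it is not a curated natural alignment and is labelled accordingly.

**Alignment.** Candidates are aligned by an ends-free ("overlap") dynamic
program: an alignment is one contiguous chain of matched (column, residue)
pairs with affine internal gaps (open −11, extend −1, the Blast protein
convention); both terminal tails are free, so N/C-terminal fusion domains
dangle off the profile instead of truncating the column map. Traceback is
deterministic: on ties, diagonal before column-skip before insertion
before chain start. `X` scores as the column-mean log-odds.

**Calls.** The residue mapped to the Sec column is reported (`x` for a
gap), with `flank_identity` = fraction of the up-to-20 columns within ±10
of the site whose mapped residue equals the column consensus; a call is
confident at ≥0.4 — permissive enough for diverged homologs, strict
enough that shuffled or reversed sequences fail (verified empirically in
the tests). Classes follow the site/SECIS logic: U+SECIS → `SPS2-Sec`,
U alone → `SPS1-UGA`, C → `SPS2-Cys`, other residues → `SPS1-<r>`.
Translation maps in-frame TGA to `U`, drops one terminal stop, and
rejects internal TAA/TAG as pseudogene-like; `N`-containing codons give
`X` and never a stop.

## Trait profiling

The Sec trait requires SelD plus at least one of {SelA, tRNAsec,
selenoproteome > 0} — an OR rule, since SelA is absent in archaeal Sec
utilizers; the SeU trait requires SelD plus ybbB; SelD with neither trait
is "orphan SelD". Co-occurrence is tested one-tailed in the enrichment
direction: with margins fixed to the two trait counts,
p = P(X ≥ observed overlap) under the hypergeometric null, summed in log
space via `gammaln` (agrees with exact rational arithmetic to ≥12
significant digits on all tested tables, and with an independent
`fisher_exact` route). When printed percentages must be converted to a
2×2 table, counts are nearest-integer rounded with the residual assigned
to "neither".

## Fusion detection

Annotated genes are extended codon-by-codon, upstream and downstream, to
the first stop codon (exclusive; all of TAA/TAG/TGA count as stops for
extension) or the contig edge, with minus-strand genes handled by reverse
complement. The extended protein is aligned to the profile; terminal
stretches before the first / after the last aligned column are extension
candidates, reported at ≥50 aa — domain scale, above ragged alignment
ends. Candidates are clustered single-linkage: two extensions link at
global-alignment identity ≥0.30 over ≥0.80 mutual coverage (end gaps
free); cluster ids are canonical (decreasing size, then lexicographic
smallest member), so clustering is input-order invariant. Clusters with
≥2 members are flagged recurrent; singletons are low-confidence. The
published screen against an external protein database is replaced by
profile-alignment coverage; an NR-style search remains an external hook.

## Selection analysis

CodeML-style ML estimation is deliberately replaced by a self-contained,
oracle-testable counting pipeline; ω *trends* across clades, not absolute
ML estimates, are the comparable output.

**Ancestral states.** Codon characters live on 62 states (61 sense codons
plus TGA, which is recodable in this family; TAA/TAG are rejected).
Bottom-up Hartigan counting (identical to Fitch on binary trees, exact on
multifurcations) yields the minimal change count; the top-down pass keeps
the parent state when admissible, otherwise prefers TGA, then TGC/TGT,
then the lexicographically smallest codon — encoding the inference that
the ancestor carried Sec.

**NG86 counting.** Per codon, each position contributes the fraction of
its three single-nucleotide mutants that are synonymous to S and the rest
to N; mutants creating stops count as nonsynonymous by default, which
preserves N + S = 3 exactly per codon (a flag selects the dialect that
drops them). Differences between codons average over all d! mutational
pathways, excluding pathways through stops (re-admitted with stop steps
nonsynonymous only if all are excluded). Proportions are Jukes–Cantor
corrected; pN or pS ≥ 3/4 raises a saturation error, reported per branch
rather than fatally. The Sec-site column is masked by default: the
U↔C↔other substitution is the object of study, not background selection.
Clade summaries report mean/median branch ω and a pooled estimator that
sums counts before forming the ratio.

**Accuracy.** On 16-leaf trees (branch length 0.2 expected candidate
mutations per codon), 400 codons, κ = 2, the pooled ω is recovered with
median relative error ~10–16% across ω ∈ {0.15, 0.5, 1.0}; the residual
downward bias at high ω comes from NG86's unweighted site counting under
transition bias and from parsimony's underestimation of multiple hits.
The planted SPS2-relaxation contrast (ω 0.6 vs 0.15) orders the clades
correctly in essentially every replicate.

## Readthrough-element scanning

**Hexamer.** Exact string match of GGG-TG[C/T] starting within +1..+9 nt
after an in-frame TGA ("adjacent" iff +1). The scan is deterministic:
recall on planted motifs is 100% and motif-free controls can never hit.

**Folding.** Single sequences fold by maximum-weighted-pair dynamic
programming — pair weights GC = 3, AU = 2, GU = 1, hairpin loops ≥3 nt,
DNA alphabet with T ≡ U — with a deterministic traceback (prefer leaving
the left end unpaired, then its smallest admissible partner). This is a
combinatorial score, not a thermodynamic model: it is exhaustively
verifiable (the tests enumerate all structures for short windows) and
sufficient to recognize planted elements. Stems are maximal runs of ≥3
stacked pairs. Element classes: HRE = ≥3 stems with the UGA in an apical
loop or the apical half of its stem; SRE = 1–2 stems with a stem starting
within 12 nt downstream of the UGA; bSECIS-like = a single fully
downstream stem, prokaryotic scan mode only.

**Consensus structures.** Over ≥4 aligned windows (≤50% gaps per
column), a column pair is admissible when complementary (GU included) in
≥80% of gapless rows; the admissible-pair consensus is folded with mean
pair weights, and covariation counts consensus pairs supported by at
least one row differing from the modal pair at both positions while
remaining complementary. Note one structural property of this model: a
*joint* column permutation cannot destroy a covarying pair (pairability
ignores position), so the negative control in the tests shuffles rows
independently, which destroys column identity.

## History inference

Internal gene-tree nodes are duplications iff their child subtrees share
species (species-overlap); external intron evidence may veto a label but
is never inferred. Site-residue history is Fitch parsimony over the
residue alphabet with `x` treated as missing data; the root/tie
preference U, then C, then alphabetical encodes a Sec-bearing ancestor
and can be disabled (`prefer_sec=False`). Every state-changing edge emits
one event: SC (U→C), SO (U→other), or SUB for changes from a non-U
parent — SUB lies outside the classical vocabulary but keeps the event
count identical to the parsimony score on arbitrary inputs. GD events are
copied from duplication labels; GDR/AE/GL annotations are accepted as
external events only, since they rest on evidence (retrotransposition,
alternative exons, synteny) a parsimony engine cannot see.

## Synthetic data

The generators define the study conditions and carry complete ground
truth.

* **Codon evolution.** Branch length is the expected number of candidate
  point mutations per codon (pre-acceptance). Candidates pick a uniform
  codon and position; the mutant base is a transition with probability
  κ/(κ+2). Acceptance: synonymous 1, nonsynonymous ω, stop-creating 0.
  The event log (branch, column, from, to, syn/nonsyn) replays exactly
  from the root to every leaf. Because stop-creating candidates are
  rejected, the accepted nonsyn/syn event ratio at neutrality matches the
  stop-excluded mutant-opportunity ratio, which sits ~5% below the raw
  NG86 N/S ratio — the tests assert both facts. No indels, no
  across-site rate variation.
* **Planted genes.** The CDS reverse-translates the profile consensus
  with the requested site residue; optional plants are the hexamer
  (GGG + TGC/TGT occupying the two codons after the TGA), a 9-bp G/C
  stem with the TGA in its loop, and N-/C-terminal fusion domains in
  frame with no intervening stop; the annotated interval covers the core
  gene bounded by in-frame TAA stops. SECIS presence is a boolean
  annotation on the gene, not a synthesized 3′-UTR structure.
* **Recoding windows** for the scanner place G/C stem arms (no
  homopolymer run of 3) in an adenine-only background. Adenine pairs with
  nothing in this composition, so the planted element is the unique
  maximum-weight structure — an explicit positive/negative control
  design. Real coding sequence folds far more promiscuously; scanner
  accuracy on these windows measures the classifier's geometry rules,
  not genome-scale specificity.
* **Marker panels** default to the surveyed study conditions: 223
  genomes, Sec trait 18%, SeU 16%, both 10%, orphan SelD 2%, Sec residue
  in 19% of SelD carriers. Counts are nearest-integer rounded, so the
  recovered fractions are exact by construction (58/223 = 26.0% SelD;
  54/58 = 93.1% of SelD genomes with SelA and/or ybbB). SelA is planted
  in every Sec-trait genome, matching its near-universal co-occurrence;
  the OR trait rule is still exercised separately in the tests.

## Problem sizes and determinism

All validation experiments are desk-scale: 16 leaves × 400 codons × 10
replicates for selection, 60 genomes for classification, 50–100 seeded
cases for the scanners, 20 seeds × 223 genomes for panels. Every
stochastic routine takes a seed or `numpy.random.Generator`; identical
seeds give byte-identical outputs, including through the CLI.

## Known limitations

* Profile alignment scoring is a package convention, not a
  re-implementation of any published gene-finder's internal scorer.
* Counting-method ω is biased downward under strong transition bias and
  long branches; use the trends, not the absolute values.
* The folding model ignores stacking energetics, pseudoknots and
  kink-turns; eukaryotic SECIS elements are out of scope by design.
* Gene finding from raw genomes, tRNA scanning, and database-backed
  domain naming are upstream/downstream of this package: marker presence
  and gene annotations are inputs.
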