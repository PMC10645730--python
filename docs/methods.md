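# Methods

This note records the models, conventions and tunable parameters behind
each stage, the design choices made where the design was genuinely open,
and what the synthetic data do and do not establish.

## Genome model and coordinates

Genomes are sets of contigs (linear or circular) with typed features:
`rRNA_16S/23S/5S`, `tRNA` (with isotype and anticodon), `CDS`,
`rep_gene` (with a Rep family label), `marker_gene` (with a marker id).
Coordinates are 0-based half-open internally and 1-based inclusive in
GFF3 on disk. Features never span a circular contig's origin: replicons
are serialized from a fixed origin, and the screen operates purely on
annotation intervals, so origin wrap-around adds nothing at the cost of
substantial interval arithmetic. rRNA subtypes are assigned from the GFF
type column plus a configurable product-keyword map (16S/23S/5S),
mirroring reliance on upstream annotation. Read depth from SAM counts
only primary mapped alignments (CIGAR M/=/X reference bases) to avoid
double-counting; breadth (fraction of positions covered ≥1×) is reported
but never used to exclude contigs from averaging.

## Screening cascade

Filters run in a fixed order; later filters are marked `n/a` after the
first failure so each exclusion is attributable to one rule.

| filter | rule | default |
|---|---|---|
| F_one_contig | exactly one contig bears any rRNA annotation | — |
| F_full_length | ≥2 rRNA genes at ≥ `min_full_fraction` of canonical length | 0.9 × (1500, 2900, 120 nt) |
| F_rep | ≥1 retained Rep hit on that contig | E < 1e-5 |
| F_length | contig length strictly < `max_contig_len` | 35,000 nt |
| F_no_marker | no configured single-copy marker on the contig | id list |

Choices made where the upstream procedure is underdetermined:
"full-length" is operationalized as a length fraction of the canonical
class length (annotation pipelines differ in how they flag partial
genes); "more than one full-length rRNA gene" is read literally as ≥2
(a ≥1 reading is a config switch); the one-contig rule counts contigs
with *any* rRNA annotation, full-length or not, which is the more
conservative exclusion; and the length rule is applied to the sole rRNA
contig after F_one_contig. The plasmid-contig dataset filter removes
single-contig genomes, the largest contig of complete genomes, and
contigs whose unique marker count exceeds 1 / 4 / 9 for lengths
< 54 kb / 54–800 kb / ≥ 800 kb.

## Translated Rep search

Each contig is translated in six frames (plain standard-code
translation, trailing partial codons dropped, N-containing codons → X)
and aligned to every panel peptide with affine-gap Smith–Waterman
(Gotoh), BLOSUM62, gap open 11 / extend 1 in the BLAST convention (a
length-L gap costs 11 + L). X is scored 0 against everything — neutral
handling of ambiguity. Significance uses Karlin–Altschul
`E = K·m·n·exp(−λS)` with gapped parameters λ = 0.267, K = 0.041 and the
raw search space m×n (no length adjustment; the threshold is
configurable to compensate). The exact external-tool parameterization
behind the published threshold is unrecoverable, so the parameters are
declared in config and the defaults preserve the threshold's semantics
at desk scale: an exact 80-aa panel peptide scores ≈ 400 (E ≈ 1e-40)
while the best random hit against a 10-kb contig scores ≈ 55
(E ≈ 10²) — the 1e-5 line separates them by many orders of magnitude.
Seeded heuristics, composition statistics and profile search are
deliberately out of scope; external tabular hits can be ingested
through the 12-column format instead.

## Copy number

A replicon's relative copy number is mean depth / baseline, where the
baseline is the length-weighted mean depth over the designated
chromosome(s) (equivalently, total chromosomal aligned bases over total
chromosomal length). Length-weighting matters only for multi-chromosome
genomes, where the unweighted mean would let a short secondary
chromosome dominate; a median option exists for robustness but is off by
default because the estimator is defined through averages. Effective
rrn copies per cell = Σ over replicons of ratio × complete-operon count.

## tRNA clusters and codon bias

Clusters are single-linkage chains of tRNA genes with end-to-start
distance ≤ 500 bp (inclusive), strand-blind — tRNA arrays commonly mix
strands and the adjacency rule says nothing about orientation.
Isoacceptor tallies key on the annotated isotype, so an Ile2 (CAU
anticodon, AUA-decoding) annotation stays distinct from Met.

Codon bias S uses the four two-codon pyrimidine families
Phe(TTC/TTT), Ile(ATC/ATT), Tyr(TAC/TAT), Asn(AAC/AAT):
`S_aa = ln[(C_HE+pc)/(U_HE+pc) ÷ (C_BG+pc)/(U_BG+pc)]`, weighted by HE
family totals (an equal-weight option exists). Pseudocount pc = 0.5
keeps S finite on sparse highly-expressed sets; pc = 0 recovers the
textbook ratio. Highly expressed genes are selected by a declared,
ranked product-keyword list (ribosomal proteins, then elongation
factors), truncated to n = 40 with ties broken by genomic order; a
shortfall warns rather than padding silently. Growth-rate regression on
codon usage is not reimplemented — codon tables can be exported for
external tools.

## Relative-rate dating

Given a rooted bifurcating tree with branch lengths b (substitutions
per site), a post-order pass computes each node's lineage mean path
length `L(u) = mean over children c of (b_c + L(c))`. Sister lineages
are assumed to have separated for equal elapsed times, so their rates
are set proportional to their lineage lengths, propagated from a
root-lineage rate of 1:
`r(c) = r(u) · 2(b_c + L(c)) / Σ_siblings (b + L)`.
Node heights are then the rate-corrected lengths `H(u) = L(u)/r(u)`,
which by construction agree along both child paths, and relative times
are H normalized to the root (root = 1, tips = 0). This variant
satisfies exactly the properties shared by published relative-rate
formulations: on ultrametric trees it reduces to normalized node depths
(clock limit), it is invariant to rescaling all branch lengths, times
decrease strictly root→tip on positive-length trees, and a cherry
(b₁, b₂) gets rate ratio b₁:b₂ with a common elapsed time. Zero-length
sister pairs are resolved by a 1e-9 rate floor with a warning.
Confidence intervals and sequence resampling are out of scope. An
optional outgroup designation excludes the outgroup side of the root
from normalization and leaves its rates uninterpreted. Calibrations:
a point value at node X fixes the global scale factor at T/t(X);
min/max constraints intersect to a feasible factor interval whose
midpoint is reported; an empty interval is an error naming a violated
pair.

## Gene gain/loss reconstruction

Presence/absence matrices (families × taxa, 0/1) are reconstructed
either by Sankoff parsimony with configurable gain/loss costs (defaults
1/1; root state by minimum total cost; *all ties resolve to absence*,
the conservative choice for gain counting) or by a two-state
continuous-time Markov model: free gain/loss rates optimized by bounded
L-BFGS on log rates, pruning-algorithm likelihood, stationary root
prior, and marginal (not joint) posterior states with argmax decoding,
ties again to absence. Events are parent→child state changes per branch;
a helper intersects gained-family sets across focal branches of several
clades. Birth–death family-size modeling is out of scope.

## Statistics

Chi-square independence is Pearson's statistic without continuity
correction (a Yates flag exists). Fisher's exact test enumerates the
hypergeometric distribution over all tables with the observed margins;
the two-sided p sums probabilities ≤ the observed table's. Mann–Whitney
U uses full enumeration of label assignments when the pooled sample is
≤ 12 and tie-free, otherwise the normal approximation with tie
correction. One caveat established empirically: the asymptotic
chi-square p tracks the exact Fisher p only in median (≈ 0.01) at
moderate sizes (n ≈ 100–200, expected counts ≥ 5); worst-case
discrepancies of ~0.1 arise from the exact test's discreteness, so the
tests assert median-level, not uniform, concordance.

## Synthetic forge

The forge emulates exactly the structures the analysis assumes:
background sequence i.i.d. uniform over {A,C,G,T}; planted genes reuse
deterministic template sequences at canonical lengths (16S 1500, 23S
2900, 5S 120, tRNA 76 nt) so homology search and full-length checks are
reproducible; operons are emitted in transcription order as
rrs–trnI–trnA–rrl–rrf; Rep genes encode a panel peptide exactly in
frame (the shipped panel is synthetic — deterministic random peptides in
four families — a stand-in for curated Rep panels); marker and
background CDSs draw synonymous codons uniformly so the genome
background is unbiased; highly expressed genes draw C-ending codons in
the four S families with odds `f : 1` (planting S = ln f). Trap
scenarios provide one negative per screen filter, giving the cascade a
complete truth table. Reads are fixed-length, uniformly placed within
each replicon at molar ratio length × copy number, substitution errors
only, with a truth SAM recording each read's origin.

What passing tests therefore show: the estimators recover planted
parameters from data satisfying their assumptions exactly. What they do
not show: robustness to annotation error, GC/coverage bias, indels,
partial assemblies, or diverged (non-identical) Rep homologs — real
screens inherit those risks from their annotation and mapping pipelines.

## Problem sizes and determinism

The bundled analyses use 40-genome cohorts with 50-kb chromosomes and
20–36-kb plasmids, 150-nt reads at 50× chromosomal depth (≈ 140–190 k
reads per simulation), 40 highly expressed + 40 background genes of 150
codons, and 5–8-taxon trees — sizes at which every planted parameter is
recovered well inside sampling error while the full suite runs in under
a minute. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical FASTA,
GFF and FASTQ output.
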