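# Methods

## Scope and model

`hortus` re-implements, as a tested library, the comparative analysis of
a plant-biomass-degrading microbial community metagenome (the leaf-cutter
ant fungus garden system): (i) top-hit taxonomic binning of assembled
sequences and reads, (ii) dual-evidence annotation of carbohydrate-active
enzymes (CAZymes) and best-hit COG assignment, (iii) cross-metagenome
clustering of functional proportion profiles, and (iv) fragment
recruitment of reads onto draft-genome pseudogenomes with identity
banding. Every stage can run either on hits produced by the built-in
aligner or on externally computed 12-column tabular hits, so the library
reproduces the analysis logic independently of any particular search
engine.

## Similarity search

The built-in search seeds candidate placements with exact k-mers
(default k = 11 for nucleotide, k = 4 for protein), then scores them
with an affine-gap local Smith–Waterman (match +1 / mismatch −1, gap
open 2 / extend 1 for nucleotide; BLOSUM62 with gap open 11 / extend 1
for protein; a gap of length g costs open + g·extend). Significance uses
the extreme-value form E = m·n·2^(−bits) with bits = (λS − ln K)/ln 2
and the standard ungapped +1/−1 nucleotide (λ = 1.28, K = 0.46) or
gapped BLOSUM62 (λ = 0.267, K = 0.041) constants, evaluated against the
size of the database actually searched. The retained-hit cutoff is
e ≤ 1e−05 throughout, matching the analysis being reproduced. Identity
is matches / alignment columns × 100. Ties on bit score break by lower
e-value, then lexicographically smallest subject id, making every search
deterministic. References ≤ 2 kb are aligned in full, so on desk-scale
pairs the result coincides with the full dynamic program (the test suite
checks this against an independently written DP oracle).

For fragment recruitment the per-read *identity* is instead taken from a
semi-global (infix) alignment of the entire read, computed as
100·(1 − edit distance / read length). Two reasons: the recruitment
statistic of interest is whole-read divergence from the reference, which
local alignment would bias by trimming mismatched ends; and edit-distance
alignments have equal-cost path ambiguity (an indel pair can substitute
for two mismatches), so defining identity over the fixed read length
makes the value path-independent. With the substitution-only read model
below, the identity of an error-free read from a strain at per-site
divergence δ is then exactly 100·(1 − Binomial(L, δ)/L), which is the
oracle the acceptance checks use. Candidate windows come from clustered
seed diagonals (clusters ≤ 32 bp apart merge; the two best-supported
clusters per genome are evaluated), and a local-alignment e-value gate
(same e ≤ 1e−05) excludes spurious placements of unrelated reads.

## Dual-evidence CAZyme annotation

A family database holds, per family: member protein sequences, one
correlated protein-domain model, and the family→domain correlation list.
A protein is annotated to family F iff it has a significant hit to a
member of F **and** a significant hit to F's correlated domain, both at
e ≤ 1e−05. Member evidence for F combined with domain evidence only for
an uncorrelated family confers nothing. One "module" is one
(protein, family) pair — a bifunctional protein contributes two modules;
multiple hits to members of the same family count once. Domain evidence
is implemented as similarity search against the domain's model sequence:
the contract retained from the original analysis is the *independent
second evidence channel keyed by the correlation list*, not any
particular profile-scoring engine. For nucleotide input, evidence is
gathered over all stop-free peptides (≥ 20 aa) of the six reading frames
and attributed to the contig, which makes annotation invariant under
reverse complement.

ORF calling is a naive six-frame maximal start→stop caller (default
floor 60 codons, a typical bacterial minimum), standing in for an
external gene predictor whose outputs the pipeline can equally ingest.

## Taxonomic binning and GC

Each query's best hit determines its superkingdom (Bacterial /
Eukaryotic / Viral); queries with no retained hit, or hits with
unresolvable taxonomy, are Unknown, so the partition is exhaustive.
Genus rank tables weight either sequence counts or total nucleotides
(for proteins, coding nucleotides = 3·residues + 3, stop included);
ranks descend by weight with lexicographic, flagged tie-breaks. Rankings
from different binning routes are compared side by side over the union
of genera (absent genera stay missing, not rank 0) with Spearman's rank
correlation over shared genera. GC content is (G+C)/(A+C+G+T) with
ambiguous bases excluded; per-group histograms default to 1% bins.

## Profile clustering

Per-metagenome feature counts become proportion rows (each row sums
to 1 over the union of features). Row correlation is Spearman with
mid-rank tie correction by default, with Pearson available — the source
analysis describes both and does not let one be singled out, so both are
implemented and the choice is recorded in outputs. Distance is the
simplest monotone transform d = 1 − r (the original transform is
unstated); 1 − r is not metric, and triangle violations are logged, not
rejected. UPGMA merges the closest pair at height d/2 and updates
distances by size-weighted average, with one numerical refinement: when
the two constituent distances are equal the common value is kept
verbatim, so ultrametric inputs round-trip through cophenetic distances
bit-exactly. Ties merge the lexicographically smallest pair. The tree is
emitted rooted (UPGMA is inherently rooted) in newick with branch
lengths; consumers may unroot. A metagenome's "nearest neighbor" is its
sister leaf/cluster at its first merge.

## Recruitment

Draft-genome contigs are concatenated in ascending length order by
default (descending available; the source material states both and the
choice is recorded in output metadata) into a pseudogenome with global
offsets, and coordinates map both ways. Recruited identities are binned
into 95–100 / 90–95 / 85–90 / 80–85 / 75–80 bands (half-open below,
topmost closed at 100; identities below the lowest band go to an
explicit below-range bucket; the lowest band follows the five-equal-band
reading of the source figure rather than the 70–80 variant in its text,
and is configurable). The strain-similarity statistic is the fraction of
recruited reads with identity strictly above 98%. Per-genome identity
summaries report mean ± sample SD for genomes with strictly more than
100 recruited reads. GC tracks use 10 kb windows at 1 kb steps (chosen
for smoothness at draft-genome scale) reporting deviation from the
genome-wide mean; reads aligned across a contig junction are flagged
rather than dropped.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes:

- **Genomes**: i.i.d. bases at a requested GC fraction, one per genus.
  The default community is six bacterial genera dominated by two
  enterobacteria-like genera (30% + 15%), over a tail of minor genera —
  the dominance structure of the target community — with genome
  surrogates of 40–60 kb so desk-scale runs stay fast.
- **Strains**: independent per-site substitution at rate δ ∈ [0, 0.25],
  uniform over the three alternatives (every substituted site differs
  from the reference); length preserved. No indels by default, keeping
  read identity analytically binomial.
- **Family genes**: each family has a random conserved motif (default
  40 aa, ≥ 10); members are the motif between random flanks; the
  correlated domain model is the motif itself. Planted genes are
  reverse-translated with random synonymous codons, framed by an
  in-frame stop before the start codon so a naive caller recovers the
  exact coordinates, placed without overlap on either strand, and fully
  recorded in a truth table.
- **Reads**: source genome drawn per abundance, uniform start, fixed
  length (default 250 bp, a typical pyrosequencing read length), i.i.d.
  substitution errors (default 1%). Forward-strand sampling is the
  default so the error-free read = exact substring contract is testable;
  recruitment aligns both orientations regardless.
- **Randomness**: each operation derives its own generator from
  seed + a fixed per-operation offset, so results are reproducible and
  operations do not share streams.

What the generator does *not* model — homopolymer error profiles,
repeats, plasmids, horizontal transfer, real codon usage, genome-scale
reference collections — bounds what the tests show: they validate the
analysis logic and its statistical behavior under the stated model, not
performance on real sequencing artifacts.

## Problem sizes and checks

The bundled checks run at desk scale by choice: 400 random matrices
(n ≤ 6) against a brute-force agglomeration oracle in the acceptance
script (1,000 in the test suite); 100 clustering replicates of four
communities (300 multinomial draws each); 400 error-free 250 bp reads
per strain at δ = 0.001 and δ = 0.03 against ~50 kb three-contig
pseudogenomes; three planted-gene contigs plus random decoys for the
dual-evidence recall/precision check. The recruited >98%-identity
fractions are asserted against the binomial-tail oracle
P(Binomial(250, δ) ≤ 4) within a 99% Monte-Carlo interval — near 1 at
δ = 0.001 and near 0 at δ = 0.03, the qualitative contrast between a
near-identical and a diverged symbiont strain. Reproducing the published
fractions for the real symbiont genomes requires the deposited reads and
draft genomes; the pipeline ingests them via external tabular hits, but
no bundled check depends on downloads.

## Known limitations

- The built-in aligner is for desk-scale fixtures; genuine metagenome
  scale should use an external search engine and `read_tabular_hits`.
- E-value constants are generic, not fitted to the scoring scheme per
  database; only the *thresholding contract* (e ≤ 1e−05 against the
  searched database size) is load-bearing.
- Domain evidence is sequence similarity to a model sequence, not a
  position-specific profile; with real domain databases a profile
  scorer should replace that channel behind the same interface.
- The COG stage assigns one best COG per protein; multi-domain proteins
  with several plausible COGs are not split.
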