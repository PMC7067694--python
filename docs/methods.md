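# Methods

This note documents the models and procedures implemented in `viromarker`,
the parameter choices that matter, and what the synthetic-data experiments
do and do not demonstrate.

## Translated marker search

Contigs are translated in all six frames with the standard genetic code;
stop codons are kept as `*` (they simply never align well) and codons
containing `N` become `X`. Each frame is aligned to every panel protein by
optimal local alignment (Smith–Waterman, affine gaps). Scoring defaults are
the standard gapped translated-BLAST constants — BLOSUM62, gap open 11,
extend 1, λ = 0.267, K = 0.041 — because the published protocol relies on
BLASTx defaults without restating them. A gap of length k costs
`open + k·extend`. Significance uses the Karlin–Altschul formula
E = K·m·n·e^(−λS) with m the translated frame length and n the total residue
count of the panel being queried; panels are searched one at a time, so the
viral (e ≤ 1e−10) and host (e ≤ 1e−30) ceilings can be applied at the search
step, mirroring the separate per-database queries of the protocol.

The alignment engine is Biopython's `PairwiseAligner` (C implementation of
the same recurrence); the test suite holds it against an independently
written full three-matrix DP oracle, itself cross-checked against explicit
path enumeration at tiny lengths. Among co-optimal alignments the engine's
canonical first path is reported; this is deterministic, which is what
downstream extraction needs. Protein-space coordinates are mapped back to
forward-strand nucleotide coordinates as
`nt = (frame − 1) + 3·aa` (reflected through the contig length for minus-
strand frames); because subject-gap columns consume no query residues, the
nucleotide span of a hit is always 3 × (aligned query residues).

No heuristic seeding is used: the search is exhaustive and intended for
desk-scale panels and contig sets, not BLAST-scale databases.

Externally produced hits enter through the 12-column tabular format
(`qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore`), with 1-based inclusive query coordinates and
`qstart > qend` marking minus-strand hits. The format cannot carry the
frame or the raw score, so round-tripping preserves exactly the twelve
representable fields.

## Candidate cascade

Hits are grouped per (contig, category); overlapping intervals are merged by
union and the merged region extracted, with the lowest-e-value hit providing
the reference, family and strand assignment. Filters, in order:

1. **Stringency** — e ≤ 1e−10 (virus) / 1e−30 (host), length strictly
   greater than 150 nt. The protocol's "greater than 150" is read strictly;
   both the boundary rule and whether the floor applies to hosts are
   configurable (`StringencyParams`), since the published text is ambiguous
   on both points (applied to both roles by default).
2. **Back-validation** — extracted viral candidates are re-searched against
   the comprehensive panel (all references, viral and host) with labels
   `viral`/`non_viral`. A best hit that is non-viral, a tie at the best
   e-value involving a non-viral subject, or no hit at all marks the
   candidate a false positive. Only viral candidates are subject to this
   check — the original refseq back-check targeted viral candidates; host
   candidates already passed the far stricter e−30 ceiling against a host
   panel. Using a user-supplied labelled panel instead of a live NCBI query
   keeps the step reproducible and offline.
3. **Completeness** — a candidate is *near-complete* when its amino-acid
   length (`floor(nt/3)`) is at least the length of the shortest protein in
   its panel, else a *fragment*. The comparison is done in amino acids with
   `≥` at the boundary; the source text names a protein length but states
   neither units nor boundary handling.

Near-full-length genome calls consume an externally produced domain-hit
table (no ORF prediction or domain scanning is performed here): an RNA-virus
candidate's source contig is flagged when it carries at least one structural
and one non-structural domain.

Dropped candidates are retained in the ledger with a drop reason, which is
what the filter-funnel report is computed from.

## Read recruitment and normalization

Read QC interprets the workbench's "score < 0.3" as the mean per-base
probability of correctness, `mean(1 − 10^(−Q/10)) < 0.3`; the floor is
configurable since the original tool does not define its score.

A read is recruited to a candidate when *some* local alignment covers at
least 90 % of the read's length at ≥ 90 % identity, identity counted over
aligned columns including gaps. The implementation proposes the best local
alignment (match +2 / mismatch −3, gap open 5 / extend 2), extends its ends
along their diagonals to span the whole read (the optimal-score path may
trim a mismatch-dense end that a qualifying lower-scoring window still
needs), then scans every contiguous sub-alignment for a qualifying window —
an O(columns) scan using cumulative match counts. Accepted reads carry a
certificate (the accepting window of alignment columns) that can be
re-verified directly against the raw sequences. A k-mer index (k = 15)
prefilters candidate pairings; the test suite checks decisions two ways:
anything accepted by an exhaustive ungapped evaluation over all diagonals
and windows must be accepted, and every acceptance certificate must
re-verify.
Multi-mapping reads go to the candidate with the best alignment identity,
exact ties to the lexicographically smallest candidate id — a deterministic
stand-in for unspecified mapper behaviour; fractional assignment is
deliberately not attempted.

Normalized expression is `count / ((len_nt/1000) · (library/10^6))` — counts
per kb of extracted candidate per million QC-passed reads. The published
normalizers (candidate length, library size) fix this up to a global scale,
which cancels in every downstream correlation; the per-kb-per-million scale
was chosen for familiarity.

## Ordination and environmental screening

Samples are compared by Bray–Curtis dissimilarity of square-root transformed
normalized abundances, with the dissimilarity of two all-zero samples
defined as 0. Non-metric MDS minimizes Kruskal stress-1
(`sqrt(Σ(d−d̂)²/Σd²)`) by alternating a Guttman transform with isotonic
regression of configuration distances on the dissimilarity order (primary
treatment of ties: tied dissimilarities may be fitted in any order).
Disparities are rescaled to the configuration's total squared distance each
iteration; if the rescaled stress ever increases the iteration stops and
the best configuration seen is kept, so the reported stress trace is
non-increasing by construction. Defaults: 20 restarts (the first
warm-started from classical Torgerson scaling, the rest random from the
seeded generator), 300 iterations, tolerance 1e−6.

Because the source protocol does not say whether environmental covariates
were screened against ordination axes or abundances, `env_correlation`
reports Pearson r against both — every nMDS axis and every virus-type
abundance row — ranked per variable by max |r|, with zero-variance variables
reported as missing and pairwise deletion of missing samples.

## Co-occurrence clustering and the network

Candidates (not samples) are the clustered objects. Pairwise Pearson r over
samples is computed on square-root transformed normalized abundances;
zero-variance rows are excluded with a warning. Hierarchical clustering is
group-average (UPGMA) linkage on distance 1 − r — the clustering tool used
originally defaults to group-average linkage but does not document it.
Determinism under ties is obtained by sorting candidate ids before linkage.

The SIMPROF test on a group of k ≥ 3 members: the observed similarity
profile is the sorted vector of the k(k−1)/2 pairwise correlations; the null
permutes each member's profile independently across samples; the mean null
profile is averaged over m₁ permutations; π = Σ|obs − mean|; the p-value
comes from m₂ further permutations as (#{π_null ≥ π} + 1)/(m₂ + 1).
Defaults m₁ = m₂ = 999, α = 0.05. The printed α = 0.5 of the source text is
almost certainly a typo for the conventional 0.05 — at 0.5 half of all null
splits would be called significant — but it remains selectable through the
configuration for anyone wanting to reproduce the printed setting.

The dendrogram is descended from the root: a node whose test rejects (its
members show more mutual association than independent profiles allow) is
split and its children tested; maximal non-rejected subtrees, plus groups
of fewer than three members (untestable by construction), are the output
clusters, which always partition the candidate set. Note a consequence of
the independent-profile null: a block of mutually correlated candidates is
itself "structure" and is decomposed until the pieces are too small to
test, so tightly co-varying virus–host pairs surface as two-member
clusters — which is exactly what the network step consumes. Resemblance
inside SIMPROF is Pearson r, matching the clustering basis, rather than a
community dissimilarity.

The network retains clusters containing at least one virus and one host and
draws an edge for every member pair with r > 0.8 (edge weight = r); nodes
left edgeless are dropped, and edges never cross clusters. The threshold is
applied per edge; the source text ("correlation coefficients greater than
0.8") does not resolve whether it meant per-edge or per-cluster. Exports:
Newick dendrogram, cluster membership TSV (with π and p), GraphML, and
Cytoscape-ready edge/node TSVs. The network encodes co-occurrence only; no
infection relationship is claimed.

## The synthetic community

The generator emulates the study design the analysis expects: 35 sample
libraries by default, marker-bearing contigs for ten categories (five viral
marker classes, three phage subcategories, two host classes), decoy contigs,
planted virus–host abundance correlations, and environmental covariates.

- **Panels.** Each category gets one random ancestor protein (130–190 aa)
  and members at 12 % amino-acid divergence from it, so within-category
  similarity (~80 %) far exceeds the ~5 % expected between independent
  random proteins; the category signal lives in protein space, as in a
  protein-level search. The shortest member defines the completeness
  threshold.
- **Contigs.** Each candidate contig embeds a back-translation (uniform
  random synonymous codons) of one panel protein, mutated at 5 % per
  nucleotide by default, on a random strand, between random flanks of
  120–320 nt; coordinates and strand are recorded in the truth table.
  Decoys are random-composition sequences with no planted marker, giving
  the filter cascade genuine negative controls.
- **Abundance.** Log-scale model `x[i,s] = μᵢ + lᵢ·t_s + σ·ε`, with t a
  latent community axis (loadings ~ N(0, 0.5)) that linked environmental
  variables track. Planted (virus, host) pairs instead share a pair factor
  with loading √|ρ|, so their log-profiles correlate at ρ (measured mean
  0.898 for ρ = 0.9 over 100 seeds; background mean |r| ≈ 0.19). Note that
  ρ is a log-scale quantity: after Poisson read sampling, normalization and
  the square-root transform the realized correlation attenuates (≈ 0.76 on
  the analysis scale for ρ = 0.9 in the worked example), which is the
  realistic behaviour of count data.
- **Reads.** Per-contig per-sample counts are Poisson around the expected
  matrix, scaled so mean library size sits mid `library_size_range`
  (default 2 000–6 000 reads — desk scale; the statistical structure, not
  throughput, is what downstream steps consume). Reads (default 100 nt,
  an Illumina-like length) are sampled uniformly along contigs on random
  strands; per-base Phred qualities are drawn around the nominal quality of
  the configured error rate (default 0.5 %) and errors are Bernoulli at
  each base's own quality, so the quality filter is exercised by real
  variation rather than a constant. Library sizes are the realized totals;
  every read carries its source contig, and the truth table's attribution
  matrix sums exactly to the reads emitted.

Seeding: every stage draws from `default_rng([seed, stage_index])`, so each
generator is deterministic in isolation and identical seeds give
byte-identical output files.

### What the synthetic experiments show — and what they do not

Passing the planted-structure and truth-recovery checks demonstrates that
the pipeline's machinery is correct: exact extraction coordinates at zero
noise, calibrated SIMPROF type-I error, recovery of planted correlations as
network edges, no decoy leakage. It does **not** demonstrate performance on
real metatranscriptomes: real marker families share deep homology across
categories (the generator's categories are independent), real assemblies
contain chimeras and strain mixtures, real abundance distributions are
heavier-tailed than log-normal, and real libraries are three orders of
magnitude deeper. Claims about, e.g., the fraction of viral reads in a real
bloom cannot be validated here.

## Numerical and scale choices in the checks

The boundary experiment for the 90/90 rule plants an exact divergence
fraction (round(0.08·L) or round(0.15·L) substitutions at random positions)
rather than Bernoulli-per-base noise: the rule's discrimination is a
statement about reads *at* a divergence, and exact-fraction reads of 100 nt
separate cleanly (measured 100 % accepted at 8 %, 0.5 % at 15 %), while
Bernoulli noise at Illumina lengths straddles the 90 % identity threshold
for any decision rule. The SIMPROF calibration uses 200 null datasets of
20 × 35 with 199 + 199 permutations; pair-recovery uses 50 runs of 30
candidates × 35 samples; the end-to-end determinism check runs a reduced
community (7 candidates, 8 samples, libraries of a few hundred reads) twice
and compares file hashes. These sizes keep the full verification suite to a
few minutes on one CPU while leaving the statistical margins wide.

## Known limitations

- The translated search is exhaustive (no seeding heuristics); panels and
  contig sets beyond desk scale belong in BLASTx, whose tabular output the
  pipeline ingests directly.
- Recruitment evaluates the 90/90 criterion on windows of the single
  best-scoring local alignment per orientation (diagonally extended to the
  full read span); a read whose only qualifying alignment lies off that
  path entirely could in principle be missed, though the ungapped
  exhaustive check has not observed this after the extension.
- SIMPROF p-values are permutation estimates; with m = 999 the smallest
  attainable p is 0.001, and repeated testing down the dendrogram is not
  multiplicity-corrected (the standard practice for this procedure).
- The nMDS stress surface is non-convex; restarts mitigate but cannot
  guarantee the global optimum.
- Host discovery reuses the viral machinery with a polymerase panel at
  stricter stringency; no attempt is made to resolve host taxonomy beyond
  best-hit family labels.
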