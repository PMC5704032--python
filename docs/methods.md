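# Methods

This note documents the models and procedures implemented in
`twinquad`, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical and design
choices made where several reasonable options existed.

## Variant identity and the high-confidence filter

Small sequence changes (SSCs: SNVs, insertions, deletions, block
substitutions) are compared across samples by canonical key
`(chrom, pos, ref, alt)` after normalization: shared terminal bases are
trimmed (extending leftwards from the reference when an allele would
empty) and shared leading bases removed, i.e. standard VCF
left-alignment. Presence/absence of a key is the only genotype notion
used — zygosity is ignored, because the sharing analysis only asks
whether a variant was called in a sample at all.

The high-confidence filter keeps calls with read depth ≥ `min_depth`
(default 50) and call quality ≥ `min_quality` (default 100, phred-like,
taken from the VCF QUAL column and applied site-level). Both thresholds
are met at equality; calls with unknown depth or quality fail. By
default the *parental* presence check for de novo labelling uses
unfiltered parental calls: a true parental variant that merely failed
the depth cut must not manufacture a false de novo
(`filter_parents=True` switches to filtered-only).

Coordinates: VCF positions are 1-based; CNV/SV intervals are 0-based
half-open, so event length is always `end − start` (the bundled
unique-CNV table satisfies this exactly, e.g. chr15:22422114–22492114 is
70 000 bp).

## Sharing and origin classification

For each twin: `shared` = keys present in the co-twin; `unshared` =
the rest; in quad mode `inherited` = unshared keys present in ≥ 1
parent and `de_novo` = the remainder, so
`|inherited| + |de_novo| = |unshared|` holds identically. Without
parents every unshared call is `provisional_de_novo` — an upper bound
on the post-zygotic set, since co-twin call dropout of inherited
variants also lands there. Both twins are classified symmetrically;
the report exposes unshared counts both before and after the
confidence filter because summary tables in this field are ambiguous
about which is printed.

## CNV/SV equivalence

Interval events (CNVs; SV deletions, tandem and distal duplications)
are the same iff they show ≥ 50% *reciprocal* overlap — the overlap
must cover at least half of *each* event, so a small event nested in a
large one never matches. CNVs must additionally agree in copy direction
(amp: state > 2; del: state < 2); cross-category matches are never
attempted. Interchromosomal events match iff origin and destination
chromosomes agree and *both* junction distances are strictly < 500 bp
("less than" is read strictly; the plural junction rule requires both
breakpoints). Inversions must share their direction and reach the
reciprocal-overlap threshold; "identity" is implemented as positional
overlap, not sequence identity — no other matcher in the pipeline
compares sequence, and the alternative reading is noted here rather
than mixed in.

Reciprocal overlap at a threshold is reflexive and symmetric but not
transitive, so merged groups are the connected components of the
pairwise match graph: a chain A~B~C forms one group even when A and C
do not match directly. This mirrors the merged-group semantics of
interval-merging CNV comparison tools.

## Annotation

Gene regions are assigned per overlapping gene with precedence
splice site > exonic (CDS) > UTR > promoter > intronic. The windows are
conventions, configurable because the vocabulary does not fix them:
promoter = 2000 bp upstream of the transcript start (strand-aware),
splice site = the 2 intronic bases flanking each internal exon
boundary. Translational impact: SNVs are translated codon-wise
(strand-aware, standard code) into synonymous / missense / stop-gain;
length-changing variants are frameshift iff the net length change is
not a multiple of 3, else in-frame; a variant straddling a CDS boundary
is reported `complex` with a warning rather than guessed. When a gene
has several transcripts the first is used and logged. Population flag:
`polymorphic` iff the canonical key appears with frequency > 0 in any
supplied frequency table, `novel` otherwise. The biological-context
filter is a flat one-step gene→tag lookup (proprietary knowledge-graph
"direct connection" semantics are out of scope); an empty tag list is
the identity filter with a warning.

## Over-representation and the GP/GPD comparison

For a query of n genes against a set of K genes in a universe of N
(default: the union of the collection), p = P(X ≥ k) with
X ~ Hypergeom(N, K, n), computed via the survival function in log
space. Ranking is by raw p with ties broken by canonicalized set name
(lowercase, collapsed whitespace) so top-k lists are deterministic;
BH q-values are reported but not used for ranking. Both background
modes (collection union or a user universe) are supported; no claim is
made that either reproduces any proprietary pathway tool's background,
so printed p-values from such tools are context, not targets.

GP/GPD: within a family, GP = affected ∩ unaffected top-k name sets and
GPD = affected \ unaffected. Across families,
`shared_affected` = ∩ affected lists and
`final_gpd` = shared_affected \ ∪ unaffected lists (the ≥ 3-family
generalization is the obvious intersection/union extension).
Membership is by name only — no p-value weighting — because pathway
ranks from different individuals are not on a common scale. Name
variants that collide after canonicalization are reported, never
silently merged.

## The synthetic quad generator

The generator emulates the *statistical structure* the analysis relies
on, at desk scale (defaults ≈ 1/1000 of realistic per-genome totals:
1800 SNVs + 200 indels + 38 block substitutions per parental pool, so
each twin carries ≈ 3600/400/76; Ti/Tv = 2.1; ~147 CNVs and ~92 SVs per
twin with deletions dominating the SV mix; 4 post-zygotic SSCs,
7 discordant-inherited decoys, 5 de novo + 2 inherited unique CNVs per
twin, mirroring published per-individual count matrices at 1/1000 for
SSCs and near-full scale for the already-small CNV counts).

Design choices:

* **Transmission** — every parental-pool variant is present in the
  parent and in both twins (MZ twins share their germline; Mendelian
  sampling of untransmitted parental variants is not modelled). This
  makes count invariants exact: doubling a pool exactly doubles the
  twins' shared count. Simulated parents therefore carry about half a
  twin's total; only class proportions matter downstream.
* **Discordant-inherited decoys** (parent + one twin only) emulate
  co-twin call dropout, the mechanism that makes a large fraction of
  real unshared variants classify as inherited.
* **Mosaicism** — each post-zygotic variant gets a cell fraction f;
  default f ~ Beta(2, 5) (mean ≈ 0.29, right-skewed), chosen to
  resemble reported minority fractions around 20%; `("fixed", f)` is
  available for controlled experiments. Dropout: the variant is kept
  iff Binomial(depth, f/2) ≥ a detection floor (default 3 reads) —
  f/2 because a heterozygous somatic variant in a fraction f of cells
  has allele fraction f/2. Dropout applies to small variants only;
  events carry no per-call depth in the interchange format.
* **Depth/quality** — depth ~ Poisson(mean 100) so essentially every
  planted call clears the depth-50 filter in noiseless runs; quality is
  constant 200 for planted calls, with optional low-quality decoys at
  30 to exercise the filter.
* **Events** — planted events never overlap one another (placement
  keeps ≥ 1.5 kb spacing), so distinct events cannot spuriously satisfy
  the 50% rule or the 500 bp junction rule; non-carrier samples receive
  a jittered copy (≤ 8% of length, junctions ≤ 200 bp) so equivalence
  must be established by the matcher, not by coordinate equality.
* **Pathway spiking** — `spike_sets` places a configurable fraction
  (default 0.8) of the affected twin's somatic SNVs inside the named
  sets' genes, round-robin across sets; all other placements (both
  twins, SSCs and events) then avoid those genes, so the planted
  condition "these pathways are hit only by the affected twin's somatic
  variants" holds exactly.
* **Determinism** — one seed spawns three independent streams (reference, quad,
  dropout) via `numpy.random.SeedSequence`; reruns are byte-identical.

What the generator does **not** emulate: reads (no FASTQ), linkage
disequilibrium and realistic allele-frequency spectra, GC bias or
read-depth noise in CNV calling, sequencing error, and caller-specific
artifacts. Passing tests therefore demonstrate the *logic* of the
pipeline — classification, matching, enrichment and the threshold
comparison are each exactly right on inputs with known truth — not
robustness to upstream calling noise in real genomes.

## Validation experiments

`twinquad.experiments` packages the protocols used by the test suite
and `scripts/acceptance.py`:

* **Two-family recovery** (noiseless): two quads share a reference and
  a gene-set collection; each affected twin is spiked in one
  family-specific pathway plus one pathway common to both families.
  De novo precision/recall are measured against planted truth, and the
  cross-family comparison must return exactly the doubly planted
  pathway. Enrichment runs with top_k = 2 here — the number of truly
  enriched sets per individual — because with only two non-null sets a
  top-20 list is padded with p ≈ 1 names in arbitrary (tie-broken)
  order; the pipeline default stays 20.
* **Mosaic degradation**: fixed cell fractions (0.9, 0.5, 0.2, 0.1,
  0.05) at Poisson-100 depth and floor 3; recall of post-zygotic SSCs
  should be ≈ 1 down to f ≈ 0.2 and collapse below, monotonically.
* **Null calibration**: random queries (n = 30) against 20 disjoint
  10-gene sets in a 200-gene universe. Hypergeometric p-values are
  discrete, so the exact attainable size at the 0.05 level is
  P(X ≥ k*) = 0.0455 for this geometry; the empirical rejection rate is
  compared to that analytic value (within binomial tolerance), not to
  0.05 itself.
* **Oracle agreement**: the reciprocal-overlap matcher against
  base-by-base position counting on 1000 random pairs, and the
  hypergeometric tail against exact rational enumeration for every
  configuration with N ≤ 25.

## Degenerate inputs and numerical notes

Empty enrichment queries return an explicit empty result with a
warning; duplicate keys within one sample are deduplicated with a
warning; zero-length intervals, impossible hypergeometric
configurations, negative thresholds and mixed-category group builds
raise typed errors (config error → exit 2, parse error → 3, contract
violation → 4 in the CLI). Hypergeometric tails use scipy's log-space
survival function (max |error| vs exact enumeration ≈ 3 × 10⁻¹⁶ over
all N ≤ 25). Tie-breaks everywhere are lexicographic on canonicalized
names, so outputs are permutation-invariant and reproducible.

## Known limitations

Real upstream callers produce no-call regions; the pipeline assumes
fully called genomes (absence of a key means absence of the variant)
and only counts declared no-call overlaps as a warning. Parent-of-origin
is not resolved (a variant in either parent is just "inherited");
germline-vs-early-embryonic timing of shared de novo variants is out of
scope; inversion matching is positional; and annotation uses one
transcript per gene.
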