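# Methods

`tyscape` annotates the Ty retrotransposon landscape of *Saccharomyces
cerevisiae* genome assemblies and compares it across strains.  This note
describes the models and procedures each stage implements, the parameters
that matter, what the synthetic benchmark does and does not emulate, and the
design choices that were genuinely open.

## The alignment engine

All detection is similarity search against a query panel, so the package
carries its own local-alignment engine with two routes to the same answer:

* `smith_waterman` — the exact affine-gap dynamic program (gap of length L
  costs `gap_open + L*gap_extend`), used as the oracle, for part-wise
  hybrid scoring, and for short sequences.
* `seeded_search` — exact k-mer seeding (default word size 11), an x-drop
  ungapped prefilter, and banded DP around the seed diagonals (band pad 32
  diagonals), suitable for megabase subjects.  Whenever the true alignment
  contains at least one exact seed word, the banded alignment equals the
  full DP; the test suite checks this against an independently written
  plain-Python DP on hundreds of random pairs.

Scoring defaults are megablast-like: match +1, mismatch −1, gap open 2, gap
extend 1.  Reporting thresholds — `min_score` 30, `min_identity` 0.70,
`min_length` 80 nt — are set so that family LTRs diverged up to ~25% are
found while the expected count of random 80-nt pseudo-hits in a megabase
genome is far below one (Gumbel tail at score 30 with these scores).  All
of this is exposed through `AlignmentParams` and captured in the run
MANIFEST.

N and soft-masked (lowercase) bases are unmatchable: they score as
mismatches, cannot seed, and are excluded from both sides of the identity
fraction.  This is what makes flank masking (below) safe.

Coordinates are 0-based half-open everywhere internally and converted to
1-based only in GFF3 output.  Hits of the same query and strand separated
by fewer than 20 nt are merged to the widest hit, re-joining alignments
split by indels.

## Stage 1 — LTR census

Each family's LTR query is searched against every contig, both strands.
Where hits of *different* families overlap by ≥50% of the shorter hit, the
better score wins (ties keep the lexicographically first family and are
flagged).  A truncated LTR hit of at least `min_length` (80 nt) counts as
one LTR copy; shorter fragments go to a side table and never enter counts.
The census table is strains × five families plus a total.

## Stage 2 — element classification

TYA/TYB similarity hits are collected genome-wide, then each LTR hit is
interpreted by its coding context:

* **full element** — two same-family, same-strand LTRs 4–8 kb apart (outer
  edges) with interior TYA then TYB in the orientation the strand implies.
  Adjacency is enforced: the coding hit must begin within 120 nt of the
  LTR's inner edge.  The 120-nt tolerance is deliberate: a Ty1/2 hybrid's
  LTR matches the Ty1 query over its 5' ~90 nt and the Ty2 query over its
  240-nt U3, so the Ty2-anchored pair needs ~90 nt of slack, while two
  independently planted neighbours are kept ≥150 nt apart by the generator
  and can never fake adjacency.
* **relic** — an LTR with adjacent TYA but no TYB and no terminal LTR.
* **solo-LTR** — an LTR with no adjacent coding sequence at all.
* **fragment** — coding sequence without a resolvable element (broken or
  nested copies), or an LTR+TYA+TYB run missing its far LTR.

LTR hits of another family that abut a constituent LTR within 20 nt are
absorbed into the element — that is the two-query signature of one physical
hybrid LTR, not two elements.

Ty1-vs-Ty2 identity of a coding element is decided by the best alignment
score of its coding sequence against a reference set of characterized
non-hybrid full elements; the margin between the two families is recorded,
and a zero margin keeps Ty1 but flags the element ambiguous.  Ty3/Ty4/Ty5
skip this step — their LTR scan already separates them.

Hybrid status is called from parts: TYA, TYB and the terminal 240-nt LTR-U3
are each assigned a family by best score.  Ty1 TYA + Ty2 TYB + Ty2 U3 is a
**full hybrid**; an otherwise pure Ty1 whose final 60 nt of TYB score Ty2
(by global alignment of the tail) is a **short hybrid**.  When only a
≥300-nt 3' segment exists and it scores Ty2, the element is labeled
**indistinguishable** — a real Ty2 and a long hybrid cannot be told apart
from that much sequence, so the pipeline refuses to guess.

The orientation check is coordinate order on the strand, not ORF
translation: classification is similarity-based throughout, and ORF
intactness is out of scope.

The Ty1/Ty2 ratio is reported per strain as full-Ty1 over full-Ty2 with
explicit flags (`no_Ty2`, `no_coding`) instead of division errors; relics
are excluded from the active counts and listed separately.

## Stage 3 — insertion atlas

For every element, up to 2,500 nt of flank is taken on each side
(truncation at contig edges is recorded).  Any panel similarity inside a
flank is masked to N before mapping, so repeated Ty sequence cannot anchor
the placement.  The masked flank is mapped to the reference by seeded
search; a placement is **unique** when the best element-side-anchored
alignment beats the runner-up by a score margin (default 30) and covers at
least half of the unmasked bases.  "Element-side-anchored" means the
alignment reaches within 50 nt of the flank end that touches the element —
this keeps a flank whose middle contains somebody else's insertion (absent
from the reference) from extrapolating across the gap.  The reported locus
position is the reference coordinate of the element-side flank end, i.e.
the insertion junction.  The left flank is tried first, the right flank is
the fallback; elements with neither flank placeable are counted unmapped.

Same-family junctions within 40 nt on the same reference contig merge into
one locus by single linkage.  The 40-nt window covers the 5-nt target-site
duplication plus mapping jitter; loci the generator plants are kept ≥150 nt
apart, so truth loci never merge.  A strain contributes at most once per
locus (boolean presence), which is also how nested same-locus copies are
represented.

From the loci come, per family: the strains × loci presence/absence matrix;
the occupancy spectrum (default normalization: insertion events at loci of
occupancy k over all insertion events, so the spectrum sums to 1; a
per-locus mode is available since either reading of "normalized by the
total number of insertions" is defensible); the Pol III proximity fraction
(locus window within 1,000 nt of an annotated tRNA gene — the Ty1–Ty4
target windows are sub-kilobase); and hierarchical clusterings of strains
and loci (binary Jaccard distance, average linkage, deterministic;
dendrograms serialized as Newick with heights).

## Stage 4 — subfamily phylogeny

TYA300 is the 300 nt immediately interior to the 5' LTR; TYB300 the 300 nt
interior to the 3' LTR; both strand-normalized to coding orientation.
Relics contribute TYA300 only; elements with less than 300 nt of coding
sequence are skipped and logged.  These segment ends are used because they
are the best-assembled, most family-discriminating parts of the coding
region.

Segments are aligned progressively: UPGMA guide tree on 6-mer distances,
then profile–profile global affine alignment at each merge ("once a gap,
always a gap").  A full reimplementation of any particular published
aligner was not attempted; for 300-nt segments of ≥80% identity the
progressive result is effectively indel-free and alignment differences are
immaterial.

Pairwise distances use the HKY85 substitution model, computed analytically
through the Tamura–Nei closed form with its equal-transition-rate
constraint and base frequencies pooled empirically from each pair.
Gap/N columns are excluded per pair (pairwise deletion — preserves signal
on 300-nt segments).  Saturated pairs return +infinity and are rejected by
the tree builder with the offending pair named.  Under equal base
frequencies and transition proportion equal to half the transversion
proportion the formula reduces to Jukes–Cantor, which the tests verify to
1e-9, and simulation under the full model recovers planted distances.

Trees are Saitou–Nei neighbor joining with the standard Q-criterion,
lexicographically smallest pair on ties, negative branch lengths clamped to
zero with the deficit moved to the sister branch, and an unrooted
trifurcating Newick output.  NJ is exact on additive matrices; the tests
round-trip a known 6-taxon tree to 1e-9 and cross-check topologies against
an independent NJ implementation.

Subfamily labels come from nearest-exemplar global identity with a 0.95
threshold: planted 89–92%-identity TYA variants split from canonical Ty1
while within-family copies (≥98%) do not.  Segments below threshold to
every exemplar are clustered among themselves by single linkage at the same
threshold and labeled `novel1`, `novel2`, ….  TYB300 segments whose first
240 nt assign Ty1 but whose final 60 nt assign Ty2 are called
`short_hybrid` before exemplar matching — a short hybrid's TYB300 is 96%
identical to Ty1 and would otherwise be absorbed into the Ty1 cluster.

## The synthetic benchmark

The generator builds what the analysis assumes and nothing more:

* **Templates.**  Five families with mutually unrelated LTRs (global
  identity ≈0.45–0.55, well under the 0.60 ceiling) and full elements of
  LTR+TYA+TYB+LTR with identical LTRs at both ends (LTR ~250–370 nt, TYA
  1,300 nt, TYB 3,600 nt).  Ty2's coding genes are derived from Ty1 at 80%
  identity — closely related but separable, like the real pair.  Subfamily
  variants are substitution-only copies of a region at a controlled
  identity (defaults: TYA at 0.89 and 0.92, echoing the identities at which
  real Ty1 variants were distinguished).  Hybrid templates follow the
  recombination structure: full hybrids carry Ty1 TYA, Ty2 TYB and Ty2's
  240-nt LTR-U3; short hybrids a 60-nt Ty2 TYB tail.
* **Planting.**  Elements are inserted with a 5-nt target-site duplication
  (the canonical Ty TSD; the analysis never assumes it) into an i.i.d.
  random background carrying 72-nt tRNA marker genes (25 per Mb).  A
  fraction of insertions (default 0.62, the observed Pol III-proximity
  rate) is placed 50–700 nt from a tRNA gene, the rest uniformly; all
  junctions keep ≥150 nt separation so distinct planted loci stay distinct
  at the 40-nt clustering window.  Solo-LTRs are planted as one LTR between
  TSD copies — the footprint of inter-LTR recombination; relics as
  LTR+TYA.  Per-copy divergence is substitution-only at a configurable
  rate.
* **Panels.**  A configurable fraction of insertions (default 0.5) is
  ancestral: present in every strain at the same background coordinate
  under the same locus id; the rest are strain-specific.  The default
  per-strain composition plants 54 LTR copies of which 59% are Ty1 and 8
  belong to full coding elements, mirroring the family proportions a
  real strain census shows at desk scale (8 strains × 1 Mb, 50 insertions
  per strain).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: indels and rearrangements within elements
(substitutions only), assembly fragmentation and collapsed repeats, real
chromosome structure and base composition, heavily nested Ty1 arrays
(nesting is available as a probability but defaults to 0 and is only
explored as a property sweep), and ORF-level degeneracy.  On real
assemblies the detection thresholds are the knobs to revisit first.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the package's
own benchmark conditions: the exact-recovery panel is 8 strains × 1 Mb at
divergence 0; divergence robustness uses 50 replicate 120-kb strains at 5%
divergence; Pol III recovery uses 20 replicate 2-strain panels; distance
recovery uses 100 simulated 10-kb pairs.  Determinism is bit-level: every
stage is seeded through `numpy.random.SeedSequence` spawning, dictionary
orders are sorted, and two same-seed runs produce byte-identical
TSV/BED/Newick/FASTA/GFF3 artifacts.

Degenerate inputs are handled explicitly: empty sequences and empty
assemblies are input errors; a zero-score alignment is an empty sentinel,
not a hit; an empty presence/absence matrix refuses a spectrum; fewer than
three taxa refuse a tree; a strain with no coding elements appears in every
table with zeros rather than being dropped.

## Known limitations

* Counts are query-panel-bound: an LTR family absent from the panel is
  invisible (no de novo repeat discovery).
* Hybrid LTRs are counted once per matching query family in the raw LTR
  census (the element layer resolves them); censuses on hybrid-rich
  genomes should be read from the element tables.
* The indistinguishable label is a refusal, not a call — elements known
  only from a 3' segment cannot be split between Ty2 and long hybrids.
* Fragmented nested elements can break LTR pairing; the affected copies
  surface as `fragment` rather than being silently dropped, but their
  true category is not recovered.
* PBS (primer-binding-site) variant annotation would need curated PBS
  coordinates per family and is out of scope; segment sequences are
  reported raw.
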