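# Methods

`culturegap` scores species-level 16S rRNA OTUs from multiple amplicon
surveys by how far each sits from laboratory culture, how abundant it is
once sequencing depth is normalized away, and how consistently it appears
across surveys.  This note documents the model behind each stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Pipeline model

**Cleaning.** Surveys deposit reads in mixed orientations over different
16S windows.  Orientation is decided by k-mer voting against a reference
16S sequence (k = 12 by default): a read keeps the orientation that shares
more k-mers with the reference; reads sharing none (or tying) in both
orientations cannot be placed and are dropped.  Trimming to a homologous
region uses two short conserved anchor motifs derived from an alignment of
the dataset's sequences: a column is conserved when its modal residue
reaches the conservation threshold (0.9), the 5′ anchor is the first
`anchor_length` (12) columns of the first conserved run of at least that
length, and the 3′ anchor is the last such columns of the last run.  Each
read keeps the span strictly between its best anchor matches (Hamming
distance over a sliding window, at most 2 mismatches, no indels — anchors
are short conserved motifs, and indel handling would add cost without
benefit at this scale; ties go leftmost for the 5′ anchor and rightmost
for the 3′ one, maximizing the retained span).  Reads missing either
anchor, with anchors in conflicting order, or shorter than the
dataset-specific minimum length (default: half the inter-anchor span) are
excluded and tallied.  A dataset is retained only when the best ungapped
mapping of its consensus onto the reference contains the required
interval — the V1+V2 window in the default configuration.

The anchor-derivation step assumes an alignment.  The pipeline feeds it
the representatives of a quick pre-trim clustering restricted to the modal
read length, which is exact for no-indel amplicons; for indel-rich data,
anchors should be supplied explicitly (`--anchors`).

**Clustering.** Percent identity is defined from a global alignment with
affine gap costs (match +1, mismatch −1, gap open −5, extend −1); identity
= identical aligned positions divided by the shorter sequence's length,
the convention greedy clustering tools use for mixed-length reads.
Clustering is greedy and incremental at 97%: reads are processed longest
first (ties broken by id, which also makes results independent of input
file order), each read joins the first existing cluster whose
representative it matches at or above the threshold, otherwise it founds a
new cluster.  A word filter skips alignments that provably cannot reach
the threshold: a pair at identity ≥ t over the shorter sequence (length n)
must share at least n−(k−1)−k(1−t)n exact k-mers (k = 8), since each
non-identical position breaks at most k windows; a small slack of one
window length absorbs repeated words.  The filter only ever skips pairs
that are certainly below threshold, so results match the unfiltered
semantics.

**Chimera screening.** A read is called chimeric when some crossover
position and ordered pair of candidate parents (A, B) exist with prefix
identity to A ≥ 0.99, suffix identity to B ≥ 0.99, and full-length
identity to both ≤ 0.97 — the signature of a PCR template switch between
two more-abundant templates.  Candidate parents must carry at least twice
the query's cluster abundance (the thresholds are package defaults; the
screening idea follows duplicate-clustering chimera detectors).  In the
pipeline the screen runs on tier-1 cluster representatives: a chimera of
sufficiently divergent parents founds its own (low-abundance) cluster,
and all reads of a flagged cluster are discarded.  Chimeras whose
crossover falls inside a conserved stretch are near-identical to one
parent, merge into its cluster, and are intrinsically undetectable by any
crossover method; they only perturb that parent's count by a few percent.

**Universal OTUs.** Per-dataset representatives and representatives of the
cultured-isolate pool (clustered at the same threshold) are first sliced
to the reference window shared by all surveys — each dataset's covered
interval is the *modal* mapped interval of its representatives, so a rare
mis-trimmed fragment cannot shrink the shared window — and then greedily
clustered again at 97%.  Member tallies are aggregated per source dataset;
an OTU *contains culture* iff a cultured representative merged into it.
This two-tier design lets each survey be clustered on its full covered
region while cross-survey comparison happens on the common window only.

**Phylogeny.** The default tree is neighbor joining over p-distances
(mismatches / compared positions, gaps excluded) between universal-OTU
representatives; ingesting an externally built newick tree is supported
and preferred when a maximum-likelihood tree is available.  NJ is
implemented deterministically: taxa in sorted order, Q-matrix ties broken
row-major, negative branch-length estimates clamped to zero.  The
culturability score of an OTU is its patristic distance to the nearest
tip whose cluster contains a cultured isolate, zero when its own cluster
does (the zero-rule).  The search runs as a two-pass dynamic program
(down-pass: best cultured tip within each subtree; up-pass: best via the
parent), linear in tree size and verified against brute-force minimization
in the tests; equidistant cultured tips resolve to the lexicographically
smallest id — determinism over biological meaning.  Pruning to the
survey-only subtree removes tips and collapses the resulting degree-2
nodes with branch lengths summed, so all kept pairwise distances are
preserved (≤ 1e-9 in the tests).  Root placement is arbitrary and never
affects path sums (asserted by a re-rooting test).

The published analysis subdivided its tree into clades by hand; that step
cannot be reproduced mechanically, so the package substitutes a
thresholded partition: top-down, a subtree becomes one clade iff its
maximal within-subtree tip-to-tip distance is at most the threshold,
otherwise its children are visited; every clade is monophyletic or a
singleton.  The threshold is an explicit configuration value (CLI default
0.25 substitutions/site) with no claimed equivalence to the manual
subdivision.

**Abundance and prevalence.** Library sizes are normalized by the trimmed
mean of M-values (TMM) with the original method's defaults, since the
analysis this package re-implements names only the method: reference =
dataset whose upper-quartile relative abundance is closest to the mean of
upper-quartiles; per-OTU log2 fold-changes (M) and average log2 abundances
(A) over OTUs nonzero in both; double trim (30% of M, 5% of A, by ranks);
factor = 2^(precision-weighted mean of surviving M), weights = inverse
delta-method variances; factors rescaled to geometric mean one; a dataset
sharing fewer than five OTUs with the reference falls back to factor 1
with a warning.  The implementation reproduces edgeR's
`calcNormFactors(method="TMM")` to 1e-6 on the frozen 20-OTU example in
the tests.  Because M and A depend only on relative abundances, factors
are invariant to uniform depth changes *up to* the precision weights,
which depend on absolute counts; the invariance is therefore tested at 3%
relative tolerance, and exactly for proportional libraries (M ≡ 0).
An OTU's mean percent abundance averages 100 × count / effective library
size over **all** retained datasets, counting absence as zero (the
all-datasets convention; the alternative denominator is configurable in
principle but not the default).  Prevalence is the fraction of datasets
with a nonzero count and is independent of the factors.

**Scaling and classification.** Distances and mean percent abundances are
each divided by their maximum over the survey OTUs, mapping both to
[0, 1]; the Euclidean distance from the origin ranks OTUs jointly and is
reported for ranking only — no threshold is applied to it.  Flags are
independent and may overlap: *core* = present in at least five of seven
surveys, generalized to ⌈5D/7⌉ of D to preserve the fraction while
staying integral; *abundant* and *novel* = scaled value strictly greater
than 0.25 (boundary equality excluded).  Among flagged OTUs, those with
more than 93% identity to a cultured rumen isolate (taxonomy and
similarity are inputs, produced externally) are emitted as sequencing
candidates, de-duplicated by nearest-isolate id keeping the
highest-similarity OTU; the remainder are listed as requiring cultivation
effort.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without downloading survey data.

* **Master gene and divergence.** A 1600 nt random master sequence
  alternates conserved and hypervariable blocks the way 16S does; all
  divergence parameters are expected substitutions/site over the whole
  gene, realized as i.i.d. substitutions at variable sites only (no
  indels by default, which keeps anchor trimming exact).  Conserved
  window flanks therefore *are* the anchors the trimming stage must
  rediscover.
* **Cultured pool and community.** 30 cultured references at 0.04
  divergence from the master (half flagged rumen-origin); 25 community
  lineages at 0.01 extra divergence from distinct references (they merge
  with their reference at the 97% threshold, realizing the zero-rule) and
  8 novel lineages at 0.20 divergence from the master, far outside the
  pool's internal nearest-neighbour radius (~0.05).
* **Abundances.** Log-normal (μ = 0, σ = 1.2) across taxa, redrawn per
  dataset for non-core taxa and jittered (σ = 0.3) around a shared mean
  for core taxa — the many-rare/few-dominant structure of real surveys
  without claiming the original distribution.  About 30% of taxa are
  core (planted in every survey); the rest appear in at most four of
  seven surveys, so the core rule is unambiguous.  Every planted taxon's
  relative abundance is floored at 0.005 in datasets where it occurs: a
  taxon below the sampling floor would be absent by chance and the truth
  labels would not describe the community actually emitted (at the
  default 2000 reads/dataset the floor gives ≥ 10 expected reads).
* **Read artifacts.** Seven windows all covering the V1+V2 analogue with
  short conserved flanks; 17% of reads truncated to start inside V1
  (they lack the 5′ anchor and are discarded by trimming, mirroring the
  typical cleaning loss); 10% reverse-complemented; 5% chimeric, spliced
  from two abundance-weighted parent taxa at a uniform crossover in the
  middle 40–70% of the window — abundance weighting reflects
  template-concentration-driven PCR crossover and keeps parents above
  the screener's abundance precondition.  Per-base error rate defaults
  to 0; error-free reads are the regime in which exact set recovery is
  claimed.
* **Truth labels.** Core: planted presence in ≥ ⌈5D/7⌉ datasets.
  Novel: a lineage whose realized nearest-cultured divergence exceeds
  the pool's internal radius *and* whose scaled distance exceeds 0.25 —
  the pool-radius condition makes the `novel_divergence = 0` limit
  behave correctly (lineages indistinguishable from pool members are not
  novel).  Abundant: scaled true mean percent > 0.25.

**What passing tests show — and do not.**  The generator produces
well-separated lineages, no indels, no PCR primer bias, no quality decay,
and (by default) no sequencing error; exact recovery of the planted core
and novel sets under these conditions validates the *bookkeeping and
algorithms*, not the biological error tolerance of the method.  Real
surveys have ragged lineage boundaries at 97%, indel-rich pyrosequencing
error, and chimera rates that vary by region; the recovered sets there
would be approximations, as in the original analysis.

## Numerical choices and degenerate inputs

* Identity ties in greedy clustering resolve to the earliest-founded
  cluster; read order is canonicalized (longest, then id) first.
* All distances are raw branch-length sums; no transformation is applied
  to ingested trees.  Missing newick branch lengths become 1.0 with a
  warning — distances are meaningless otherwise, and explicit beats a
  silent zero.
* If every nearest-cultured distance is zero, all scaled distances are
  zero (no division by a zero maximum); scaling requires at least one
  positive abundance.
* Percentages in reports round half-up to whole percent; published
  tables that were rounded differently cell-by-cell are not chased.
* Empty count tables, zero flagged OTUs, and single-phylum inputs all
  produce valid (possibly header-only) outputs rather than errors.
* Every stage is deterministic given the seed; rerunning the CLI with
  unchanged inputs reproduces byte-identical artifacts (checked via
  manifest checksums in the tests).

## Problem sizes

The default study — seven surveys × 2000 reads, 30 cultured references,
33 community lineages — was chosen so that a full pipeline run completes
in ~10 s and the whole test suite in about a minute on one CPU, while
still exercising every stage (tens of OTUs, a ~40-tip tree).  The
original analysis operated three orders of magnitude higher (22,031
universal OTUs from ~1.4 M reads); its headline counts require the seven
published read sets and the isolate-database export and are out of scope
here, but all in-paper arithmetic that is recomputable from transcribed
per-phylum tables is reproduced by the report module.

## Known limitations

* One clustering algorithm is used everywhere; the original analysis used
  two related tools depending on the dataset.  Exact byte-compatibility
  with those tools' outputs is a non-goal.
* The NJ tree is a self-contained default, not a substitute for a
  maximum-likelihood phylogeny; external newick ingest is the fidelity
  path.
* Chimeras crossing over inside conserved regions are undetectable by the
  parent-crossover signature (they are near-duplicates of one parent);
  they inflate parent counts by a few percent at the default chimera
  rate.
* Taxonomy (and percent identity to the nearest cultured rumen isolate)
  is an input, not computed; the pipeline only propagates it from source
  sequences to OTUs through representatives.
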