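# Methods

## Core definition and the low-abundance filter

An OTU is a member of a subject's temporal core when it is detected
(count ≥ 1) in at least θ percent of that subject's samples; θ defaults to
80 and the comparison is inclusive, with no rounding of the prevalence
ratio. Detection is purely presence-based — there is no per-sample
abundance floor beyond the table-level filter below — because with typical
amplicon depths (~1,000–3,000 reads/sample) the detection limit is already
around 10⁷ cells/gram, and persistent low-abundance populations routinely
dip below it.

Before any analysis, OTUs with ≤ `min_count` (default 5) reads summed
within a subject are removed. The filter drops an OTU from the whole table
only when the condition holds in **every** subject: a subject-specific drop
would give different column sets per subject and silently break shared-core
and accumulated-curve comparisons. A per-subject mode (zeroing counts only
where the subject total is ≤ 5) is available for workflows that want the
stricter reading; it is off by default.

## Fixture-based quantities

The packaged `table1.tsv` summary stores per-OTU/per-subject printed means,
SDs and percent-detected values. Operations on it take the printed
`pct_detected` as the prevalence and the sum of printed per-OTU means as
the core abundance share — the per-sample data behind the summary are not
available, so these sums are means-of-percent rather than
percent-of-pooled-reads. `ND` entries are treated as prevalence 0 and mean
0 wherever a numeric is required.

## Accumulated shared-OTU curves

`shared_otus(k)` is the set of OTUs present in all of the first k samples;
the OTU fraction divides by the union of OTUs seen in those k samples and
the sequence fraction by their total reads. The default ordering is
chronological; because the ordering convention is a genuine free choice, a
random-order mode (mean over R seeded permutations) is provided for
smoother curves. Both fractions start at 100 at k = 1 by construction, and
the shared sets are nested by construction.

## Rank stability

Presence/absence stability per taxonomic rank is summarized as the mean
Jaccard similarity of presence sets over all sample pairs (a
consecutive-pairs option exists for drift-style questions). Collapsing to a
rank sums counts over OTUs sharing the label; OTUs unassigned at the rank
pool into `unclassified-<nearest assigned parent>` so per-sample depth is
conserved exactly. For nested labelings, coarsening can only merge presence
sets, so the profile is non-increasing from phylum to OTU pair-by-pair —
this is tested as a deterministic property, not just on simulations. The
Firmicutes:Bacteroidetes ratio is reported per sample; zero-Bacteroidetes
samples yield `inf`, are flagged, and are excluded from period mean ± SD
summaries.

## Event calling

The caller fits at most one changepoint per OTU: a boundary b such that one
side is entirely absent and the other is present in ≥ p of its samples with
mean relative abundance ≥ a_min, both sides at least m samples long. Among
qualifying boundaries the presence-fraction contrast is maximized, ties
toward the earliest index. The defaults m = 5, p = 0.8, a_min = 0.1% were
chosen once so that half-year-scale stable runs qualify while single-sample
blips and sub-detection noise do not; all three are exposed as parameters.
The defaults are deliberately conservative: an event call asserts a
sustained state change, not a fluctuation.

Resilience is a two-number summary per OTU: treatment-phase mean over
baseline mean (fold-change), and a recovery flag set when the washout mean
lies within baseline mean ± 2 baseline SD. Each phase needs ≥ 2 samples.

## Sequence merging

Representative sequences are aligned globally (match +1, mismatch −1, gap
open −5, gap extend −2, a length-L gap run costing −5 −2(L−1)); identity is
matches over aligned columns excluding terminal-gap columns, so amplicons
trimmed to different lengths are not penalized. The aligner is a standard
affine-gap global aligner; the merging criterion is the p-distance
complement on the pairwise alignment, and the scores are configurable.
Merging is single-linkage on the graph with edges at identity strictly
greater than the cutoff (97.0 itself does not merge), restricted within
phylum by default. Group abundance is the member sum; the representative is
the most abundant member, ties to the smallest id. Raising the cutoff can
only refine the partition, and merging the representatives again at the
same cutoff is the identity — both are property-tested.

## The simulator

`TruthSpec` plants: per-taxon base abundances (percent, summing to 100),
week-to-week lognormal noise (σ on the log scale), transient occurrence
probability, an invasion/extinction schedule, treatment fold-changes, and
the error model. Per week the true composition is renormalized and `depth`
reads are drawn multinomially; each read is then routed to its true OTU, to
one of `n_satellites` recurring satellite OTUs of its taxon (total
conditional probability `satellite_fraction`), or — with probability
`singleton_rate` — to a fresh singleton OTU that exists only in that
sample. Read totals are conserved exactly, and all randomness flows from
one integer seed through one generator.

The error model is a deliberate abstraction of how OTU pickers behave on
error-containing reads: systematic error modes (homopolymer artifacts,
recurring chimeric forms) produce the *same* spurious cluster across
samples (satellites), while scattered errors produce one-off clusters
(singletons). Satellites and singletons inherit their parent's genus in the
generated taxonomy, mirroring the empirical finding that read-level
classifiers place error reads correctly even when OTU picking splits them
off. The model does not simulate reads, quality scores, chimera structure
or primer bias, and its parameters are not fitted to any real run — so
passing recovery tests demonstrates that the *analysis operations* behave
correctly under a realistic inflation regime, not that the error model
matches any particular instrument.

### Preset conditions

- `human_preset`: 40 core + 360 transient taxa (≈ the observed 411 ± 119
  OTUs per subject), core carrying 80% of base mass, lognormal(0, 1)
  rank-abundance within each block (making the top ~40 taxa cover ~80% of
  reads, with core means spanning roughly 0.1–10%), σ = 0.5 weekly noise,
  transient occurrence probability 0.2, depth 3,000 (≈ 10⁵ reads over 33
  weekly samples), singleton rate 0.01, no satellites.
- `mock_preset`: three taxa at 60/20/20 (Bacteroides / Bifidobacterium /
  Escherichia), Dirichlet concentration 200 across 9 animals, depth 1,000,
  2 satellites per taxon carrying 18% of its reads between them, singleton
  rate 0.026. These error parameters were chosen so the regime matches the
  published defined-community experiment qualitatively: ~240 total OTUs of
  which 9 are shared across all animals, the shared set carrying ~97% of
  reads and the top 3 OTUs ~80%.
- `event_preset`: 30 core taxa (80% of mass) plus 20 event taxa at ~1%
  each, alternating invasion/extinction at uniformly drawn weeks leaving
  ≥ 5 samples on each side of the boundary; no transients, so every
  non-event call is unambiguously a false positive.

The mock calibration interval used in the acceptance test, total richness
mean ∈ [223, 263] over 20 seeds, was fixed from a 1,000-replicate pilot of
`mock_preset` (per-replicate mean 243.1, SD 14.8; the interval is the mean
± 6 SD of a 20-seed average) before the test was locked.

## Numerical choices and degenerate inputs

- Relative abundances are percent of per-sample depth; zero-depth samples
  are an error naming the sample, never silently dropped.
- Prevalence and threshold comparisons are exact floating comparisons on
  the percent scale; no epsilon is applied (thresholds are user-chosen
  round numbers and counts are integers, so ties are exact).
- Jaccard of two empty presence sets is defined as 1 (identical samples).
- Empty cores are legal: phylum splits and abundance fractions return
  zeros.
- Merged-OTU labels from upstream pipelines (e.g. `16/548`) are opaque row
  keys and are never split.

## Problem sizes in the shipped tests

The test suite and acceptance script use 20 seeds for the core-recovery and
mock studies and 200 replicates for event recovery, with the preset depths
and 33-week series above; these sizes give sub-percent Monte-Carlo error on
every reported rate while keeping a full run under ten seconds.

## Known limitations

- Fixture-derived abundance shares are sums of printed per-OTU means;
  they agree with pooled-read fractions only to rounding.
- The event caller requires a strictly all-absent phase; populations that
  decline to sporadic detection rather than zero are not called. This is
  intentional — such patterns are not distinguishable from deep temporal
  fluctuation at survey depth.
- The merge step evaluates all O(n²) pairwise alignments; it targets core
  OTU sets (tens of sequences), not de novo clustering of read sets.
- Jaccard rank-coarsening monotonicity holds for nested labelings;
  taxonomies with rank-inconsistent labels (the same genus under two
  families) void the guarantee.
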