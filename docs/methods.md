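# Methods

This note documents the models, conventions and design choices behind
`dsbdart`: what each stage computes, what the synthetic-data generator does
and does not emulate, and where genuinely open design decisions were settled.

## Coordinates and anchors

All intervals are 0-based half-open (`[start, end)`), the BED convention,
everywhere in memory and on disk; GTF input (1-based closed) is converted on
read. Chromosome names are never normalized — a preflight check
(`check_chrom_namespaces`) reports name-set disagreement between inputs
instead of silently dropping data. A DSB site wider than 1 bp (e.g. the 8 bp
AsiSI recognition motif) is anchored at `floor((start+end)/2)`; the midpoint
is the only symmetric choice and, for an 8 bp palindromic motif, sits at the
centre of the recognition sequence. DSB anchors are treated as unstranded:
flank windows run left-to-right in genomic coordinates and rows are never
flipped — orientation enters later through neighbouring genes, not through
the site itself.

## Strand assignment and coverage

Stranded libraries report transcript orientation through alignment
orientation. Under the dUTP-type (`reverse`) protocol — the default, as
produced by TruSeq stranded kits — a single-end or first-of-pair alignment
on `+` derives from a `−` transcript and vice versa, while second-of-pair
orientation is preserved; the `forward` protocol is the identity. The
protocol is an explicit, logged parameter because applying the wrong one
exactly swaps every downstream sense/antisense call.

Coverage is counts-per-million per base: position *p* on strand *s* gets
`(reads on s covering p) × 10⁶ / library_size`. Coverage counts full read
spans (the SAM adapter spans the aligned region of the primary alignment; no
fragment extension, no splice-aware splitting in the BED path) — the simplest
contract consistent with per-nucleotide CPM, and documented as such.
`library_size` may exceed the number of retained reads: it is the library's
total read count, of which the retained reads may cover only a region of
interest. CPM is invariant under duplicating the read multiset.

Flank matrices hold, per site, the mean per-base CPM of each `bin_size`-bp
bin across `[anchor − flank, anchor + flank)`. The bin statistic is the mean
rather than the sum so values stay comparable across bin sizes; at the
default `bin_size=1` the two coincide. Window positions beyond a contig end
contribute zero and flag the row as clipped.

## Sense/antisense annotation

For each site, gene regions are intersected with the flank window
(any-overlap at bin resolution: a partially covered bin counts as covered —
at 1 bp bins the question vanishes). Plus-strand coverage over bins inside a
`+` gene region is sense and inside a `−` region antisense; minus-strand
coverage mirrors this. Contributions from multiple gene regions at one site
are summed per bin, identically for sense and antisense. Two deliberate
choices here:

* **Same-strand regions are merged per site before summation.** Nested or
  overlapping same-strand records (isoform-style annotations) would otherwise
  double-count the same physical coverage.
* **Opposite-strand overlap contributes to both outputs.** A bin inside both
  a `+` and a `−` gene adds its plus-track value to sense (via the `+` gene)
  and to antisense (via the `−` gene), and symmetrically for the minus track.
  This is the per-gene-annotate-then-sum semantics; it intentionally breaks
  simple sense+antisense = plus+minus conservation, which holds only where
  every bin is covered by at most one gene (a property the test suite checks
  in both regimes).

Sites whose flank overlaps no gene cannot be oriented and are removed; their
ids are reported, never silently dropped.

## Site stratification

*Cleavage efficiency* is the raw count of DSB-capture (BLESS-style) reads
overlapping `anchor ± 500 bp` — counts, not CPM, because the capture assay's
read count is itself the efficiency readout. Ranks ascend with count; ties
break lexicographically by site id (stable and documented; every ordering
consumer uses the same rule).

*Repair-pathway propensity* is the ratio of summed RAD51 coverage in
`anchor ± 4 kb` to summed XRCC4 coverage in `anchor ± 1 kb`; the *k* = 30
largest ratios are labelled HR-prone and the *k* smallest NHEJ-prone. The
ratio-of-summed-coverages is the fixed interpretation of the factor-coverage
"correlation ratio" used in this field's site classifications; the original
ratio definition is not restated in the source material, so the plain ratio
is used and named as such. A zero denominator sorts as +∞. The classification
is meaningful only for cleaved sites; feeding uncleaved sites (no coverage in
either track) places their 0/0 → ∞ ratios at the top, so callers classify the
cut-site subset.

*Transcription classes* score each site by total sense CPM across the flank
in the undamaged condition (the pre-existing transcriptional state, not the
damage response) and label the top and bottom quantile (default terciles,
quantile = 1/3) high and low.

*Motif scanning* reports every exact, possibly overlapping occurrence on the
forward strand, plus reverse-complement hits (flagged `-`) when the motif is
not its own reverse complement. GCGATCGC is palindromic, so forward scanning
is complete for the default motif.

## Statistics

* **Metagene profiles**: column means over a site group with
  SEM = sample SD (ddof 1)/√n; SEM is defined as 0 for a single site.
* **Windowed coverage**: per-site sum of bin values over a `width`-bp window
  centred `offset` bp from the anchor. Width and offset are explicit
  parameters (default 500 bp at offset 0, i.e. ±250 bp around the break)
  and are recorded in every output header, because "a 500 bp window at the
  DSB" admits both ±250 and ±500 readings; making the window explicit
  surfaces rather than hides that ambiguity.
* **Fold changes**: `log2((W_cond + c)/(W_ctrl + c))` with pseudocount
  c = 0.01 CPM (arbitrary but far below one read's contribution); sites with
  zero windowed coverage in *both* conditions are flagged and excluded from
  downstream tests rather than contributing log₂(c/c) = 0.
* **Rank-sum test**: Mann–Whitney U via midranks; the exact null
  distribution when n + m ≤ 12 and the pooled sample is tie-free, otherwise
  the normal approximation with tie-corrected variance and continuity
  correction (scipy's implementation behind the module surface). The ≤ 12
  threshold keeps exact enumeration trivially cheap where it matters —
  small-group comparisons — without paying for it at metagene scale.
  Exhaustive enumeration at n = m = 6 shows the two branches agree within
  0.016 in p (worst at mid-range U; the tails are closer).
* **PCA**: samples are observations, per-site coverages are features;
  features are centred but not scaled (they share CPM units), constant
  features are dropped with a warning, and each component's sign is fixed by
  making its largest-magnitude loading positive so results are reproducible.
* **2^(−ΔΔCt)** with ΔΔCt = (Ct_target_IP − Ct_target_input) −
  (Ct_ref_IP − Ct_ref_input), the standard relative-quantification
  convention.

No multiple-testing correction is applied: the pipeline's comparisons are
single planned contrasts, not families of hypotheses.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes — it is
a calibration instrument, not a sequence simulator.

**What it models.** A small multi-chromosome genome (default 2 × 1.5 Mb)
carries non-overlapping stranded genes (default 300, 2–6 kb) whose expression
rates are lognormal (median 30 reads/kb/library, log-sd 1.0 — a realistic
spread of transcription levels). Cut and uncut sites sit inside distinct host
genes; a configurable handful of gene-free sites (default 3) exercises the
orientation-stage exclusion rule. Cut sites carry cleavage efficiencies
e_s ~ Uniform(0.5, 1) (annotated-but-efficiently-cut sites; uncut sites have
e_s = 0). Background transcription emits reads uniformly within each gene on
its own strand. Under damage, each cleavable site adds reads on *both*
strands — induced transcription is bidirectional and symmetric about the
anchor by default — with per-position intensity ∝ e_s · A · exp(−d/L);
the exponential decay (L = 500 bp) concentrates the induced signal in the
±500 bp window the windowed statistics analyse. The knockdown condition
multiplies host-strand (sense) induction by κ_sense = 1.3 and opposite-strand
(antisense) induction by κ_antisense = 2.0 — a preferential antisense
amplification. Counts are Poisson by default; a negative-binomial option
(`dispersion: nb`) adds overdispersion when wanted, at the cost of the
closed-form means the calibration checks rely on.

**Library-size model.** Only the region of interest is simulated, but the
reported `library_size` is `base_library_size` (default 10⁷) plus the emitted
reads: the simulated locus set behaves as a small slice of a deep library, as
damage-induced transcripts are in a genome-scale experiment. Without this,
CPM normalization at desk scale would suffer a composition bias (induced
reads dominating the simulated library) that the genome-scale experiment does
not have, and fold-change calibration would measure that artifact instead of
the planted multipliers.

**Why these defaults.** The windowed fold-change median estimates
log₂ κ only in the signal-dominated regime: with window background b and
induced signal g·b, the expected ratio is (b + κ·g·b)/(b + g·b), biased
toward 0 for small g. The defaults are chosen from that closed form:
induced-to-background ratio ≈ 20 at the median site (A = 1000 expected
induced reads/strand/site at e_s = 1 vs ~15 background reads per ±250 bp
window) keeps the bias below ~0.02 log₂ units; ~15 background reads per
uncut-site window keep the log-ratio of two Poisson counts stable enough
that the uncut median concentrates near 0; and the 10⁷ notional library
keeps the CPM composition factor above 0.985. Site anchors keep a minimum
spacing (default 2.5 kb) so the ±500 bp counting windows of neighbouring
sites never overlap; the ±4 kb pathway windows can still reach a
neighbouring site at this density, so planted pathway-label recovery on
generator data is high but not exact — the exact-recovery guarantee is
checked on isolated planted tracks.

**Planted truth.** Every run writes a truth record: per-site efficiencies,
host genes and strands, expected induced read counts per condition, planted
pathway ratios (a shuffled geometric ladder over cut sites), and the
generator configuration itself. Tests compare recovered quantities against
this record, never against re-derived values.

**What it does not model.** Sequence-level reads (no FASTQ, no errors, no
alignment), splicing, fragment-size distributions, replication timing or
copy-number structure, resection-dependent asymmetries (an asymmetric
induction option exists but is off by default), and overdispersion beyond
the negative binomial. Passing tests therefore demonstrate that the
*pipeline arithmetic* recovers planted structure under the stated noise
model — not that any biological claim holds in real data.

## Pipeline driver and figures

`run_pipeline` executes simulate → coverage → matrices → orientation →
stratification → statistics → figures, refuses to run a stage whose
dependency is disabled (e.g. statistics without orientation), and writes a
manifest with parameters, library versions, the seed, every excluded site and
a SHA-256 digest of every output file; re-running with the same configuration
and seed reproduces every digest. Figures are artifacts: heatmap rows follow
the ascending cleavage-efficiency order (stable ties), colour limits clip at
the 1st–99th percentile of the matrix (recorded in the figure), metagene
plots give sense and antisense independent vertical scales, and no numeric
claim is made by a figure that the underlying tables do not carry.

## Scale of the shipped checks

The test suite and the acceptance script run the full analysis at the default
scale (100 cut + 100 uncut + 3 gene-free sites on 3 Mb, ~10⁵–10⁶ reads per
condition) in seconds on one CPU; oracle comparisons (triple-loop orientation
oracle, nested-loop pileup, rank-sum enumeration) run on instances small
enough for brute force to be unquestionably correct. These sizes are the
package's chosen desk-scale study conditions; nothing in the code depends on
them.
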