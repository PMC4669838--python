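# Methods

This note documents the models behind `mbdseq`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing its
behaviour.

## The study design being modelled

The package targets a capture-based methylation experiment with two
crossed factors:

* **condition** — control vs dexamethasone-exposed (Dex) cultures;
* **passage/lineage** — parent cells harvested right after exposure
  (P1) vs daughter cells two passages later that were never directly
  exposed (D3).

Methylated DNA is enriched with a methyl-CpG-binding-domain (MBD)
pulldown: the bound ("captured") fraction is sequenced as signal and
the unbound supernatant of the same sample as its background.  All
analyses operate on aligned read coordinates; sequence content,
alignment, and bisulfite chemistry are out of scope.

## Synthetic data generator

### Genome

`build_genome` lays out a small multi-chromosome genome (default 4
chromosomes, 30 Mb total) with non-overlapping transcripts in refFlat
semantics (strand, tx/cds bounds, exon blocks; ~20% non-coding) and
CpG islands, roughly half of which are anchored at transcription start
sites because real CGIs cluster at promoters and the CGI-restricted
context distributions would otherwise be vacuous.  Interval placement
distributes the free base pairs as multinomial gaps, which is uniform
over feasible non-overlapping placements; infeasible requests raise a
packing error rather than degrading silently.

### Methylation landscapes

Methylation is modelled at *region* granularity, not per-CpG: the unit
of downstream analysis is the peak, and region-level truth keeps the
truth table directly comparable to called peak sets.  The base
(control-P1) landscape plants 900 non-overlapping 2 kb regions with
methylation levels drawn from U(0.8, 1.0) — strongly methylated
regions, as befits regions that an MBD pulldown captures efficiently.

The condition effect: Dex-P1 demethylates a fraction of the base
landscape and gains a smaller set of fresh methylated regions.  The
two fractions default to 110000/164801 ≈ 0.667 demethylated and
37005/164801 ≈ 0.225 gained, i.e. the proportions implied by the peak
partition of the emulated study (110 000 control-unique and 37 005
Dex-unique peaks out of 164 801 control peaks), so the default run
reproduces its directional structure: many more control-unique than
Dex-unique DMRs, and net genome-wide hypomethylation in Dex-P1.
Demethylation is biased toward promoter-overlapping regions (weight 4
vs 1) so that promoter-context effects are visible in the annotation
module.

The lineage effect: each P1 methylated region survives into its
lineage's D3 landscape independently with probability 0.63 (Dex) or
0.36 (control) — the preservation proportions of the emulated study.
Non-retained regions are redrawn at uniform random positions rather
than deleted, keeping D3 peak-set sizes comparable to P1.  Redraws
exclude the parental region set: otherwise chance re-landings (~12%
of the genome is within a fragment of a parental region at default
density) would inflate the realized preservation above the configured
retention, and the configured probability would no longer be the
quantity the preservation analysis estimates.

### Capture libraries

`simulate_mbd_library` draws `depth` fragment positions uniformly over
the genome (fragment length 200 bp, matching sonicated DNA of that
protocol) and assigns each fragment to the captured fraction with
probability

    p = min(1, base_rate * max(1, enrichment * level))

where `level` is the methylation level of the region containing the
fragment midpoint (0 outside regions).  This is the simplest monotone
capture model with an analytic oracle: unmethylated ground is captured
at the base rate (non-specific carry-over, default 0.02) and a fully
methylated region at `min(1, base_rate * enrichment)` (default
enrichment 50, i.e. capture probability 1 — MBD pulldowns are highly
specific).  Captured plus supernatant reads always equal `depth`
(default 800 000 per sample, a desk-scale stand-in for the tens of
millions of reads of a real experiment; at the default genome size it
yields ~20 reads per kb, comparable per-bin statistics to a real
library over a mammalian genome).

### qPCR plates

`simulate_qpcr` produces Ct values as `baseline − log2(fold) + N(0,
noise_sd)` with the housekeeping reference gene fixed at fold 1 in all
groups.  Defaults: 0.2 cycles noise, ≥3 replicates enforced (the
emulated protocol ran triplicates; recovery tests use 6).

### What the generator does *not* emulate

No sequence content, sequencing error, mappability structure, GC or
fragment-length bias, copy-number variation, within-region CpG
heterogeneity, or overdispersion beyond Poisson sampling.  Passing
tests therefore demonstrate that the analysis logic is correct under
its own statistical assumptions, not that those assumptions hold on
any particular real library.

### Seeding

One global seed with fixed named streams (genome 0, landscapes 1,
libraries 2 + per-sample index, qPCR 3) via numpy `SeedSequence`
lists, so every stage is reproducible in isolation and the four
samples' libraries are mutually independent.

## Peak calling

Duplicates are collapsed to one read per (chromosome, start, strand);
including strand is the stricter reading of one-read-per-position and
is configurable.  Reads are assigned to fixed-width bins by fragment
midpoint (conservation-friendly and adequate when bins are at least as
wide as the 200 bp fragments).  Each captured bin count `k` is tested
against `lambda = max(background_bin * scale, genome_rate)` where
`scale` is the captured/background library-size ratio — library-size
scaling is the minimal defensible normalization — and `genome_rate`
the mean captured reads per bin; `p = P(Poisson(lambda) >= k)`.  With
no background track, the uniform genome rate is used everywhere.
Significant bins are merged across gaps of at most `merge_gap`,
candidates shorter than `min_width` are dropped, and the merged span
must itself pass the Poisson test (summed counts vs summed
expectation), which guarantees that every emitted peak's recomputed
p-value is at or below the threshold.

Module-level defaults (bin 200 bp, p ≤ 1e-5, min width 400 bp, merge
gap 200 bp) follow common conventions for ~200 bp fragments at deep
coverage.  The bundled pipeline instead uses bin = min width = 1 kb
and no gap merging, matched to its 2 kb planted regions and desk-scale
depth; at ~20 reads/kb, 200 bp bins hold ~4 reads and have essentially
no power at p ≤ 1e-5, while 1 kb bins hold ~20.

This caller is deliberately simple — no local-lambda windows, no
fragment-model shifting, no duplicate-rate modelling — because the
package's contribution is the downstream comparison machinery, which
only consumes peak sets.

### Calibration and the discreteness of the Poisson test

The test statistic is integer-valued, so the attained per-bin false
positive rate sits below the nominal threshold except exactly at the
rates where the critical value steps.  The calibration check in the
acceptance suite therefore simulates null tracks at 0.9866 expected
reads per bin: the critical value k = 8 first attains p = 1e-5 at
lambda ≈ 0.9966, and at 0.99× that rate the attained level is 9.3e-6,
close enough to nominal for a two-sided interval check while leaving
margin for the caller's self-estimated rate to stay on the k = 8
plateau.  The check runs with `min_width` equal to one bin; at the
400 bp default a false peak would require two adjacent false bins and
the expected false-peak count is ~0, which is unobservable against a
per-bin expectation.

## DMR partition and preservation

"Shared" defaults to any overlap (≥ 1 bp) because the emulated study
never states its criterion; a reciprocal-fraction rule is exposed, and
tightening the rule can only shrink the shared set (tested as a
monotonicity property).  Shared peaks are counted as merged clusters —
one common entity per connected component of the overlap graph —
since the study reports a single common count.  Preservation is
computed on full peak sets, not DMRs, and the chi-square comparison
uses no continuity correction (counts here are large; a flag exists).
Accounting (`|input| = |unique| + |contributors to common|`) is
asserted on every partition.

The genome fraction under peaks (`global_methylated_fraction`) serves
as a coarse, direction-level proxy for global 5-mC assays; it is not a
calibrated methylation level.

## Genomic context annotation

Promoter = strand-aware TSS window, default −2000/+500 bp (a common
convention; the emulated study never defines "promoter").  UTRs are
the exonic base pairs outside the CDS (strand-aware), introns the
transcript minus exons, and non-coding transcripts contribute no UTRs.
Each peak gets exactly one primary context by precedence — promoter >
5'UTR > 3'UTR > exon > intron > intergenic, configurable — with ties
within a context broken by larger overlap, then gene name; one context
per peak keeps distribution counts additive.  CGI overlap is recorded
independently of the primary context.  "Normalizing to the gene
annotation" is implemented as peaks per megabase of feature, with raw
counts always reported alongside, and a zero-bp feature yields an
undefined (NaN) density rather than zero.

## Expression statistics

ΔCT is computed per replicate against that same sample's reference
gene and only then averaged per group, preserving replicate variance
for the t-test (the order of operations is otherwise a free choice).
The two-group test is the pooled-variance Student's t by default with
a Welch flag.  With more than two groups, Bonferroni-adjusted pairwise
t-tests are run only after a significant one-way ANOVA omnibus at
α = 0.05.  Fold changes obey `fold(a,b) * fold(b,a) = 1` exactly and
are invariant to per-sample Ct shifts; both properties are tested.
Concordance scores a gene as concordant when promoter hypomethylation
coincides with upregulation (fold > 1) or hypermethylation with
downregulation; genes with unchanged or mixed promoters are unscored.

Group means are reported with standard deviations; standard errors are
trivially derived and deliberately not asserted anywhere, since error
bar conventions vary.

## Problem sizes

The default study (30 Mb genome, 900 regions, 4 × 800 000 reads) runs
in a few seconds; the acceptance suite's twenty replicate studies and
null-calibration simulations complete in about a minute each on one
CPU.  These sizes were chosen so that per-bin counts, peak counts
(~10^2–10^3), and preservation denominators (~900) give the same
statistical regimes as the full-scale experiment while remaining
desk-runnable.

## Known limitations

* Absolute peak counts are depth- and threshold-sensitive; only
  directions and proportions are meaningful points of comparison with
  any real experiment.
* The caller assumes Poisson counts; overdispersed real libraries
  would need a local background or a negative-binomial test.
* Peak boundaries are bin-quantized; sub-bin localization is out of
  scope.
* Preservation treats any overlap as identity of a region across
  passages; it does not track region identity through coordinate
  changes.
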