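# Methods

## Problem and model

TERRA transcripts start at subtelomeric promoters and read through into
the telomeric UUAGGG repeat. A *TERRA transcription region* is modeled as
an interval on a chromosome arm consisting of a transcription start site
(TSS), a subtelomeric segment of unique sequence, and the telomeric
repeat tract itself; transcription is oriented toward the tract. Three
region types are distinguished by location and promoter content: Type I
(chromosome end, at least one of the 61/29/37 bp promoter repeat element
families in the 3 kb upstream of the TSS), Type II (chromosome end, none
of the three families), and Type III (transcribed from an interstitial
telomeric sequence, regardless of promoter content). All coordinates are
0-based half-open internally; BED output is 0-based half-open and GTF
output 1-based inclusive.

## Repeat tract detection

Tracts are found by exact-motif chaining: every exact occurrence of the
hexamer (TTAGGG; its reverse complement for the minus strand) is located,
and consecutive occurrences separated by at most `max_gap` bp are chained
into one candidate. Candidates are trimmed to the outermost exact match
and kept when span ≥ `min_tract` and purity (6 × copies / span) ≥
`min_purity`. Because TTAGGG has no nontrivial self-overlap, copies in a
chain are disjoint and purity is bounded by 1.

Parameter defaults and rationale:

| parameter | genome scan | long reads | rationale |
|---|---|---|---|
| `min_tract` | 200 bp | 30 bp | ITS convention of >200 bp; reads carry shorter informative tracts |
| `max_gap` | 24 bp | 48 bp | 4 motif units of interruption in genomic tracts; double for indel-rich reads |
| `min_purity` | 0.8 | 0.5 | see below |

At a per-base error rate *e*, the probability that a given repeat unit
survives as an exact hexamer is (1 − *e*)⁶ — at the 8% error rate typical
of the targeted long reads this is ≈ 0.61, so the *expected* purity of a
true tract is barely above 0.6 and sampling noise puts a sizeable
fraction of true tracts below it. The read-measurement default is
therefore 0.5. False positives remain negligible: a chance exact hexamer
occurs every ~4 kb of random sequence (4⁻⁶ per position), so a chained
pair of chance hits within `max_gap` has probability ≈ 10⁻⁵ per 2 kb
read, and none were observed in 500 random reads. Genome scans keep the
stricter 0.8 since assemblies are essentially error-free.

Terminal classification assigns `terminal_p`/`terminal_q` to the tract
closest to the respective sequence end when it lies within `end_window`
(default 100 kb) of it; distance ties go to the longer tract. Everything
else is interstitial. Per-read measurement reports the longest G-rich
tract; `telo_touches_3prime` uses a 30 nt margin at the read's 3′ end
(the expected transcript architecture; the margin absorbs adapter or
basecall ragged ends).

Long-read alignment filtering keeps MAPQ ≥ 1 records whose flags are
primary or supplementary (unpaired, non-secondary, non-duplicate), drops
supplementary records whose read retains a primary alignment, and leaves
at most one record per read (highest MAPQ, leftmost on ties). The filter
is idempotent.

## Promoter element arrays

The 61/29/37 bp element families diverge between chromosome arms, so
detection is a similarity search: candidate positions are seeded by exact
11-mers of the consensus, verified by edit-distance alignment of the
consensus against a ±5 bp window (band 5), and accepted at identity ≥
`min_identity` (default 0.8). After each accepted copy the expected next
tandem position is probed directly, so a diverged copy that lacks any
clean seed k-mer is still found. Copies whose starts lie within 1.5 ×
element length are chained into arrays; arrays need ≥ `min_copies`
(default 2, since a lone degenerate hit is weak evidence of a promoter
array). Overlapping arrays of different families are all reported. The
real element consensus sequences are a configuration input (FASTA with
records e61/e29/e37); the package ships synthetic stand-in consensuses —
fixed GC-rich sequences free of telomeric hexamers — used by the
simulator and tests.

A promoter signature records which families overlap (≥ 1 bp) the 3 kb
window upstream of a region's TSS, oriented by transcription direction.

## Region calling

Historically these regions were assigned by manual curation over three
evidence tracks; here the procedure is algorithmic. For each terminal
tract the `end_window` on its subtelomeric flank is searched for maximal
runs of enrichment bins (per-bin log₂((capture + p)/(control + p)), bin
size 30 bp, pseudocount 1.0) at or above `enr_threshold` (default 1.0,
i.e. two-fold). A run that reaches the tract (within one bin) anchors the
proximal region; the TSS is the nearest CAGE cluster peak to the run's
inner boundary (upstream preferred on ties), else the modal long-read 5′
end, else the boundary itself — CAGE is the most precise 5′ evidence,
long-read ends are cap-biased but informative, and the enrichment
boundary is only bin-resolution. CAGE tags are clustered by
single-linkage within 50 bp; cluster peaks are modal positions with ties
resolved toward the transcription-5′ side. An arm with fewer than
`min_evidence` (default 2) of the three evidence classes yields no
region ("no TERRA detected"); candidates shorter than 200 bp are
discarded as noise.

A second enriched run distal to the proximal one, with its own CAGE or
long-read TSS evidence nearby, yields a second region with
`tss_rank = distal`, spanning from its TSS to the distal edge of the
telomere tract. Interstitial tracts are evaluated on both flanks under
the same rules; the flank with more evidence classes wins (left on
ties). Strand convention: a q-arm region lies on the strand where TTAGGG
reads toward increasing coordinates, a p-arm region on the opposite
strand, and an ITS region takes the orientation implied by the flank
carrying its TSS evidence.

Classification is a pure function: interstitial tract → III; terminal
with non-empty signature → I; terminal with empty signature → II.

## Counting

A fragment is the union of the primary spans of a read pair (pairs count
once; the fragment MAPQ is the minimum over mates, its strand that of the
first-in-pair mate). A fragment overlapping a feature by ≥ 1 bp counts,
and counts once per feature when it overlaps several. Modes:

* `arm_specific` — MAPQ ≥ 30 (paired) or MAPQ = 255 (single-end; the
  aligner convention for unique single-end mappings), counting only the
  subtelomeric sub-intervals: reads inside the pure repeat cannot be
  assigned to an arm.
* `total` — primary alignments, MAPQ ≥ 1, duplicates removed (flag-based
  when duplicate flags are present, positional collapse of identical
  seq/start/end/strand fragments otherwise), both sub-intervals counted.
* `capture` — MAPQ ≥ 30 over whole regions (one feature per region).

Total TERRA per sample sums Type I and Type II features with proximal
TSSs (both sub-intervals); Type III and distal-TSS regions are excluded.
CPM divides by total mapped fragments of the library, not the TERRA
subtotal. Poly(A) analysis computes each region's share of its
fraction's total TERRA reads (Types I + II + III) and the log₂ ratio of
plus over minus shares; a region with zero reads in either fraction gets
a flagged undefined ratio, and an all-zero fraction is an error.

## Normalization

Features are dropped unless their group-aggregated CPM (mean by default;
median available) reaches the threshold (default 1) in at least one
group; TERRA features are always retained because they are the analyte
and low counts are informative. Smooth quantile normalization then sorts
each sample, computes per-rank global and group references, weights them
by wᵤ = 1 − SSBᵤ/SSTᵤ (1 where SSTᵤ = 0, e.g. single-sample groups or
identical values), smooths wᵤ with a centered running median over
⌈`window_frac` × n⌉ ranks (ends copy the nearest fully computed value),
clamps to [0, 1], and maps values back to original order with ties
receiving the mean of their tied normalized values. With one group the
procedure reduces exactly to classical quantile normalization.
Normalization operates on counts; any log transform is left downstream.

## Simulator

The simulator emulates the data a TERRA capture study produces, at desk
scale: arms of a few hundred kb with terminal tracts (tract lengths are
whole numbers of repeat units, so planted coordinates are exactly
recoverable), promoter arrays placed in the 3 kb upstream of the planted
TSS with the 37 bp family nearest the TSS, interstitial tracts (expressed
ones get a 37 bp array upstream, mirroring the observation that ITS
promoters usually carry the 37 bp element), paired-end fragments drawn
per region as Poisson with fragment length Normal(300, 30) and uniform
placement, uniform background fragments that avoid region intervals (so
truth counts are exact), long reads built as transcript-sense
subtelomeric prefix plus planted repeat units corrupted by an i.i.d.
substitution/insertion/deletion process (defaults 4%/2%/2%), CAGE tags
Normal-jittered around the TSS (sd 10 bp, 20 tags per TSS), noise-free
capture/control coverage implied by the planted truth, and a per-region
binomial poly(A) split. Background sequence is i.i.d. uniform ACGT
scrubbed of chance telomeric hexamers outside planted tracts. Every
generator derives its random stream from (seed, operation-id), so outputs
are byte-identical across runs and call orders. The default condition is
six arms (300–500 kb): three expressed Type I regions with promoter
compositions {61,29,37}, {61,37} and {37}, one Type II, two silent ends,
and two expressed ITS sites; per-region expression of 100–300 expected
fragments and polyadenylation probabilities of 0.8/0.2/0.5 give clearly
resolvable poly(A) biases at that depth.

What the simulator does **not** emulate: alignment ambiguity and mapping
errors inside the repeat (MAPQ values are assigned, not earned),
basecaller-specific error profiles (errors are i.i.d., real Nanopore
errors are bursty and homopolymer-biased), splicing, degradation-induced
3′ truncation, and genome-scale repeat families competing for reads.
Passing tests therefore demonstrate correctness of the algorithms and
bookkeeping under the stated generative model, not end-to-end accuracy on
real sequencing data.

## Numerical and design choices

* Enrichment threshold (log₂ = 1), evidence minimum (2 of 3) and the
  CAGE > long-read > boundary TSS precedence are package decisions where
  the curation-based procedure left no numeric rule; all are exposed in
  configuration.
* Degenerate repeat variants (TGAGGG, TCAGGG, …) are not matched by
  default; the motif is a parameter, so variant sets can be scanned
  separately.
* The running-median window fraction (0.05) balances responsiveness of
  the qsmooth weight against rank-to-rank noise; endpoints copy the
  nearest computed value rather than shrinking the window.
* Problem sizes in the test-suite and acceptance runs (six arms of
  300–500 kb, 500 long reads, ≤ 300-fragment counting configurations)
  were chosen as the smallest sizes at which every recovery property is
  non-trivially exercised.
* Interstitial antisense transcription at telomere-fusion sites (ARIA) is
  out of scope: no algorithmic definition exists for it.

## Known limitations

* The exact-motif chaining detector underestimates tract length at read
  errors well above ~10%, where exact hexamers become too sparse; an
  alignment-based measurement would degrade more gracefully.
* Element detection reports the best local alignment per copy; heavily
  rearranged arrays (inversions, large internal deletions) may fragment
  into multiple arrays.
* The region caller assumes one telomeric tract per arm end; assemblies
  with interrupted terminal tracts may yield a terminal plus an
  interstitial call.
* qsmooth weight smoothing can, in principle, produce small rank
  inversions when the weight changes rapidly across ranks; in practice
  the running median prevents this on all tested data.
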