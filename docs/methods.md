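# Methods

`partchar` implements an imaging- and sequencing-based workflow for
characterizing DNA parts (promoters and ribosome-binding sites) at colony
scale: a combinatorial reporter library is grown on plates, every colony is
phenotyped from dual-channel photographs, pooled amplicons tagged with
per-colony barcodes are genotyped by long-read sequencing, and the two views
are joined to produce per-part relative strengths. This note records the
models, the parameters that matter, and the design decisions taken where the
workflow left them open.

## The measurement model

Each colony carries a characterization circuit with two reporter modules: a
GFP module whose promoter–RBS combination is the object of measurement, and
an RFP module with a fixed part combination acting as an internal growth
control. The quantified phenotype of a colony is the ratiometric **colony
intensity**

```
colony_intensity = (mean green value × green-channel colony size)
                 / (mean red value × red-channel colony size)
```

i.e. integrated GFP over integrated RFP. We interpret "channel value" as the
*mean* pixel value of the segmented region so that value × size is the
integrated signal; this makes the statistic an integrated-intensity ratio in
which exposure, gain, and colony size cancel to first order (the mean-based
reading is the default; a summed reading is available via
`DetectParams.use_sum`). The ratio is undefined for colonies without RFP
signal; such colonies are an explicit error, not a silent zero.

A part's strength is the mean colony intensity over the colonies that carry
it in the standard-circuit context (its RFU), and its **relative unit** is

```
RPU or RRU = mean part colony fluorescence / standard circuit fluorescence
```

with the standard circuit J23119–B0030–sfGFP–L3S2P56 as the baseline, so the
standard part itself scores exactly 1.0 and common scale factors cancel. A
subtractive variant of the denominator (standard − part) is retained behind
`convention="typeset"` purely for audit; it diverges as a part approaches
the standard and is not used by the pipeline.

Promoters are aggregated over colonies whose RBS is the standard one, RBSs
over colonies whose promoter is the standard one; groups need at least 3
colonies (configurable) or they are dropped with a logged reason, and the
standard baseline itself must rest on at least 3 QC-passing colonies.

## Colony detection and channel linking

Detection works per channel on the relevant RGB plane. The background is a
large-kernel median estimate computed on a 4× downscaled copy; the
threshold on the smoothed, background-subtracted plane is a robust noise
floor, median + 5·1.4826·MAD. We deliberately do not threshold with Otsu by
default (it is selectable): on plates that mix very bright and very dim
colonies the bimodal foreground makes a global Otsu threshold land between
the two colony classes and silently drop the dim ones, whereas the noise
floor tracks only the background and keeps any colony that clears camera
noise; speckle is removed instead by the minimum-size (30 px) and
circularity (4πA/P² ≥ 0.6) filters. Touching colonies are split by
distance-transform watershed seeded at local maxima at least 8 px apart.
Pixels at the top of the 8-bit range are counted per region; a region with
more than 5% saturated pixels is flagged, flagged colonies are excluded
from part aggregation, and a plate-level warning is raised because
saturation truncates exactly the signal the assay is supposed to measure.

GFP- and RFP-channel detections of the same plate are linked by mutual
nearest neighbour within 10 px (default), confirmed greedily by increasing
distance then lower record id, so no detection is used twice; unmatched
records are reported, never discarded silently. Coordinates are 0-based,
origin top-left, x = column, y = row.

## Barcode tags and demultiplexing

Each picked colony is amplified with a forward and a reverse primer whose
5' ends carry a 7-bp barcode tag ahead of an 18-bp primer-binding site.
Eight forward × twelve reverse tags address 96 colonies; nesting the tag
grid inside the 24 platform barcodes multiplies capacity to 2304.

Tag sets are designed by greedy distance-filtered sampling with homopolymer
runs capped at 3 and self-complementary sequences excluded. The separation
metric defaults to **sequence-Levenshtein** distance — the embedded-barcode
distance (minimum over the last row and column of the edit-distance DP
matrix) under which a tag remains decodable when its terminal bases shed
into, or borrow from, the adjacent DNA. Plain Levenshtein spacing is not
sufficient here: a deletion-damaged tag concatenated with the constant
binding-site sequence can lie within one edit of a *different* tag even
when the tags themselves are 3–4 edits apart, which we observed directly as
percent-level misassignment before adopting the sequence-aware metric.
Forward and reverse sets are designed jointly (cross-set distance enforced)
so a read scanned on the wrong strand can never match the other
orientation's tags, and candidates within 1 edit of the binding-site
context are rejected.

Demultiplexing searches both strands of each read. Matching is anchored at
the read terminus (prefix-anchored edit distance, free inner end), because
the tags sit at the molecule ends by construction; widening the search
window into the constant binding site only lets near-matches inside that
shared sequence light up in every read. A read is assigned iff exactly one
declared pair matches within `max_edit` (default 1) at both ends; any tie,
strand conflict, or undeclared tag combination leaves the read unassigned
with a reason (`no-fwd`, `no-rev`, `ambiguous`, `unknown-pair`) —
conservative demultiplexing never best-guesses. With tag sets at minimum
distance `d`, reads whose tags carry at most `⌊(d−1)/2⌋` errors each can
never be misassigned; the suite proves this on exhaustively mutated tags.

At the nominal nanopore error model (5% substitution + 3% indel per base)
roughly 83% of reads have ≤ 1 edit in *both* 7-bp tags — the binomial
ceiling for any per-end matcher at this budget — with misassignment held
around 0.2–0.3%. Deeper per-colony read counts, not a looser matcher, are
the intended remedy for the discarded fraction.

## Genotyping and QC

Every promoter × RBS × CDS × terminator combination, flanked by the constant
binding-site context, is an alignment reference. Reads are ranked against
all references on both strands by glocal edit distance (fast), and the
top-ranked candidates are re-scored with affine local alignment
(match +2, mismatch −3, gap open −5, gap extend −2), which decides the
final call, resolves ties (lowest construct id, flagged ambiguous), and
yields the **query coverage** — the aligned span of the read divided by
read length. Reads below 95% query coverage are discarded. In library
profiling mode each reference is doubled before alignment so reads starting
anywhere on a circular plasmid still align contiguously.

Per colony bin, the genotype is the construct supported by the most
coverage-passing reads, and two purity statistics gate the call:

```
score1 = primary mapped read count / total read count
score2 = (primary − second mapped read count) / primary
```

where *second* is the read count of the second-best-supported reference
within the bin (a bin-purity reading, not secondary alignments of single
reads — the interpretation under which score2 functions as a
demultiplexing QC). The denominator of score1 counts every read in the
bin including coverage-failed ones, so score1 reflects mapping success as
well as purity; `count_failed_in_total=False` restricts it to passed reads.
A bin passes QC when total > 15 and score1 > 0.4 and score2 > 0.65 (strict
inequalities, all configurable).

Library profiling tallies combination counts and ratios with per-slot
marginals; given the input molar ratios of an assembly reaction it also
reports the Spearman rank correlation between input and measured
combination ratios, the assembly-fidelity readout.

## Synthetic data generator

The generator exists so every stage is testable offline with exact ground
truth; its defaults are the workflow's nominal study conditions.

**Plates.** Colonies are rendered as flat discs at the programmed GFP/RFP
level with a Gaussian edge skirt (σ = 2 px) falling off strictly *outside*
the nominal radius, so the disc mean equals the programmed level exactly
before noise — which is what makes render-level fidelity testable to < 1%.
Radii are uniform in 6–14 px, placement is rejection-sampled with
non-overlap enforced (failure names the achieved packing density), the
background sits at 8 with additive Gaussian noise σ = 3 (σ = 5 in the
stress fixtures) on the 8-bit scale, and levels that would clip at 255
raise a warning. Signal lives in the green plane of the GFP image and the
red plane of the RFP image.

**Assembly.** Construct genotypes are drawn independently per slot with
probability proportional to the input molar ratio — the regime in which
measured combination frequencies track input ratios.

**Reads.** Each simulated read is forward-tag + construct (binding sites
included as flanks) + reverse-complemented reverse-tag, corrupted by i.i.d.
per-base substitution (5%), insertion (1.5%) and deletion (1.5%) — an
8%/base total chosen as a realistic nanopore figure and exposed in
`ReadSimConfig`. Half the reads are emitted reverse-complemented. Read ids
encode the full ground truth (colony, tag pair, genotype) so any downstream
assignment can be audited.

What the generator does **not** emulate: optics (vignetting, flat-field,
point-spread), colony growth dynamics and lawns, agar autofluorescence
gradients, homopolymer-biased nanopore error, chimeric PCR products, and
carrier-level read-quality variation. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated model,
not camera- or chemistry-robustness on real plates and flow cells.

**Colony indexing.** On the bench, the experimenter picks colonies from the
photograph and assigns tag pairs to them; the demo generator reproduces
this by assigning tag pairs in (y, x) raster order, the same order in which
the detector reports colonies, which is what makes the phenotype–genotype
join on `colony_index` meaningful for synthetic data.

## Numerical and degenerate-input conventions

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give byte-identical
  images, FASTQ files and reports. There is no global random state.
- A blank or flat image yields an empty detection list, not an error; a
  bin with zero coverage-passing reads yields an undefined genotype and a
  failed QC, not an error.
- Equal alignment scores break ties toward the lexicographically lowest
  construct id and set an ambiguity flag; equal tag distances never break
  ties — the read is left unassigned.
- Rank correlations use Spearman's ρ throughout (scale-free, appropriate
  for cross-strain and input-ratio concordance); a constant vector makes
  the correlation undefined and it is reported as NaN.
- Problem sizes used by the bundled verification runs — 50-colony plates
  for detection, a 96-colony pool at 30 reads/colony for demultiplexing
  and genotyping, 20,000 reads for library profiling, and a 52-colony,
  13-part pipeline run for end-to-end recovery — were chosen as the
  smallest sizes at which the binomial/rank statistics being checked are
  stable.

## Known limitations

- Query coverage is span-based (first to last aligned base of the read);
  internal deletions inside the span are not subtracted.
- The end-to-end colony-index linkage relies on raster-order picking; two
  colonies at nearly identical y can swap order between truth and
  detection. The demo's placement keeps colonies separated enough that
  this does not occur at the bundled sizes.
- The assignment-rate ceiling discussed above is a property of 7-bp tags
  under a 1-edit budget; the package reports, but cannot overcome, the
  fraction of reads whose tags carry 2+ errors.
- Strain labels are free text; no cross-strain normalization is applied
  beyond each strain's own standard-circuit baseline.
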