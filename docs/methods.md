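# Methods

This note documents the models, parameter choices and numerical
conventions behind `acetydyn`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Coordinates and containers

All internal coordinates are 0-based half-open (BED convention); GTF
input is converted on read. Chromosomes sort naturally (chr1 < chr2 <
chr10). Signal lives on a fixed per-chromosome bin grid
(`SignalTrack`); values are per-base densities (FPKM-like), so window
means and resampling are length-weighted: a bedGraph record spanning
part of a bin contributes `value × overlap / bin_size`. Hi-C contacts
are dense symmetric per-chromosome matrices at fixed resolution, read
from upper-triangle triplet text; duplicate pairs are an error rather
than silently summed, so malformed exports surface immediately.

## Cross-stage scaling

Stages with broad versus narrow acetylation landscapes have
incomparable raw FPKM. The scaling procedure ranks promoters by mean
signal over TSS ± 2 kb and multiplies each stage by
`median(top-3000, reference) / median(top-3000, stage)`, ESC being the
reference with factor exactly 1. Two points were genuinely open and
are package decisions:

- the promoter window width is not prescribed by the procedure itself;
  ± 2 kb is used because it matches the promoter window used everywhere
  else in this analysis family (e.g. Polycomb-target promoters);
- the top-3,000 set is selected independently per track rather than
  frozen from the reference; ties in signal break by gene id so the
  selection is deterministic. With fewer than 3,000 genes all are used,
  with a warning.

A zero stage median is a degenerate track and raises. The procedure is
self-consistent: rescaling a stage by its own factor and recomputing
yields 1 to within 1e-9 (floating-point division only).

## Domain calling

The caller rebins scaled signal to the stage's working bin (1 kb for
broad oocyte/zygote landscapes, 500 bp for canonical-peak stages),
takes maximal runs of bins ≥ 3 scaled FPKM, and merges runs whose
end-to-end gap is ≤ 2 × bin size. "Within 2 × bin size" is read
inclusively; the gap is exposed as a parameter so the exclusive reading
is one flag away. The threshold applies to scaled FPKM, since scaled
signal feeds all downstream analysis. A merged domain's mean signal is
recomputed over the whole merged interval including sub-threshold gap
bins, so it may sit below the threshold even though every domain
contains at least one qualifying bin. Domains are called on combined
(allele-pooled) tracks by default; per-allele calling uses the same
path on allelic tracks.

## Transition clustering and profiles

Domain-transition clustering is k-means over a row-per-domain matrix of
positional signal (± 10 kb around the domain center, 100 bins per
stage, stage layers concatenated — the feature construction is a
package default, exposed as parameters). Determinism: fixed seed,
k-means++ seeding, 10 restarts, and labels renumbered by descending
cluster mean so label 0 is always the strongest cluster. Identical
rows collapse to fewer effective clusters; this is reported, not an
error.

Track correlations (Spearman by default, 5 kb bins) exclude bins where
both tracks are zero: sparse embryo tracks are otherwise dominated by
zero-zero ties. The flag is exposed. Metagene profiles rescale each
gene body to a fixed bin count with per-base averaging, reverse
minus-strand genes, and skip (and count) genes shorter than one track
bin per body bin. Peak-to-TSS distance is measured from the peak
midpoint (scale-free); < 1 kb is a promoter peak, > 2.5 kb distal,
between the bounds "other". Peak response thresholds (≤ 0.5× lost,
≥ 2× enhanced, pseudocount 0.5) are package defaults, not published
constants, and are configurable.

## Allelic analysis

Fragments are filtered at length ≥ 140 bp and MAPQ ≥ 30 with duplicates
dropped; each dropped fragment is tallied under the first rule it
fails. Assignment counts overlapped SNPs whose observed base matches
the maternal versus paternal genome: evidence on exactly one side
assigns the fragment; none leaves it unassigned; both sides mark it
conflicting and exclude it from both allelic tracks (consistent with
how split-read assigners treat conflicting reads). Bases matching
neither parental genome are ignored as sequencing errors in evidence.

Allelic tracks use fragment-coverage FPKM (fragments per kilobase of
bin per million assigned fragments, both alleles pooled as the library
size) on the same grid as combined tracks. Bias is per-bin
log2((M + 0.5)/(P + 0.5)) over bins with any signal; positive is
maternal-high, and swapping the tracks negates every ratio. Region
comparisons use a paired t-test on per-region maternal-minus-paternal
means — regions are matched between alleles, which argues for pairing;
the published analyses say only "t-test", so unpaired is available.
Zero variance of differences is flagged degenerate: identical signals
report t = 0 with one-sided p = 0.5 (the analytic null value), anything
else NaN.

## Repeat pseudo-genome

Each family's instances are concatenated in genomic order with 200-N
spacers between consecutive instances only (no terminal spacers);
minus-strand instances are reverse-complemented. The coordinate map
inverts every non-spacer base. Quantification is an exact-substring
placer for error-free synthetic reads — the scientific content here is
the pseudo-genome construction, not alignment. Reads matching k > 1
families split 1/k (expectation-style counting at desk scale); reads
spanning a spacer never match because N matches no base.

## Gene sets

Filters operate on DE tables (gene, two group-mean FPKMs, log2 fold
change oriented B over A, adjusted p). Fold changes compare on the
log2 scale against exact log2(cutoff) with no rounding. The "mean FPKM
≥ 1" requirement is read as max of the two group means — keeping genes
expressed in either condition; min-of-both and pooled-mean readings
would only shrink sets. Minor-ZGA direction: the transcription
inhibitor (DRB) blocks zygotic transcription, so ZGA transcripts drop
in treated samples; the filter takes genes significantly *down* in
treated versus control. Polycomb targets require the promoter mark
plus max FPKM strictly below 0.1 at every stage. Every set serializes
its cutoffs as provenance.

## Contact pile-ups

Anchor pairs are all same-chromosome distal-peak × promoter
combinations with bin separation in [min, max] (minimum 2 bins so the
window excludes the diagonal), deduplicated at bin resolution.
Observed is the mean (2w+1)² submatrix over pairs (w = 5 bins at 10 kb
by default, i.e. ± 50 kb; the pad is configurable). Controls shift
each pair uniformly along its chromosome while preserving its exact bin
separation — distance decay divides out without explicit
expected-by-distance modeling — with one shift and seed 0 by default.
Matrices are raw counts: no balancing, since the synthetic matrices are
unbiased by construction and balancing is out of scope. Out-of-bounds
pairs are dropped and counted, never clipped; zero-control cells are
masked NaN. Note a design consequence: if many anchors share one bin
separation, shifted controls sample the same diagonal the loops sit on
and the enrichment is diluted — anchor sets with mixed separations (the
realistic case) do not have this problem.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 2 × 5 Mb
chromosomes, 200 genes, SNPs at 1/kb (hybrid-cross density), 17
maternal and 4 paternal imprinting control regions, three repeat
families with 2% instance divergence. Stage parameters encode the
three waves — GV/zygote broad (30 domains, 20–80 kb, plateau 6 scaled
FPKM over background 0.5), MII sparse (6 domains, 2–6 kb), 2-cell
onward canonical (60–80 peaks, 1–3 kb, plateau 8). The zygote plants
the paternal asymmetry: plateau × 1.8 and intervals widened 25% per
side, and a sub-threshold (+2 FPKM) acetylation gain on the allele
opposite each imprinting control region's parent of origin, which makes
imprinted regions allele-biased without creating unplanted domains.
Domain placement is non-overlapping with generous gaps so planted
boundaries are unambiguous; boundaries snap to the stage's calling
grid. Noise is i.i.d. Gaussian per bin, clipped at zero.

Expression tables are synthesized directly from planted class
membership: true contrasts draw |log2FC| above the class cutoff with
padj log-uniform in [1e-8, cutoff/10]; null genes stay below |log2FC|
0.8 with padj in [0.2, 1]. The DE estimator itself is out of scope —
the filters are what is tested, and at zero noise they recover the
planted classes exactly.

All randomness flows through named substreams of one seed (crc32 of
the stream name mixed with the seed), so adding an output never
perturbs the others and a fixed seed reproduces byte-identical outputs.

What passing tests therefore show: the implementations are exact on
their defined contracts and recover planted structure under the stated
noise. What they do not show: robustness to mappability artifacts,
copy-number bias, fragment-length confounding, realistic repeat
homology between families, balanced-versus-raw Hi-C differences, or DE
miscalibration — none of which the generator emulates.

## Problem sizes

Default runs use the desk-scale genome above: the full pipeline
completes in a few seconds, and the test suite (including 1,000-vector
domain-caller oracle sweeps, 100-replicate t-test power simulations and
two full pipeline runs) in well under a minute.

## Known limitations

- The exact-substring repeat quantifier assumes error-free reads;
  divergent real reads need a real aligner upstream.
- Allelic FPKM counts whole-fragment overlaps per bin rather than
  base-resolution coverage; at 1 kb bins and ≥ 140 bp fragments the
  difference is a near-constant factor.
- The pile-up control is a single uniform shift per pair; it does not
  avoid other anchors or planted features (beyond what mixed
  separations make negligible).
- `compute_scale_factor` assumes the two tracks share a genome; it
  errors on mismatched chromosomes but does not attempt lift-over.
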