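# Methods

This note documents the statistical model behind `barcodesv`, the
parameters that matter, what the built-in simulator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## The generative picture

A linked-read library is modeled as a two-level point process:

1. **Molecules.** HMW DNA molecules arrive on the genome as a Poisson
   process with exponentially distributed lengths (mean `F` = 50 kb).
   ~10 molecules share each droplet partition, i.e. each barcode. The
   molecule coverage `C_mol` at any position equals
   `depth / coverage_per_molecule`; at 30x with 0.2x per molecule this is
   150 molecules.
2. **Read pairs.** Along a molecule, read-pair start positions follow a
   Poisson process with rate `lambda` (default 0.001/bp, i.e. ~1000 bp
   between pairs); each pair is 2 x 100 bp with insert size
   `N(400, 50^2)`. Per-molecule short-read coverage is
   `lambda * 2 * read_length = 0.2x`.

Both evidence types and all four test statistics derive from this picture.

### The gap threshold G

Same-barcode reads are chained into fragments whenever consecutive
read-pair start positions are closer than `G`. `G` is calibrated in two
passes: a provisional pass at 50 kb (safe for molecule integrity), then
`G` := the 99th percentile of the observed intra-fragment gap distribution
(lower-interpolation on the sorted array, hence deterministic). Under the
pure Poisson model the gap law is `Exp(lambda)` and
`G = ln(100)/lambda ~ 4.6 kb`; real libraries are overdispersed (molecule
length and rate heterogeneity), which fattens the gap tail and pushes `G`
into the 5–15 kb range. By construction 1% of true intra-molecule gaps
exceed `G`, so roughly half the molecules chance-split somewhere; this is
the deliberate price for sensitivity to SVs smaller than the molecule
length, and it is why a supporting endpoint lands within `G` of its
breakpoint with probability 0.99 per side (0.9801 per pair).

Gap distances are measured start-to-start between *collapsed read-pair
events* (a concordant pair becomes one event from leftmost start to
rightmost end; discordant pairs stay two events so a junction-straddling
pair cannot bridge its own breakpoints). Start-to-start makes the gap law
exactly exponential under the model, which the Gamma gap test assumes.

### Library parameters

| parameter | meaning | default / estimator |
|---|---|---|
| `G` | chaining distance (bp) | 99th pct of intra-fragment gaps |
| `lambda` | read-pair rate on a molecule (per bp) | `1 / mean(intra-fragment gap)` from the 50 kb pass |
| `N_ifp` | same-barcode fragment pairs genome-wide | `sum_b C(k_b, 2)` |
| `N_rp` | total read-pair events | counted |
| `mu, sigma` | insert-size moments (bp) | proper pairs, 0.1% tails trimmed |
| `min_mapq` | read filter | 20 |
| `min_reads_per_fragment` | fragment support | 2 (a single pair is a zero-length fragment with uninformative endpoints) |

`lambda` is estimated from the mean intra-fragment gap rather than the
reads/span ratio: the gap mean is the maximum-likelihood inverse rate
under the exponential gap law and is unbiased to within the negligible
50 kb truncation, whereas the reads/span ratio is inflated >10% by event
widths and two-read fragments.

## Type 1: endpoint-pair evidence

Every unordered same-barcode fragment pair yields one point per endpoint
plane (RL, LR, RR, LL; the fragment with the smaller linear midpoint is
F1). Coordinates are linearized head-to-tail over the chromosomes so
translocations use the same code path. Clusters are connected components
under Chebyshev distance < `G` (k-d tree + sparse connected components,
no all-pairs scan); clusters wider than `G x G` are reduced by a moving
`G x G` square (100 bp stride, ties toward the smallest breakpoint span).
Breakpoints are the square-corner coordinates appropriate to each plane's
geometry (max x / min y for RL, etc.).

Two tests gate a cluster of `n` points:

* **Barcode coincidence.** Under the null that all pairs are independent
  molecules that happened to share a barcode, endpoints are uniform on the
  plane and `p1 = P[Binom(N_ifp, (G/L)^2) >= n]` (survival function at
  `n-1`). The printed form of the multiplicity adjustment in the source
  material multiplies by `(G/L)^2 < 1`, which would *shrink* every p-value;
  the default here is the Bonferroni-consistent factor `(L/G)^2` capped at
  1, with `adjust_mode="printed"` available for comparison.
* **Gap lengths** (colinear RL geometry only). Under the rival null that
  F1 and F2 are one molecule whose middle simply went unsequenced, each
  reference gap `g_i = L(F2) - R(F1)` is `Exp(lambda)`, so the mean of `n`
  gaps is `Gamma(n, n*lambda)`; `p2` is its survival function evaluated at
  the observed mean (the evaluation point is left implicit in the source
  material), adjusted by `N_rp / n`. For LR/RR/LL and cross-chromosome
  geometry the one-molecule hypothesis is impossible under reference
  orientation and only the coincidence test gates the call.

Both applicable adjusted p-values must fall below `p_threshold` (1e-5);
`score1 = -log10(max of them)`, floored at 1e-300.

### Guards the uniform-plane null needs at small L

Four suppression rules remove pileup artifacts that the binomial null
does not model. They are no-ops at human-genome scale but essential on
megabase test genomes, and each has a physical reading:

* pairs whose facing reference gap is in `[0, 3G)` are chance-split
  molecule halves (`P[Exp gap > 3G | > G] = 1e-4`; a truly rearranged pair
  faces a gap at the SV scale) — without this rule the ~0.5 chance splits
  per molecule seed clusters in every plane;
* near-diagonal points (`|x - y| < 2G`) are self-pairs;
* endpoints within `G` of a chromosome boundary are masked (telomere-like
  endpoint pileups);
* a cluster must contain `min_support` (default 5) points *and* distinct
  barcodes — points sharing one fragment share its barcode and are not
  independent evidence.

Satellite clusters seeded by a real junction's endpoint column are removed
by keeping at most one call per junction (any call whose breakpoints come
within `G` of a stronger call's is dropped). RR and LL inversion clusters
with mutually consistent breakpoints (within `G`) merge into one inversion
with support-weighted mean breakpoints, summed support, and the stronger
score.

## Type 2: twin-window similarity

The scan counts, at every 100 bp boundary, the distinct barcodes `m1`,
`m2` of the two flanking windows (width `G` for WGS, 40 kb for WES), the
shared count `x`, and a distance term `d` = mean distance of left-window
read positions to the boundary + the same on the right. The counting is
O(unique (barcode, bin) pairs) via disjoint-interval difference arrays,
not per-boundary set operations. Boundaries with fewer than 10 barcodes a
side are skipped.

Similarity is `S = 2x/(m1+m2)` in simple (WGS) mode. The "fraction of
shared barcodes" has no printed denominator; the symmetric mean keeps
`S` in [0, 1] and invariant to barcode relabeling. In regression (WES)
mode `S = x/(m1^a m2^b) * n_lib * exp(-alpha d)` with parameters fitted by
least squares of `log x` on `(log m1, log m2, d, 1)` over boundaries with
`x >= 1`, so `S ~ 1` on null boundaries; inadmissible fits (a, b outside
(0, 1], alpha < 0, rank deficiency, <1000 points) fall back to simple
mode with a warning. The exact original regression is not printed in the
available material; this log-linear reconstruction recovers known
parameters within 10% on synthetic null data.

Candidates are boundaries below the 5th percentile of `S`; consecutive
sub-threshold runs collapse to their minimum. The p-value is empirical
over all scanned boundaries of the dataset; `score2 = -log10(p)`.

## Combination, refinement, VAF

Each type-1 breakpoint is independently matched to the nearest type-2
candidate within the scan window; `combined = score1 + score2a + score2b`
with unmatched ends contributing zero. Refinement searches 10 kb around
each breakpoint: discordant pairs (orientation per SV type, span beyond
`mu + 5*sigma` — the conventional read-pair threshold, unstated in the
source material) are clustered by proximity connected components;
junction-clip positions (clip >= 20 bp; read end for 3' clips, read start
for 5' clips) are tallied and the modal position (ties leftmost) with >= 2
supporting reads at *both* ends moves the call exactly there
(`refined = True`). Discordant-only support re-centers on the innermost
cluster coordinates (few-hundred-bp resolution, `refined = False`); no
support leaves the barcode-only call standing, which is precisely the
value of the method at repeat-mediated junctions. Clipped bases are not
re-aligned; supplementary alignments are not consumed.

VAF is estimated as `n_support / (n_support + spanning non-supporting
fragments)`, averaged over the two breakpoints — supporters terminate at
the junction and do not span it, so a homozygous event approaches 1.

## Small deletions (~1–10 kb)

Non-overlapping 500 bp windows, per haplotype (HP tag; pooled when
unphased, which catches homozygous events only). Candidates are maximal
runs of `m` windows below 10% of the haplotype's mean depth; windows above
20x the pooled mean (collapsed repeats) and within 50 kb of a chromosome
end (real molecule-coverage taper, `~1 - exp(-x/F)`) are masked. With
>= 3 straddling read pairs of the haplotype, the mean insert is tested
against `N(mu, sigma^2/n)` one-sided at 1e-5 (threshold reused from
`p_threshold`; unstated in the source material) and breakpoints are the
innermost pair coordinates; otherwise `p = (a/b)^m` with `a` the
genome-wide low-window count and `b` the total, called below 1e-10. The
independence assumption across windows is taken as printed — depth is
autocorrelated at the molecule scale, so `p` is optimistic; the 1e-10
threshold absorbs this in practice. Overlapping calls from the two
branches keep the insert-size breakpoints; calls restating a type-1
deletion (>= 50% reciprocal overlap) are dropped.

## The simulator

Coordinate-level: reads are emitted as pre-aligned records (positions,
clips, mates, BX/HP tags), not base calls, because the caller consumes
alignments. Molecules are placed as a *stationary* process — starts are
drawn on a pad-extended chromosome (6 mean molecule lengths) and reads
falling outside the chromosome are discarded — so an excerpt genome
behaves like an interior window of a real chromosome, without coverage
tapers or endpoint pileups at the boundaries.

SVs are applied as piecewise-linear segment maps from the variant genome
to the reference (deletion, tandem duplication, inversion, reciprocal
translocation; non-overlapping, coordinate-validated). One uniform draw
`u` per molecule fixes both its haplotype tag (`u < 0.5` -> HP1) and, per
SV with fraction `vaf`, variant status (`u < vaf`), so `vaf = 0.5` is a
haplotype-1 heterozygote, `vaf = 1` homozygous, `vaf < 0.5` mosaic within
haplotype 1. Reads crossing a junction keep their longer piece as the
primary alignment with the overhang soft-clipped — which is what produces
discordant mates, junction clips, split molecules and barcode
discontinuities with no further modeling. Output is reproducible to the
byte for a fixed seed; `write_alignment_file` round-trips the table
through a sorted, indexed BAM.

Defaults are the stated library geometry: 50 kb mean molecule length
(exponential), 10 molecules per partition, `lambda` = 0.001/bp, 2 x 100 bp
reads, insert 400 +- 50, 30x depth. Read length 100 (not 150) is forced
by the joint constraints 0.2x per-molecule coverage *and* ~1000 bp
read-pair spacing: `0.2 = lambda * 2 * read_length` has no solution at
150 bp with `lambda = 0.001`.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: sequencing errors and mappability (mapq is
uniformly 60; an optional repeat-BED can zero it), GC and capture bias,
overdispersed molecule lengths and read rates (so `G ~ 4.6 kb` here vs
5–15 kb in real libraries), barcode collisions beyond the partition model,
chimeric molecules, and real SV breakpoint homology. Exome mode
down-samples a WGS table at read-pair granularity (a pair survives iff
either mate overlaps a padded target), preserving pair integrity but not
a real capture-efficiency profile.

## Evaluation

Interval SVs match truth at strictly >50% reciprocal overlap with equal
type; translocations match when both junction ends agree within 1 kb.
Matching is greedy one-to-one; recall, precision and F1 follow. Empty
truth leaves recall undefined rather than zero.

## Problem sizes in the tests and the acceptance script

All checks run on simulated megabase-scale genomes: 10 Mb for the
coverage identity and null calibration, 2.5–4.5 Mb per replicate
elsewhere (flanks of >= 0.75 Mb around each SV, far beyond the molecule
scale that the measured quantities depend on). The fragment-coverage
identity (150 molecules at 30x / 0.2x) is measured on fragments chained
at the 50 kb molecule-integrity distance: chaining at the final `G`
over-splits 1% of gaps per molecule by construction and trims molecule
ends, measuring the reconstruction's intentional SV sensitivity (~133)
rather than the coverage identity itself (~145; the residual ~3% is the
one mean read-pair spacing per molecule end that no reconstruction can
observe).

## Known limitations

* The binomial null treats all `N_ifp` pairs as independent; pairs
  sharing a fragment are not, and on toy genomes (~2 Mb) the `(L/G)^2`
  correction is only marginally protective for n ~ 8 clusters near real
  junction pileups — satellite calls can survive next to a true event's
  junction. The effect shrinks as `L^(2-2n)` and is negligible at real
  genome scale.
* Insertions and repeat expansions are not detected (no evidence model);
  assembly-based sub-kilobase deletion calling is out of scope.
* No genotyping (ref/het/hom likelihoods) and no complex-SV
  reconstruction; phasing is consumed (HP tags), never computed.
* The depth-only small-deletion p-value ignores window autocorrelation
  (see above).
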