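# barcodesv

Structural-variant (SV) calling from **barcoded linked-read sequencing**
(10x Genomics Chromium-style libraries), built around the long-range
information carried by molecule barcodes rather than by individual short
reads.

In linked-read sequencing, high-molecular-weight (HMW) DNA molecules of
~50 kb are dispersed into droplet partitions (~10 molecules per partition),
amplified with a partition-specific barcode, and sequenced as ordinary
paired-end short reads. Reads sharing a barcode can be chained back into
*fragments* — computational reconstructions of the original molecules. A
molecule that spans an SV junction reconstructs into **two** fragments whose
facing endpoints mark the two breakpoints. Because ~150 molecules cover any
position of a 30x dataset (0.2x short-read coverage per molecule), even a
10%-VAF mosaic SV is supported by ~15 independent molecules where ordinary
short-read callers see ~3 read pairs.

`barcodesv` detects and scores two independent barcode-derived evidence
types and combines them:

**Type 1 — enriched fragment-endpoint pairs.** Every same-barcode fragment
pair (F1, F2) is a point in a 2D plane, e.g. (R(F1), L(F2)) with R/L the
right/left endpoints in head-to-tail linearized genome coordinates. Points
from coincidental barcode sharing are uniform over the L x L plane; true
supporting pairs concentrate in a G x G square cornered at the breakpoint
pair, where G is the 99th percentile of the intra-fragment gap-distance
distribution (calibrated per dataset, 50 kb first pass). Clusters found with
a k-d tree are scored by

* a binomial tail test: `p1 = P[Binom(N_ifp, (G/L)^2) >= n]`, adjusted for
  the ~`(L/G)^2` testable squares (`N_ifp` = same-barcode fragment pairs
  genome-wide), and
* a gap test for colinear deletion geometry: under the rival "one molecule,
  unsequenced middle" hypothesis the mean of n reference gaps follows
  `Gamma(n, n*lambda)` with `lambda` the per-molecule read-pair rate;
  the survival probability at the observed mean gap is adjusted by `N_rp/n`.

A call needs both applicable adjusted p-values below 1e-5;
`score1 = -log10(max of them)`. The endpoint-pattern geometry (RL/LR/RR/LL
plane, chromosomes) classifies DEL / DUP / INV / TRA.

**Type 2 — twin-window barcode similarity.** Two adjacent windows share
almost all barcodes — except across a breakpoint. A twin window (width G for
WGS, 40 kb for WES) slides in 100 bp steps; similarity is the shared-barcode
fraction `S = 2x/(m1+m2)`, or for capture data a regression-calibrated model
`S = x / (m1^a m2^b) * n * exp(-alpha*d)` fitted so S ~ 1 on null windows.
Candidates are the lowest 5th percentile of S; `score2 = -log10(empirical p)`.

Final calls carry `combined = score1 + score2a + score2b`, are refined to
base-pair resolution with discordant mate pairs and junction-clipped reads
when short-read support exists near the junctions, and get a VAF estimate
from the supporting-fragment fraction. Deletions of ~1–10 kb (below the
endpoint evidence's resolution) are called separately from haplotype-aware
500 bp depth windows plus an insert-size test (`N(mu, sigma^2/n)`), with a
depth-only fallback `p = (a/b)^m` at 1e-10.

A **coordinate-level linked-read simulator** (molecules, Poisson read-pair
process, SV spike-in at arbitrary VAF, WES down-sampling, truth ledger) makes
the whole pipeline testable without any external data.

## Worked example

```python
from barcodesv import SimConfig, SVSpec, simulate
from barcodesv.pipeline import run_call

cfg = SimConfig(chrom_lengths={"chr1": 3_000_000}, depth=30.0,
                svs=[SVSpec("DEL", "chr1", 1_000_000, 1_500_000, vaf=0.2)],
                seed=11)
res = simulate(cfg)
out = run_call(res.table, res.genome)
print(f"G = {out.stats.gap_threshold} bp, lambda = {out.stats.lambda_rate:.2e}/bp, "
      f"N_ifp = {out.stats.n_ifp}, depth = {out.stats.mean_depth:.1f}x")
for c in out.calls:
    print(f"{c.sv_type} {c.chrom1}:{c.pos1}-{c.pos2}  support={c.n_support} "
          f"score1={c.score1:.1f} score2a={c.score2a:.1f} score2b={c.score2b:.1f} "
          f"combined={c.combined_score:.1f} refined={c.refined} VAF={c.vaf_estimate:.2f}")
```

prints

```
G = 4594 bp, lambda = 1.03e-03/bp, N_ifp = 57948, depth = 29.4x
DEL chr1:1000000-1500000  support=22 score1=34.5 score2a=4.5 score2b=3.0 combined=42.0 refined=False VAF=0.18
```

The 500 kb deletion spiked in at 20% VAF is recovered at its exact
breakpoints with 22 supporting fragment pairs (~0.2 x 150 molecules, minus
split halves too sparse to reconstruct), both twin-window breakpoints
matched, and a VAF estimate of 0.18 — the mosaic fraction read directly off
the molecule support.

The same pipeline runs from the shell on any coordinate-sorted, indexed BAM
with `BX` barcode tags (and optional `HP` haplotype tags):

```bash
barcodesv simulate --genome-length 2500000 --depth 30 \
    --sv DEL:chr1:800000:1600000 --seed 7 --out-prefix sim
barcodesv call sim.bam --out-prefix calls           # BEDPE + VCF 4.2
barcodesv evaluate --calls calls.bedpe --truth sim.truth.bedpe
```

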