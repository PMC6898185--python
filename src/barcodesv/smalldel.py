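"""Haplotype-aware detection of small deletions (roughly 1-10 kb).

Deletions below the resolution of the fragment-endpoint evidence still
leave two short-read footprints: a per-haplotype read-depth hole and
inflated insert sizes of the read pairs that straddle it. The scan walks
non-overlapping 500 bp windows and flags runs of m consecutive windows
where one haplotype's depth falls below 10% of that haplotype's mean
(windows above 20x the pooled mean are masked -- collapsed repeats).

Each candidate run is then tested two ways:

* insert size -- the mean template length of the n straddling read pairs
  of the affected haplotype is compared against N(mu, sigma^2/n); a
  significant upper tail calls a deletion with breakpoints at the
  innermost read-pair coordinates;
* depth only -- when fewer than 3 pairs straddle the hole, the run itself
  is scored as p = (a/b)^m (a = genome-wide count of low windows, b =
  total windows, independence across windows assumed) and called when
  p < 1e-10.

On unphased data the haplotypes pool, which can only catch homozygous
events; phased input is strongly preferred.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import DatasetStats, GenomeIndex

DEFAULT_WINDOW = 500
LOW_DEPTH_FRACTION = 0.10
HIGH_DEPTH_MULTIPLE = 20.0
DEFAULT_P_INSERT = 1e-5
DEFAULT_P_DEPTH = 1e-10
MIN_SPANNING_PAIRS = 3


@dataclasses.dataclass
class DepthCandidate:
    chrom_id: int
    start: int          # bp, run start (window-aligned)
    end: int            # bp, run end (exclusive)
    haplotype: int      # 1, 2, or 0 (pooled / unphased)
    m: int              # consecutive low windows


@dataclasses.dataclass
class SmallDeletionCall:
    chrom: str
    start: int
    end: int
    haplotype: int
    p_value: float
    evidence: str       # "DEPTH_INSERT" or "DEPTH_ONLY"
    n_pairs: int = 0
    m_windows: int = 0


def window_depths(table: pd.DataFrame, genome: GenomeIndex,
                  window: int = DEFAULT_WINDOW,
                  haplotype: int | None = None) -> dict[int, np.ndarray]:
    """Read-base depth per non-overlapping window, per chromosome.

    ``haplotype``: 1 or 2 restricts to reads with that tag; None pools all
    reads. Returns {chrom_id: depth array}.
    """
    sel = np.ones(len(table), dtype=bool)
    if haplotype is not None:
        sel = table["hap"].to_numpy() == haplotype
    chrom = table["chrom_id"].to_numpy()[sel]
    pos = table["pos"].to_numpy()[sel]
    end = table["end"].to_numpy()[sel]
    out = {}
    for cid in range(len(genome.names)):
        nbin = int(genome.lengths[cid]) // window + 1
        bases = np.zeros(nbin, dtype=np.float64)
        m = chrom == cid
        p, e = pos[m], end[m]
        b0 = p // window
        b1 = (e - 1) // window
        same = b0 == b1
        np.add.at(bases, b0[same], (e - p)[same])
        sp = np.flatnonzero(~same)
        for i in sp:  # reads shorter than the window touch <= 2 bins
            a, b = p[i], e[i]
            for bb in range(b0[i], b1[i] + 1):
                lo = max(a, bb * window)
                hi = min(b, (bb + 1) * window)
                bases[bb] += hi - lo
        out[cid] = bases / window
    return out


def scan_low_depth(table: pd.DataFrame, genome: GenomeIndex,
                   window: int = DEFAULT_WINDOW,
                   low_fraction: float = LOW_DEPTH_FRACTION,
                   high_multiple: float = HIGH_DEPTH_MULTIPLE,
                   phased: bool | None = None,
                   edge_margin: int = 50_000,
                   ) -> tuple[list[DepthCandidate], dict[int, int], int]:
    """Find runs of consecutive low-depth windows per haplotype.

    Returns ``(candidates, low_counts, total_windows)`` where
    ``low_counts[hap]`` is the genome-wide number of low windows of that
    haplotype (the a of p = (a/b)^m) over the scanned (non-masked)
    windows, and ``total_windows`` is b. ``phased=None`` auto-detects
    haplotype tags. Windows within ``edge_margin`` (default one mean
    molecule length) of a chromosome boundary are masked: molecule
    coverage genuinely tapers toward a reference edge -- no molecule
    extends past it, so depth at distance x is ~(1 - exp(-x/50 kb)) of
    the interior mean -- which would otherwise read as a deletion.
    """
    if phased is None:
        phased = bool((table["hap"].to_numpy() > 0).any())
    haps = (1, 2) if phased else (0,)

    pooled = window_depths(table, genome, window, haplotype=None)
    pooled_mean = np.mean([d.mean() for d in pooled.values()]) if pooled else 0.0

    candidates: list[DepthCandidate] = []
    low_counts: dict[int, int] = {}
    total_windows = 0
    for hap in haps:
        depths = (window_depths(table, genome, window, haplotype=hap)
                  if hap else pooled)
        hap_mean = np.mean([d.mean() for d in depths.values()])
        n_low = 0
        n_tot = 0
        for cid, dep in depths.items():
            mask_high = pooled[cid] > high_multiple * pooled_mean
            scanned = ~mask_high
            edge_bins = max(1, edge_margin // window)
            scanned[:edge_bins] = False
            scanned[-edge_bins:] = False
            n_tot += int(scanned.sum())
            low = (dep < low_fraction * hap_mean) & scanned
            n_low += int(low.sum())
            # maximal runs of consecutive low windows
            idx = np.flatnonzero(low)
            if idx.size == 0:
                continue
            run_start = np.r_[True, np.diff(idx) > 1]
            rid = np.cumsum(run_start) - 1
            for r in range(rid[-1] + 1):
                members = idx[rid == r]
                candidates.append(DepthCandidate(
                    chrom_id=cid,
                    start=int(members[0]) * window,
                    end=(int(members[-1]) + 1) * window,
                    haplotype=hap,
                    m=len(members)))
        low_counts[hap] = n_low
        if hap == haps[0]:
            total_windows = n_tot
    return candidates, low_counts, total_windows


def spanning_pairs(table: pd.DataFrame, candidate: DepthCandidate
                   ) -> pd.DataFrame:
    """Read pairs of the candidate's haplotype whose inner gap covers the
    candidate midpoint (left mate rows only)."""
    mid = (candidate.start + candidate.end) // 2
    sel = (
        (table["chrom_id"].to_numpy() == candidate.chrom_id)
        & (table["insert_size"].to_numpy() > 0)
        & (table["mate_chrom_id"].to_numpy() == table["chrom_id"].to_numpy())
        & (table["end"].to_numpy() <= mid)
        & (table["mate_pos"].to_numpy() >= mid)
    )
    if candidate.haplotype:
        sel &= table["hap"].to_numpy() == candidate.haplotype
    return table[sel]


def test_insert_size(pairs: pd.DataFrame, stats: DatasetStats) -> float:
    """One-sided upper-tail p-value of the mean insert size of n pairs
    under N(mu, sigma^2/n)."""
    n = len(pairs)
    if n < 1:
        raise ValueError("no pairs to test")
    mean_ins = float(pairs["insert_size"].to_numpy(dtype=np.float64).mean())
    z = (mean_ins - stats.insert_mu) / (stats.insert_sigma / np.sqrt(n))
    return float(sps.norm.sf(z))


def test_depth_only(a_low: int, b_total: int, m: int) -> float:
    """p = (a/b)^m for a run of m low windows (a conservatively floored at
    1 so a clean genome still yields a finite p)."""
    if m <= 0:
        return 1.0
    a = max(a_low, 1)
    return float((a / b_total) ** m)


def call_small_deletions(
    table: pd.DataFrame,
    genome: GenomeIndex,
    stats: DatasetStats,
    window: int = DEFAULT_WINDOW,
    min_size: int = 1000,
    max_size: int = 10_000,
    p_insert_threshold: float = DEFAULT_P_INSERT,
    p_depth_threshold: float = DEFAULT_P_DEPTH,
    phased: bool | None = None,
) -> list[SmallDeletionCall]:
    """Run the depth scan and both tests; emit merged deletion calls.

    Candidates between ``min_size`` and ``max_size`` go through the
    insert-size branch when >= 3 spanning pairs exist, otherwise (or when
    not significant) through the depth-only branch. Overlapping calls from
    the two branches are merged keeping the insert-size breakpoints.
    """
    candidates, low_counts, b_total = scan_low_depth(
        table, genome, window=window, phased=phased)
    calls: list[SmallDeletionCall] = []
    for cand in candidates:
        size = cand.end - cand.start
        if size < min_size:
            continue
        made_insert_call = False
        if size <= max_size:
            pairs = spanning_pairs(table, cand)
            if len(pairs) >= MIN_SPANNING_PAIRS:
                p = test_insert_size(pairs, stats)
                if p < p_insert_threshold:
                    b1 = int(pairs["end"].to_numpy().max())
                    b2 = int(pairs["mate_pos"].to_numpy().min())
                    if b2 > b1:
                        calls.append(SmallDeletionCall(
                            chrom=genome.names[cand.chrom_id],
                            start=b1, end=b2, haplotype=cand.haplotype,
                            p_value=p, evidence="DEPTH_INSERT",
                            n_pairs=len(pairs), m_windows=cand.m))
                        made_insert_call = True
        if not made_insert_call:
            p = test_depth_only(low_counts[cand.haplotype], b_total, cand.m)
            if p < p_depth_threshold:
                calls.append(SmallDeletionCall(
                    chrom=genome.names[cand.chrom_id],
                    start=cand.start, end=cand.end,
                    haplotype=cand.haplotype,
                    p_value=p, evidence="DEPTH_ONLY", m_windows=cand.m))

    # merge overlaps, preferring the (more precise) insert-size breakpoints
    calls.sort(key=lambda c: (c.chrom, c.start))
    merged: list[SmallDeletionCall] = []
    for c in calls:
        if merged:
            prev = merged[-1]
            if (prev.chrom == c.chrom and prev.haplotype == c.haplotype
                    and c.start < prev.end):
                if prev.evidence == "DEPTH_ONLY" and c.evidence == "DEPTH_INSERT":
                    merged[-1] = c
                continue
        merged.append(c)
    return merged
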