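"""Evidence combination, short-read breakpoint refinement and VAF estimates.

Type 1 gives breakpoint *pairs*; type 2 gives single positions where the
barcodes change abruptly. Each type-1 call is matched, independently at
both of its breakpoints, to the nearest type-2 candidate within the scan
window; the combined confidence score is the sum

    combined = score1 + score2a + score2b

with unmatched breakpoints contributing zero. Breakpoints are then refined
against the short reads: discordant mate pairs (orientation and span
inconsistent with the reference, clustered by proximity) re-center the
call to a few-hundred-bp resolution, and junction-clipped reads at both
ends pin it to base-pair resolution. Barcode evidence stands alone when no
short-read support exists near the junctions (repeat-mediated breakpoints)
-- the call is simply left unrefined.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dataset import DatasetStats, GenomeIndex
from .fragments import fragments_covering
from .type1 import TypeOneCall

DEFAULT_SEARCH_RADIUS = 10_000
DEFAULT_MIN_CLIP = 20
DEFAULT_MIN_SPLIT_READS = 2
DEFAULT_MIN_DISCORDANT = 2


@dataclasses.dataclass
class SVCall:
    """A final, typed, scored structural-variant call."""

    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    score1: float
    score2a: float = 0.0
    score2b: float = 0.0
    n_support: int = 0
    n_discordant: int = 0
    n_split: int = 0
    refined: bool = False
    vaf_estimate: float | None = None
    evidence: str = "BARCODE"
    frag1_rows: np.ndarray | None = None
    frag2_rows: np.ndarray | None = None

    @property
    def combined_score(self) -> float:
        return self.score1 + self.score2a + self.score2b


def merge_evidence(
    type1_calls: list[TypeOneCall],
    type2_candidates: pd.DataFrame,
    genome: GenomeIndex,
    match_dist: int,
) -> list[SVCall]:
    """Attach type-2 scores to type-1 breakpoint pairs.

    Each breakpoint is matched to the nearest type-2 candidate on its
    chromosome within ``match_dist`` (default: the scan window size);
    unmatched breakpoints score zero.
    """
    cand_chrom = type2_candidates["chrom_id"].to_numpy() if len(
        type2_candidates) else np.array([], dtype=int)
    cand_pos = type2_candidates["pos"].to_numpy() if len(
        type2_candidates) else np.array([], dtype=int)
    cand_score = type2_candidates["score2"].to_numpy() if len(
        type2_candidates) else np.array([], dtype=float)

    def best_score(chrom_name: str, pos: int) -> float:
        cid = genome.chrom_id(chrom_name)
        sel = np.flatnonzero(cand_chrom == cid)
        if sel.size == 0:
            return 0.0
        dist = np.abs(cand_pos[sel] - pos)
        j = int(np.argmin(dist))
        return float(cand_score[sel[j]]) if dist[j] <= match_dist else 0.0

    out = []
    for c in type1_calls:
        out.append(SVCall(
            sv_type=c.sv_type, chrom1=c.chrom1, pos1=c.pos1,
            chrom2=c.chrom2, pos2=c.pos2,
            score1=c.score1,
            score2a=best_score(c.chrom1, c.pos1),
            score2b=best_score(c.chrom2, c.pos2),
            n_support=c.n_support,
            frag1_rows=c.frag1_rows, frag2_rows=c.frag2_rows,
        ))
    return out


def _proximity_clusters(positions: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Connected components of positions under gap <= max_gap (1D)."""
    if positions.size == 0:
        return []
    order = np.argsort(positions)
    ps = positions[order]
    new = np.r_[True, np.diff(ps) > max_gap]
    cid = np.cumsum(new) - 1
    return [order[cid == c] for c in range(cid[-1] + 1)]


def _discordant_mask(table: pd.DataFrame, sv_type: str, c1: int, c2: int,
                     w1: tuple[int, int], w2: tuple[int, int],
                     max_concordant_span: float) -> np.ndarray:
    """Reads in window 1 whose mates sit in window 2 with the orientation
    and span expected for ``sv_type``."""
    chrom = table["chrom_id"].to_numpy()
    pos = table["pos"].to_numpy()
    mpos = table["mate_pos"].to_numpy()
    mchrom = table["mate_chrom_id"].to_numpy()
    strand = table["strand"].to_numpy()
    mstrand = table["mate_strand"].to_numpy()

    in1 = (chrom == c1) & (pos >= w1[0]) & (pos < w1[1])
    mate2 = (mchrom == c2) & (mpos >= w2[0]) & (mpos < w2[1])
    base = in1 & mate2
    if sv_type == "TRA":
        if c1 != c2:
            return base
        return base & (np.abs(mpos - pos) > max_concordant_span)
    span_ok = np.abs(mpos - pos) > max_concordant_span
    if sv_type == "DEL":
        return base & span_ok & (strand == 0) & (mstrand == 1) & (mpos > pos)
    if sv_type == "DUP":
        return base & span_ok & (strand == 1) & (mstrand == 0) & (mpos > pos)
    if sv_type == "INV":
        return base & span_ok & (strand == mstrand)
    raise ValueError(f"unknown sv_type {sv_type!r}")


def refine_breakpoints(
    call: SVCall,
    table: pd.DataFrame,
    stats: DatasetStats,
    genome: GenomeIndex,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    min_clip: int = DEFAULT_MIN_CLIP,
    min_split_reads: int = DEFAULT_MIN_SPLIT_READS,
    min_discordant: int = DEFAULT_MIN_DISCORDANT,
) -> SVCall:
    """Refine one call with discordant mate pairs and clipped reads.

    Within ``search_radius`` of each predicted breakpoint, discordant
    pairs (mate in the partner window, orientation matching the SV type,
    span beyond mu + 5 sigma) are clustered by proximity; clip-position
    candidates (read start for 5' clips, read end for 3' clips, clip
    length >= ``min_clip``) are tallied per window. If a modal clip
    position with >= ``min_split_reads`` support exists at *both* ends,
    the breakpoints move there exactly and ``refined`` is set; with
    discordant support only, the call re-centers on the innermost
    coordinates of the largest cluster (few-hundred-bp resolution,
    ``refined`` stays False). No support leaves the call untouched.
    Refinement is idempotent and never moves a breakpoint by more than
    the search radius.
    """
    c1 = genome.chrom_id(call.chrom1)
    c2 = genome.chrom_id(call.chrom2)
    w1 = (call.pos1 - search_radius, call.pos1 + search_radius)
    w2 = (call.pos2 - search_radius, call.pos2 + search_radius)
    max_span = stats.insert_mu + 5 * stats.insert_sigma

    disc = _discordant_mask(table, call.sv_type, c1, c2, w1, w2, max_span)
    idx = np.flatnonzero(disc)
    n_disc = 0
    disc_b1 = disc_b2 = None
    if idx.size:
        clusters = _proximity_clusters(table["pos"].to_numpy()[idx],
                                       int(max_span))
        best = max(clusters, key=len)
        if len(best) >= min_discordant:
            rows = idx[best]
            n_disc = len(rows)
            ends = table["end"].to_numpy()[rows]
            mposs = table["mate_pos"].to_numpy()[rows]
            if call.sv_type in ("DEL", "TRA"):
                disc_b1 = int(ends.max())
                disc_b2 = int(mposs.min())
            elif call.sv_type == "DUP":
                disc_b1 = int(table["pos"].to_numpy()[rows].min())
                disc_b2 = int((mposs + (ends - table["pos"].to_numpy()[rows])).max())
            else:  # INV: junction side depends on the cluster's strand
                disc_b1 = int(ends.max())
                disc_b2 = int(mposs.min())

    def modal_clip(cid: int, window: tuple[int, int]) -> tuple[int | None, int]:
        chrom = table["chrom_id"].to_numpy()
        pos = table["pos"].to_numpy()
        end = table["end"].to_numpy()
        in_w = (chrom == cid) & (end > window[0]) & (pos < window[1])
        cand = np.concatenate([
            end[in_w & (table["clip3"].to_numpy() >= min_clip)],
            pos[in_w & (table["clip5"].to_numpy() >= min_clip)],
        ])
        cand = cand[(cand >= window[0]) & (cand < window[1])]
        if cand.size == 0:
            return None, 0
        vals, counts = np.unique(cand, return_counts=True)
        # modal position, ties broken leftmost (np.unique sorts ascending)
        j = int(np.argmax(counts))
        return int(vals[j]), int(counts[j])

    clip1, nclip1 = modal_clip(c1, w1)
    clip2, nclip2 = modal_clip(c2, w2)

    new = dataclasses.replace(call)
    new.n_discordant = n_disc
    if (clip1 is not None and nclip1 >= min_split_reads
            and clip2 is not None and nclip2 >= min_split_reads):
        new.pos1, new.pos2 = clip1, clip2
        new.n_split = nclip1 + nclip2
        new.refined = True
    elif disc_b1 is not None:
        new.pos1 = int(np.clip(disc_b1, w1[0], w1[1] - 1))
        new.pos2 = int(np.clip(disc_b2, w2[0], w2[1] - 1))
        new.refined = False
    if new.sv_type != "TRA" and new.chrom1 == new.chrom2 and new.pos1 > new.pos2:
        new.pos1, new.pos2 = new.pos2, new.pos1
    return new


def estimate_vaf(call: SVCall, fragments: pd.DataFrame,
                 genome: GenomeIndex) -> SVCall:
    """Supporting-fragment fraction at the two breakpoints.

    vaf = n_support / (n_support + spanning non-supporting fragments),
    averaged over the two breakpoints; absent when nothing spans either
    breakpoint. Fragments that terminate at the junction (the supporters)
    do not span it, so a homozygous event approaches 1.
    """
    support = set()
    if call.frag1_rows is not None:
        support.update(call.frag1_rows.tolist())
    if call.frag2_rows is not None:
        support.update(call.frag2_rows.tolist())
    n_s = call.n_support
    ratios = []
    for chrom_name, pos in ((call.chrom1, call.pos1), (call.chrom2, call.pos2)):
        cid = genome.chrom_id(chrom_name)
        sel = ((fragments["chrom_id"].to_numpy() == cid)
               & (fragments["L"].to_numpy() <= pos)
               & (fragments["R"].to_numpy() > pos))
        spanning = set(np.flatnonzero(sel).tolist()) - support
        denom = n_s + len(spanning)
        if denom > 0:
            ratios.append(n_s / denom)
    vaf = float(np.mean(ratios)) if ratios else None
    return dataclasses.replace(call, vaf_estimate=vaf)
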