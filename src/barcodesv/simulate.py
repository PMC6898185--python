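"""Coordinate-level linked-read simulator with SV spike-in and evaluation.

The generator emulates the linked-read library geometry directly in
coordinate space, skipping base calls entirely (the caller consumes
alignments, not sequence): high-molecular-weight molecules of exponentially
distributed length (mean 50 kb) are placed uniformly on a diploid genome,
~10 molecules share each barcode partition, and each molecule emits read
pairs by a Poisson process with rate ``read_pair_rate`` per bp (default
0.001, i.e. ~1000 bp between read pairs and ~0.2x short-read coverage per
molecule at 2 x 100 bp reads). Total depth fixes the molecule count:
``depth = molecules_per_position * coverage_per_molecule``, so 30x depth
means ~150 molecules covering every position.

Structural variants are spiked in at arbitrary variant allele fraction by
drawing each molecule's allele: one uniform ``u`` per molecule drives both
the haplotype tag (``u < 0.5`` -> haplotype 1) and, for each SV with
fraction ``vaf``, whether the molecule carries the variant (``u < vaf``).
Molecules live on the *variant* genome of their allele and their reads are
mapped back to reference coordinates through a piecewise-linear segment
map, which naturally produces every downstream signal: split molecules
(fragment endpoint pairs), barcode discontinuities (twin-window drops),
discordant mates, and junction-clipped reads.
"""
from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import GenomeIndex

SV_TYPES = ("DEL", "DUP", "INV", "TRA")


@dataclasses.dataclass
class SVSpec:
    """One spiked-in SV. For same-chromosome types ``pos1 < pos2`` delimit
    the affected interval; for TRA the two positions are the junction ends
    on the two chromosomes."""

    sv_type: str
    chrom1: str
    pos1: int
    pos2: int
    chrom2: str | None = None     # None -> same as chrom1
    vaf: float = 1.0

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError("vaf must be in (0, 1]")
        if self.chrom2 is None:
            self.chrom2 = self.chrom1
        if self.sv_type != "TRA" and self.pos2 <= self.pos1:
            raise ValueError("pos2 must exceed pos1")


@dataclasses.dataclass
class SimConfig:
    """Study conditions of a simulated linked-read run (defaults: WGS at
    30x with the standard library geometry)."""

    chrom_lengths: dict[str, int]
    mean_molecule_length: float = 50_000.0
    molecules_per_partition: int = 10
    read_pair_rate: float = 0.001      # read pairs per bp along a molecule
    read_length: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    depth: float = 30.0                # total read-base depth
    svs: list[SVSpec] = dataclasses.field(default_factory=list)
    phased: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, ln in self.chrom_lengths.items():
            if ln <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if min(self.mean_molecule_length, self.read_pair_rate,
               self.insert_mean, self.insert_sd, self.depth) <= 0:
            raise ValueError("rates and lengths must be positive")

    @property
    def coverage_per_molecule(self) -> float:
        return self.read_pair_rate * 2 * self.read_length


@dataclasses.dataclass
class TruthRecord:
    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    vaf: float
    supporting_molecules: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([], dtype=np.int64))


@dataclasses.dataclass
class SimResult:
    table: pd.DataFrame           # alignment table (dataset.TABLE_COLUMNS)
    molecules: pd.DataFrame
    truth: list[TruthRecord]
    genome: GenomeIndex
    config: SimConfig


class SegmentMap:
    """Piecewise-linear map from a variant genome to reference coordinates.

    The variant genome is the reference with a set of non-overlapping SVs
    applied; each variant chromosome is a concatenation of oriented
    reference segments. Junction positions (in variant coordinates) are
    recorded per SV so ground truth can name the molecules that straddle
    them.
    """

    def __init__(self, genome: GenomeIndex, svs: Sequence[SVSpec]):
        self.genome = genome
        per_chrom: dict[int, list[SVSpec]] = defaultdict(list)
        tra: list[SVSpec] = []
        for sv in svs:
            if sv.sv_type == "TRA":
                tra.append(sv)
            else:
                c1, c2 = genome.chrom_id(sv.chrom1), genome.chrom_id(sv.chrom2)
                if c1 != c2:
                    raise ValueError("DEL/DUP/INV must be intra-chromosomal")
                per_chrom[c1].append(sv)

        tra_chroms = set()
        for sv in tra:
            tra_chroms.add(genome.chrom_id(sv.chrom1))
            tra_chroms.add(genome.chrom_id(sv.chrom2))
        if tra_chroms & set(per_chrom):
            raise ValueError("a chromosome cannot carry both a TRA and "
                             "another SV in one simulation")

        chrom_segments: dict[int, list[tuple[int, int, int, int]]] = {}
        junction_offsets: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for cid in range(len(genome.names)):
            L = int(genome.lengths[cid])
            segs: list[tuple[int, int, int, int]] = []
            cur = 0
            varpos = 0
            for sv in sorted(per_chrom.get(cid, []), key=lambda s: s.pos1):
                b1, b2 = int(sv.pos1), int(sv.pos2)
                if b1 < cur:
                    raise ValueError("overlapping SVs on one chromosome")
                if b2 > L:
                    raise ValueError(f"SV outside chromosome bounds: {sv}")
                sid = id(sv)
                if sv.sv_type == "DEL":
                    segs.append((cid, cur, b1, +1)); varpos += b1 - cur
                    junction_offsets[cid].append((sid, varpos))
                    cur = b2
                elif sv.sv_type == "INV":
                    segs.append((cid, cur, b1, +1)); varpos += b1 - cur
                    junction_offsets[cid].append((sid, varpos))
                    segs.append((cid, b1, b2, -1)); varpos += b2 - b1
                    junction_offsets[cid].append((sid, varpos))
                    cur = b2
                elif sv.sv_type == "DUP":
                    segs.append((cid, cur, b2, +1)); varpos += b2 - cur
                    junction_offsets[cid].append((sid, varpos))
                    segs.append((cid, b1, b2, +1)); varpos += b2 - b1
                    cur = b2
            segs.append((cid, cur, L, +1))
            chrom_segments[cid] = segs

        for sv in tra:
            cA, cB = genome.chrom_id(sv.chrom1), genome.chrom_id(sv.chrom2)
            b1, b2 = int(sv.pos1), int(sv.pos2)
            LA, LB = int(genome.lengths[cA]), int(genome.lengths[cB])
            if not (0 < b1 < LA and 0 < b2 < LB):
                raise ValueError(f"SV outside chromosome bounds: {sv}")
            sid = id(sv)
            chrom_segments[cA] = [(cA, 0, b1, +1), (cB, b2, LB, +1)]
            chrom_segments[cB] = [(cB, 0, b2, +1), (cA, b1, LA, +1)]
            junction_offsets[cA] = [(sid, b1)]
            junction_offsets[cB] = [(sid, b2)]

        # flatten to global arrays in variant-linear coordinates
        vs, rc, rs, re, st = [], [], [], [], []
        var_lengths = []
        self.junctions: dict[int, list[int]] = defaultdict(list)  # id(sv) -> var-linear
        var_off = 0
        for cid in range(len(genome.names)):
            seglist = chrom_segments[cid]
            pos = var_off
            for (rchrom, r0, r1, strand) in seglist:
                vs.append(pos); rc.append(rchrom); rs.append(r0); re.append(r1)
                st.append(strand)
                pos += r1 - r0
            for sid, off in junction_offsets.get(cid, []):
                self.junctions[sid].append(var_off + off)
            var_lengths.append(pos - var_off)
            var_off = pos
        self.seg_var_start = np.asarray(vs, dtype=np.int64)
        self.seg_ref_chrom = np.asarray(rc, dtype=np.int32)
        self.seg_ref_start = np.asarray(rs, dtype=np.int64)
        self.seg_ref_end = np.asarray(re, dtype=np.int64)
        self.seg_strand = np.asarray(st, dtype=np.int8)
        self.var_lengths = np.asarray(var_lengths, dtype=np.int64)
        self.var_offsets = np.concatenate([[0], np.cumsum(self.var_lengths)[:-1]])
        self.total_var_length = int(self.var_lengths.sum())

    def sv_junctions(self, sv: SVSpec) -> list[int]:
        """Variant-linear junction positions introduced by ``sv``."""
        return self.junctions.get(id(sv), [])

    def map_reads(self, s: np.ndarray, e: np.ndarray):
        """Map variant-linear read intervals [s, e) to reference coordinates.

        Returns arrays ``(chrom_id, pos, end, flip, clip5, clip3)``. Reads
        that cross a junction keep their longer piece as the primary
        alignment; the overhang becomes a soft clip on the junction side
        (this is what a short-read aligner reports for a junction read).
        ``flip`` marks reads landing on an inverted segment (their reference
        strand is the opposite of the molecule strand).
        """
        s = np.asarray(s, dtype=np.int64)
        e = np.asarray(e, dtype=np.int64)
        i0 = np.searchsorted(self.seg_var_start, s, side="right") - 1
        i1 = np.searchsorted(self.seg_var_start, e - 1, side="right") - 1

        n = len(s)
        chrom = np.empty(n, dtype=np.int32)
        pos = np.empty(n, dtype=np.int64)
        end = np.empty(n, dtype=np.int64)
        flip = np.zeros(n, dtype=bool)
        clip5 = np.zeros(n, dtype=np.int32)
        clip3 = np.zeros(n, dtype=np.int32)

        same = i0 == i1
        si = i0[same]
        off = s[same] - self.seg_var_start[si]
        ln = e[same] - s[same]
        fwd = self.seg_strand[si] > 0
        p = np.where(fwd,
                     self.seg_ref_start[si] + off,
                     self.seg_ref_end[si] - off - ln)
        chrom[same] = self.seg_ref_chrom[si]
        pos[same] = p
        end[same] = p + ln
        flip[same] = ~fwd

        for k in np.flatnonzero(~same):
            pieces = []
            a = s[k]
            for seg in range(i0[k], i1[k] + 1):
                seg_end_var = (self.seg_var_start[seg + 1]
                               if seg + 1 < len(self.seg_var_start)
                               else self.seg_var_start[seg]
                               + (self.seg_ref_end[seg] - self.seg_ref_start[seg]))
                b = min(e[k], seg_end_var)
                if b > a:
                    pieces.append((seg, a, b))
                a = b
            seg, ps, pe = max(pieces, key=lambda t: t[2] - t[1])
            off = ps - self.seg_var_start[seg]
            ln = pe - ps
            if self.seg_strand[seg] > 0:
                p = self.seg_ref_start[seg] + off
                c5, c3 = ps - s[k], e[k] - pe
            else:
                p = self.seg_ref_end[seg] - off - ln
                c5, c3 = e[k] - pe, ps - s[k]
                flip[k] = True
            chrom[k] = self.seg_ref_chrom[seg]
            pos[k] = p
            end[k] = p + ln
            clip5[k] = c5
            clip3[k] = c3
        return chrom, pos, end, flip, clip5, clip3


def simulate(config: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Generate a full linked-read dataset under ``config``.

    Deterministic for a fixed seed: identical config and seed reproduce the
    alignment table, molecule ledger and truth records exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genome = GenomeIndex.from_dict(config.chrom_lengths)
    rl = int(config.read_length)

    # allele groups: molecules with u in [edge_k, edge_{k+1}) carry every SV
    # whose vaf exceeds u, i.e. vaf >= edge_{k+1}
    vaf_edges = np.concatenate([[0.0], np.unique([sv.vaf for sv in config.svs]),
                                [1.0]]) if config.svs else np.array([0.0, 1.0])
    vaf_edges = np.unique(vaf_edges)
    maps = []
    active_lists = []
    for k in range(len(vaf_edges) - 1):
        hi = vaf_edges[k + 1]
        active = [sv for sv in config.svs if sv.vaf >= hi]
        active_lists.append(active)
        maps.append(SegmentMap(genome, active))

    # stationary molecule process: placement extends one pad (several mean
    # molecule lengths) upstream of every chromosome so interior coverage
    # has no start-of-chromosome taper; reads falling outside the
    # chromosome are discarded, as they would be outside a real excerpt
    pad = int(6 * config.mean_molecule_length)
    cov_mol = config.coverage_per_molecule
    density = config.depth / cov_mol / config.mean_molecule_length
    n_mol = int(round(density
                      * (genome.total_length + pad * len(genome.names))))
    if n_mol < 1:
        raise ValueError("configuration yields zero molecules")

    u = rng.random(n_mol)
    hap = np.where(u < 0.5, 1, 2).astype(np.int8)
    barcode_id = (rng.permutation(n_mol) // config.molecules_per_partition
                  ).astype(np.int32)
    mol_len = rng.exponential(config.mean_molecule_length, n_mol)
    group = np.searchsorted(vaf_edges, u, side="right") - 1

    mol_start = np.empty(n_mol, dtype=np.int64)
    mol_elen = np.empty(n_mol, dtype=np.int64)   # truncated length
    tables = []
    pair_base = 0
    for g in range(len(maps)):
        smap = maps[g]
        sel = np.flatnonzero(group == g)
        if sel.size == 0:
            continue
        # uniform placement over the pad-extended variant chromosomes
        ext_lengths = smap.var_lengths + pad
        ext_offsets = np.concatenate([[0], np.cumsum(ext_lengths)[:-1]])
        ext_total = int(ext_lengths.sum())
        epos = np.floor(rng.random(sel.size) * ext_total).astype(np.int64)
        vc = np.searchsorted(
            np.concatenate([ext_offsets, [ext_total]]), epos,
            side="right") - 1
        start = smap.var_offsets[vc] + (epos - ext_offsets[vc]) - pad
        chrom_start = smap.var_offsets[vc]
        chrom_end = smap.var_offsets[vc] + smap.var_lengths[vc]
        elen = np.minimum(np.ceil(mol_len[sel]).astype(np.int64),
                          chrom_end - start)
        mol_start[sel] = start
        mol_elen[sel] = elen

        k = rng.poisson(config.read_pair_rate * elen)
        rows = np.repeat(sel, k)
        starts_rep = np.repeat(start, k)
        elen_rep = np.repeat(elen, k)
        cstart_rep = np.repeat(chrom_start, k)
        cend_rep = np.repeat(chrom_end, k)
        p = starts_rep + np.floor(rng.random(len(rows)) * elen_rep).astype(np.int64)
        ins = np.maximum(
            np.round(rng.normal(config.insert_mean, config.insert_sd,
                                len(rows))).astype(np.int64),
            rl)
        # a pair survives only if both reads land inside the chromosome
        ok = (p >= cstart_rep) & (p + ins <= cend_rep)
        rows, p, ins = rows[ok], p[ok], ins[ok]

        c1, p1, e1, f1, a5, a3 = smap.map_reads(p, p + rl)
        c2, p2, e2, f2, b5, b3 = smap.map_reads(p + ins - rl, p + ins)
        strand1 = f1.astype(np.int8)              # read1 is + on the molecule
        strand2 = (~f2).astype(np.int8)           # read2 is - on the molecule

        same_chrom = c1 == c2
        lo = np.minimum(p1, p2)
        hi_ = np.maximum(e1, e2)
        tlen = np.where(same_chrom, hi_ - lo, 0)
        tlen1 = np.where(same_chrom, np.where(p1 <= p2, tlen, -tlen), 0)
        tlen2 = np.where(same_chrom, np.where(p2 < p1, tlen, -tlen), 0)

        npairs = len(rows)
        pid = pair_base + np.arange(npairs, dtype=np.int64)
        pair_base += npairs
        hap_rows = hap[rows] if config.phased else np.zeros(len(rows), np.int8)
        for (cc, pp, ee, ss, c5_, c3_, is1, mc, mp, ms, tl) in (
            (c1, p1, e1, strand1, a5, a3, True, c2, p2, strand2, tlen1),
            (c2, p2, e2, strand2, b5, b3, False, c1, p1, strand1, tlen2),
        ):
            tables.append(pd.DataFrame({
                "chrom_id": cc,
                "pos": pp,
                "end": ee,
                "mapq": np.full(npairs, 60, dtype=np.int16),
                "barcode_id": barcode_id[rows],
                "hap": hap_rows,
                "strand": ss,
                "is_read1": np.full(npairs, is1, dtype=bool),
                "mate_chrom_id": mc.astype(np.int32),
                "mate_pos": mp,
                "mate_strand": ms,
                "insert_size": tl,
                "clip5": c5_,
                "clip3": c3_,
                "pair_id": pid,
                "mol_id": rows.astype(np.int64),
            }))

    table = pd.concat(tables, ignore_index=True)
    order = np.lexsort((table["pos"].to_numpy(), table["chrom_id"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)

    molecules = pd.DataFrame({
        "mol_id": np.arange(n_mol, dtype=np.int64),
        "barcode_id": barcode_id,
        "hap": hap,
        "u": u,
        "group": group.astype(np.int32),
        "var_start": mol_start,
        "length": mol_elen,
    })

    truth: list[TruthRecord] = []
    for sv in config.svs:
        supp: list[np.ndarray] = []
        for g, smap in enumerate(maps):
            juncs = smap.sv_junctions(sv)
            if not juncs:
                continue
            sel = group == g
            for j in juncs:
                hit = sel & (mol_start < j) & (mol_start + mol_elen > j)
                supp.append(np.flatnonzero(hit))
        supp_ids = (np.unique(np.concatenate(supp)) if supp
                    else np.array([], dtype=np.int64))
        truth.append(TruthRecord(
            sv_type=sv.sv_type, chrom1=sv.chrom1, pos1=int(sv.pos1),
            chrom2=sv.chrom2, pos2=int(sv.pos2), vaf=sv.vaf,
            supporting_molecules=supp_ids))

    return SimResult(table=table, molecules=molecules, truth=truth,
                     genome=genome, config=config)


# ---------------------------------------------------------------------------
# Exome down-sampling
# ---------------------------------------------------------------------------

def downsample_to_targets(
    table: pd.DataFrame,
    targets: pd.DataFrame,
    genome: GenomeIndex,
    padding: int = 0,
    keep_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Restrict a WGS table to capture targets, at read-pair granularity.

    ``targets`` has columns (chrom, start, end). A read pair is retained iff
    either mate overlaps a padded target -- if one read is retained its mate
    is always retained too. ``keep_fraction`` optionally thins the retained
    pairs uniformly (capture-efficiency emulation).
    """
    if len(targets) == 0:
        return table.iloc[0:0].copy()
    starts_by_chrom: dict[int, np.ndarray] = {}
    ends_by_chrom: dict[int, np.ndarray] = {}
    for name, sub in targets.groupby("chrom"):
        cid = genome.chrom_id(str(name))
        s = np.maximum(sub["start"].to_numpy() - padding, 0)
        e = sub["end"].to_numpy() + padding
        order = np.argsort(s)
        s, e = s[order], e[order]
        # merge overlapping padded intervals
        ms, me = [s[0]], [e[0]]
        for a, b in zip(s[1:], e[1:]):
            if a <= me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a); me.append(b)
        starts_by_chrom[cid] = np.asarray(ms)
        ends_by_chrom[cid] = np.asarray(me)

    chrom = table["chrom_id"].to_numpy()
    pos = table["pos"].to_numpy()
    end = table["end"].to_numpy()
    on_target = np.zeros(len(table), dtype=bool)
    for cid, ms in starts_by_chrom.items():
        me = ends_by_chrom[cid]
        sel = chrom == cid
        i = np.searchsorted(me, pos[sel], side="right")
        ok = (i < len(ms)) & (ms[np.minimum(i, len(ms) - 1)] < end[sel])
        on_target[np.flatnonzero(sel)[ok]] = True

    pid = table["pair_id"].to_numpy()
    codes, uniques = pd.factorize(pid)
    pair_hit = np.zeros(len(uniques), dtype=bool)
    np.logical_or.at(pair_hit, codes, on_target)
    if keep_fraction < 1.0:
        if rng is None:
            rng = np.random.default_rng(0)
        pair_hit &= rng.random(len(uniques)) < keep_fraction
    return table[pair_hit[codes]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvaluationResult:
    n_truth: int
    n_calls: int
    n_tp: int
    recall: float | None
    precision: float | None
    f1: float | None


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "sv_type": [t.sv_type for t in truth],
        "chrom1": [t.chrom1 for t in truth],
        "pos1": [t.pos1 for t in truth],
        "chrom2": [t.chrom2 for t in truth],
        "pos2": [t.pos2 for t in truth],
    })


def evaluate_calls(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    min_reciprocal: float = 0.5,
    tra_tolerance: int = 1000,
) -> EvaluationResult:
    """Match calls to truth and compute recall / precision / F1.

    Interval SVs (DEL/DUP/INV) match when the types agree and the overlap
    strictly exceeds ``min_reciprocal`` of both spans (reciprocal-overlap
    rule); translocations match when both junction ends are within
    ``tra_tolerance`` bp. Matching is greedy one-to-one. With empty truth
    recall is undefined (None); with no calls precision is undefined.
    """
    used = np.zeros(len(truth), dtype=bool)
    n_tp = 0
    for _, call in calls.iterrows():
        for ti in range(len(truth)):
            if used[ti]:
                continue
            t = truth.iloc[ti]
            if call["sv_type"] != t["sv_type"] or call["chrom1"] != t["chrom1"]:
                continue
            if call["sv_type"] == "TRA":
                if (call["chrom2"] == t["chrom2"]
                        and abs(call["pos1"] - t["pos1"]) <= tra_tolerance
                        and abs(call["pos2"] - t["pos2"]) <= tra_tolerance):
                    used[ti] = True
                    n_tp += 1
                    break
            else:
                ov = (min(call["pos2"], t["pos2"])
                      - max(call["pos1"], t["pos1"]))
                len_c = call["pos2"] - call["pos1"]
                len_t = t["pos2"] - t["pos1"]
                if (ov > min_reciprocal * len_c and ov > min_reciprocal * len_t):
                    used[ti] = True
                    n_tp += 1
                    break
    recall = n_tp / len(truth) if len(truth) else None
    precision = n_tp / len(calls) if len(calls) else None
    f1 = None
    if recall is not None and precision is not None and (recall + precision) > 0:
        f1 = 2 * recall * precision / (recall + precision)
    elif recall is not None and precision is not None:
        f1 = 0.0
    return EvaluationResult(
        n_truth=len(truth), n_calls=len(calls), n_tp=n_tp,
        recall=recall, precision=precision, f1=f1)
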