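"""Fragment reconstruction: chaining same-barcode reads into molecules.

A *fragment* is the computational proxy of one high-molecular-weight DNA
molecule: the maximal run of same-barcode, same-chromosome read-pair events
whose consecutive start positions are closer than the gap threshold G. A
molecule spanning an SV breakpoint reconstructs into two fragments sharing a
barcode -- exactly the signal the endpoint-pair (type 1) evidence consumes.

Reads of a concordant pair are collapsed to one *event* spanning from the
leftmost read start to the rightmost read end before gap computation, so
fragment read counts and the rate ``lambda`` are in read-pair units (the
Poisson model is about read-pair generation along a molecule). Discordant or
unpaired reads stay as single-read events: a deletion-straddling pair must
not fuse its two breakpoints into one event.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

#: Maximum template length for a pair to be collapsed into one event (bp).
DEFAULT_MAX_COLLAPSE_INSERT = 5000

#: Minimum read-pair events for a fragment to be retained.
DEFAULT_MIN_READS = 2

EVENT_COLUMNS = ("chrom_id", "start", "end", "barcode_id", "hap", "pair_id")

FRAGMENT_COLUMNS = ("chrom_id", "L", "R", "barcode_id", "n_reads", "hap",
                    "hap1_votes", "hap2_votes")


def collapse_pairs(table: pd.DataFrame,
                   max_insert: int = DEFAULT_MAX_COLLAPSE_INSERT) -> pd.DataFrame:
    """Collapse concordant read pairs into single events.

    A pair is collapsed when both mates are present, map to the same
    chromosome on opposite strands, and the template length is positive and
    at most ``max_insert``. Everything else contributes one event per read.
    """
    pid = table["pair_id"].to_numpy()
    order = np.argsort(pid, kind="stable")
    pid_s = pid[order]
    second = np.zeros(len(pid_s), dtype=bool)
    second[1:] = pid_s[1:] == pid_s[:-1]

    i = order[np.flatnonzero(second) - 1]   # first mate of each pair
    j = order[second]                       # second mate

    chrom = table["chrom_id"].to_numpy()
    pos = table["pos"].to_numpy()
    end = table["end"].to_numpy()
    strand = table["strand"].to_numpy()
    ins = table["insert_size"].to_numpy()

    proper = (
        (chrom[i] == chrom[j])
        & (strand[i] != strand[j])
        & (np.abs(ins[i]) > 0)
        & (np.abs(ins[i]) <= max_insert)
    )
    ci, cj = i[proper], j[proper]

    ev_chrom = [chrom[ci]]
    ev_start = [np.minimum(pos[ci], pos[cj])]
    ev_end = [np.maximum(end[ci], end[cj])]
    ev_bc = [table["barcode_id"].to_numpy()[ci]]
    ev_hap = [table["hap"].to_numpy()[ci]]
    ev_pid = [pid[ci]]

    # everything not collapsed stays one event per read
    single = np.ones(len(table), dtype=bool)
    single[ci] = False
    single[cj] = False
    ev_chrom.append(chrom[single])
    ev_start.append(pos[single])
    ev_end.append(end[single])
    ev_bc.append(table["barcode_id"].to_numpy()[single])
    ev_hap.append(table["hap"].to_numpy()[single])
    ev_pid.append(pid[single])

    return pd.DataFrame({
        "chrom_id": np.concatenate(ev_chrom).astype(np.int32),
        "start": np.concatenate(ev_start).astype(np.int64),
        "end": np.concatenate(ev_end).astype(np.int64),
        "barcode_id": np.concatenate(ev_bc).astype(np.int32),
        "hap": np.concatenate(ev_hap).astype(np.int8),
        "pair_id": np.concatenate(ev_pid).astype(np.int64),
    })


def chain_events(events: pd.DataFrame, gap_threshold: int) -> pd.DataFrame:
    """Assign a fragment id to every event by left-to-right chaining.

    Events are sorted by (barcode, chromosome, start); a new fragment starts
    whenever the barcode or chromosome changes or the start-to-start gap is
    >= ``gap_threshold``. Returns the sorted events with a ``frag_id``
    column. Deterministic and invariant to the input record order.
    """
    bc = events["barcode_id"].to_numpy()
    chrom = events["chrom_id"].to_numpy()
    start = events["start"].to_numpy()
    end = events["end"].to_numpy()
    order = np.lexsort((end, start, chrom, bc))
    events = events.iloc[order].reset_index(drop=True)
    bc, chrom, start = bc[order], chrom[order], start[order]

    new = np.ones(len(events), dtype=bool)
    if len(events) > 1:
        new[1:] = (
            (bc[1:] != bc[:-1])
            | (chrom[1:] != chrom[:-1])
            | ((start[1:] - start[:-1]) >= gap_threshold)
        )
    events["frag_id"] = np.cumsum(new) - 1
    return events


def build_fragments(
    table: pd.DataFrame,
    gap_threshold: int,
    min_reads: int = DEFAULT_MIN_READS,
    max_insert: int = DEFAULT_MAX_COLLAPSE_INSERT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct fragments from an alignment table.

    Returns ``(fragments, events)``: the fragment table (columns
    :data:`FRAGMENT_COLUMNS`, one row per retained fragment, L/R 0-based
    half-open) and the chained event table whose ``frag_id`` column refers to
    fragment rows (-1 for events of discarded fragments). A fragment's
    haplotype is the majority vote of its events' haplotype tags (0 when
    tied or untagged).
    """
    events = chain_events(collapse_pairs(table, max_insert), gap_threshold)
    fid = events["frag_id"].to_numpy()
    if len(events) == 0:
        frags = pd.DataFrame({c: np.array([], dtype=np.int64)
                              for c in FRAGMENT_COLUMNS})
        return frags, events

    bnd = np.flatnonzero(np.r_[True, fid[1:] != fid[:-1]])
    start = events["start"].to_numpy()
    end = events["end"].to_numpy()
    L = start[bnd]
    R = np.maximum.reduceat(end, bnd)
    n = np.diff(np.r_[bnd, len(events)])
    hap = events["hap"].to_numpy()
    h1 = np.add.reduceat((hap == 1).astype(np.int64), bnd)
    h2 = np.add.reduceat((hap == 2).astype(np.int64), bnd)
    frag_hap = np.where(h1 > h2, 1, np.where(h2 > h1, 2, 0)).astype(np.int8)

    keep = n >= min_reads
    frags = pd.DataFrame({
        "chrom_id": events["chrom_id"].to_numpy()[bnd][keep],
        "L": L[keep],
        "R": R[keep],
        "barcode_id": events["barcode_id"].to_numpy()[bnd][keep],
        "n_reads": n[keep].astype(np.int64),
        "hap": frag_hap[keep],
        "hap1_votes": h1[keep],
        "hap2_votes": h2[keep],
    })

    # remap event frag ids onto retained fragment rows (-1 = discarded)
    new_id = np.full(len(bnd), -1, dtype=np.int64)
    new_id[keep] = np.arange(int(keep.sum()))
    events["frag_id"] = new_id[fid]
    return frags.reset_index(drop=True), events


def fragments_covering(fragments: pd.DataFrame, chrom_id: int,
                       positions) -> np.ndarray:
    """Number of fragments with ``L <= pos < R`` at each query position."""
    positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
    sel = fragments["chrom_id"].to_numpy() == chrom_id
    Ls = np.sort(fragments["L"].to_numpy()[sel])
    Rs = np.sort(fragments["R"].to_numpy()[sel])
    return (np.searchsorted(Ls, positions, side="right")
            - np.searchsorted(Rs, positions, side="right"))
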