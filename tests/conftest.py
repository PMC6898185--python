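"""Shared fixtures: small simulated datasets reused across test modules.

All fixtures are deterministic (fixed seeds) and generated in memory at
session scope so the expensive simulations run once.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from barcodesv.dataset import (estimate_dataset_stats, estimate_gap_threshold)
from barcodesv.fragments import build_fragments
from barcodesv.simulate import SimConfig, SVSpec, simulate


class Prepared:
    """A simulated dataset with the standard calling preamble applied."""

    def __init__(self, res):
        self.res = res
        self.table = res.table
        self.genome = res.genome
        self.truth = res.truth
        self.molecules = res.molecules
        self.G, self.gaps = estimate_gap_threshold(res.table)
        self.fragments, self.events = build_fragments(res.table, self.G)
        self.stats = estimate_dataset_stats(
            res.table, self.fragments, res.genome, self.G, self.gaps)


@pytest.fixture(scope="session")
def del_vaf1():
    """30x WGS, one homozygous 500 kb deletion."""
    cfg = SimConfig(chrom_lengths={"chr1": 3_000_000}, depth=30.0,
                    svs=[SVSpec("DEL", "chr1", 1_000_000, 1_500_000, vaf=1.0)],
                    seed=101)
    return Prepared(simulate(cfg))


@pytest.fixture(scope="session")
def inv_vaf1():
    """30x WGS, one homozygous 900 kb inversion."""
    cfg = SimConfig(chrom_lengths={"chr1": 3_000_000}, depth=30.0,
                    svs=[SVSpec("INV", "chr1", 900_000, 1_800_000, vaf=1.0)],
                    seed=102)
    return Prepared(simulate(cfg))


@pytest.fixture(scope="session")
def sv_free():
    """30x WGS with no SV (null fixture)."""
    cfg = SimConfig(chrom_lengths={"chr1": 2_000_000}, depth=30.0, seed=103)
    return Prepared(simulate(cfg))


def make_read_table(reads, genome, barcodes=None):
    """Build an alignment table from shorthand tuples.

    ``reads``: iterable of dicts with at least (chrom_id, pos, end,
    barcode_id); other columns default to sensible single-read values.
    """
    defaults = dict(mapq=60, hap=0, strand=0, is_read1=True,
                    mate_chrom_id=-1, mate_pos=-1, mate_strand=1,
                    insert_size=0, clip5=0, clip3=0, mol_id=-1)
    rows = []
    for i, r in enumerate(reads):
        row = dict(defaults)
        row.update(r)
        row.setdefault("pair_id", i)
        rows.append(row)
    columns = ["chrom_id", "pos", "end", "mapq", "barcode_id", "hap",
               "strand", "is_read1", "mate_chrom_id", "mate_pos",
               "mate_strand", "insert_size", "clip5", "clip3", "pair_id",
               "mol_id"]
    df = pd.DataFrame(rows, columns=columns)
    for c, t in (("chrom_id", np.int32), ("pos", np.int64), ("end", np.int64),
                 ("mapq", np.int16), ("barcode_id", np.int32),
                 ("hap", np.int8), ("strand", np.int8),
                 ("mate_chrom_id", np.int32), ("mate_pos", np.int64),
                 ("mate_strand", np.int8), ("insert_size", np.int64),
                 ("clip5", np.int32), ("clip3", np.int32),
                 ("pair_id", np.int64), ("mol_id", np.int64)):
        df[c] = df[c].astype(t)
    return df
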