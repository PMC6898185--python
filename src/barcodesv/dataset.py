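"""Ingestion of barcoded linked-read alignments and library-wide parameters.

Every statistical test in the caller depends on a handful of dataset-wide
quantities estimated here:

* ``G`` -- the gap-distance threshold used to chain same-barcode reads into
  fragments (99th percentile of the intra-fragment gap distribution, after a
  provisional 50 kb first pass);
* ``lambda_rate`` -- the rate of the Poisson read-pair process along a
  molecule (read pairs per bp);
* ``n_ifp`` -- the number of same-barcode fragment pairs genome-wide, the
  trial count of the barcode-coincidence binomial test;
* ``n_rp`` -- the total read-pair count, the multiplicity factor of the gap
  test;
* insert-size mean/sd for the small-deletion insert test.

Alignments are held in a flat :class:`pandas.DataFrame` (one row per read,
see :data:`TABLE_COLUMNS`) so that fragment reconstruction and scanning are
vectorised; :class:`BarcodedAlignment` is the record-level view used at I/O
boundaries. Coordinates are 0-based half-open everywhere internally.
"""
from __future__ import annotations

import dataclasses
import logging
import os
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: First-pass chaining distance (bp) used before G is calibrated.
PROVISIONAL_GAP = 50_000

#: Default mapping-quality filter for reads entering fragment reconstruction.
DEFAULT_MIN_MAPQ = 20

#: Haplotype code for reads without a haplotype tag.
HAP_UNASSIGNED = 0

#: Columns of the internal alignment table (one row per mapped read).
TABLE_COLUMNS = (
    "chrom_id", "pos", "end", "mapq", "barcode_id", "hap", "strand",
    "is_read1", "mate_chrom_id", "mate_pos", "mate_strand", "insert_size",
    "clip5", "clip3", "pair_id", "mol_id",
)


class InsufficientDataError(RuntimeError):
    """Raised when the dataset is too small to calibrate a parameter."""


@dataclasses.dataclass(eq=False)
class GenomeIndex:
    """Ordered chromosomes with lengths and head-to-tail linear offsets.

    Chromosomes are conceptually concatenated head-to-tail so intra- and
    inter-chromosomal breakpoint pairs live in the same linear coordinate
    system (and the same 2D endpoint plane).
    """

    names: tuple[str, ...]
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if np.any(self.lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)[:-1]])
        self.total_length = int(self.lengths.sum())
        self._name_to_id = {n: i for i, n in enumerate(self.names)}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeIndex":
        return cls(tuple(lengths), np.fromiter(lengths.values(), dtype=np.int64))

    @classmethod
    def from_alignment_file(cls, af) -> "GenomeIndex":
        """Build from a :class:`pysam.AlignmentFile` header."""
        return cls(tuple(af.references), np.asarray(af.lengths, dtype=np.int64))

    @classmethod
    def from_fai(cls, path: str | os.PathLike) -> "GenomeIndex":
        names, lengths = [], []
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                names.append(fields[0])
                lengths.append(int(fields[1]))
        return cls(tuple(names), np.asarray(lengths, dtype=np.int64))

    # -- lookups ----------------------------------------------------------
    def chrom_id(self, name: str) -> int:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise KeyError(f"unknown chromosome: {name!r}") from None

    def linearize(self, chrom: str | int, pos: int) -> int:
        cid = chrom if isinstance(chrom, (int, np.integer)) else self.chrom_id(chrom)
        if not 0 <= pos < self.lengths[cid]:
            raise ValueError(f"position {pos} outside chromosome {self.names[cid]}")
        return int(self.offsets[cid] + pos)

    def linearize_arrays(self, chrom_ids: np.ndarray, pos: np.ndarray) -> np.ndarray:
        return self.offsets[np.asarray(chrom_ids)] + np.asarray(pos)

    def delinearize(self, lin):
        """Inverse of :meth:`linearize`; accepts scalars or arrays."""
        lin = np.asarray(lin)
        edges = np.concatenate([self.offsets, [self.total_length]])
        cid = np.searchsorted(edges, lin, side="right") - 1
        if np.any((lin < 0) | (lin >= self.total_length)):
            raise ValueError("linear coordinate outside the genome")
        pos = lin - self.offsets[cid]
        if lin.ndim == 0:
            return int(cid), int(pos)
        return cid.astype(np.int64), pos

    def delinearize_endpoint(self, lin: int, kind: str) -> tuple[int, int]:
        """Delinearize a fragment endpoint.

        R endpoints are exclusive coordinates and may sit exactly at a
        chromosome's end (which coincides with the next chromosome's linear
        offset); ``kind="R"`` resolves that boundary to (previous
        chromosome, its length) instead of (next chromosome, 0).
        """
        if kind == "R":
            cid, pos = self.delinearize(lin - 1)
            return cid, pos + 1
        cid, pos = self.delinearize(lin)
        return cid, pos


@dataclasses.dataclass
class BarcodedAlignment:
    """One mapped read with its barcode and pairing metadata."""

    chrom: str
    pos: int                      # 0-based leftmost mapped position
    end: int                      # 0-based exclusive rightmost position
    mapq: int
    barcode: str
    haplotype: int = HAP_UNASSIGNED
    is_read1: bool = True
    mate_chrom: str | None = None
    mate_pos: int = -1
    mate_strand: str = "+"
    insert_size: int = 0          # signed template length
    clip5: int = 0
    clip3: int = 0
    strand: str = "+"
    qname: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.pos:
            raise ValueError("end must exceed pos")
        if self.mapq < 0 or self.clip5 < 0 or self.clip3 < 0:
            raise ValueError("mapq and clip lengths must be non-negative")


@dataclasses.dataclass
class DatasetStats:
    """Library-wide parameters consumed by the evidence tests."""

    gap_threshold: int            # G (bp)
    gap_ecdf: np.ndarray          # sampled intra-fragment gap distances (bp)
    lambda_rate: float            # read-pair events per bp on a molecule
    n_ifp: int                    # same-barcode fragment pairs, genome-wide
    n_rp: int                     # total read-pair events
    insert_mu: float              # genome-wide mean insert size (bp)
    insert_sigma: float           # genome-wide insert-size sd (bp)
    mean_depth: float             # genome-wide read-base depth
    hap_depths: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.gap_threshold <= 0:
            raise ValueError("G must be positive")
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be positive")
        if self.n_rp <= 0:
            raise ValueError("n_rp must be positive")
        if self.insert_sigma <= 0:
            raise ValueError("insert_sigma must be positive")


# ---------------------------------------------------------------------------
# Alignment-file ingestion
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | os.PathLike,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    barcode_tag: str = "BX",
    hap_tag: str = "HP",
) -> Iterator[BarcodedAlignment]:
    """Stream mapped, primary, non-duplicate reads carrying a barcode tag.

    Coordinates are converted to 0-based half-open. Records missing the
    barcode tag are skipped and counted; a warning is logged if they are the
    majority. BAM/CRAM input must be indexed (random access is needed
    downstream); plain SAM is streamed as-is.
    """
    import pysam

    af = pysam.AlignmentFile(str(path))
    try:
        if af.is_bam or af.is_cram:
            if not af.has_index():
                raise FileNotFoundError(
                    f"alignment file {path} has no index (.bai/.crai); "
                    "sort and index it first"
                )
        n_skipped = n_yielded = 0
        for rec in af:
            if (rec.is_unmapped or rec.is_secondary or rec.is_duplicate
                    or rec.is_supplementary):
                continue
            if rec.mapping_quality < min_mapq:
                continue
            try:
                barcode = rec.get_tag(barcode_tag)
            except KeyError:
                n_skipped += 1
                continue
            if not barcode:
                n_skipped += 1
                continue
            try:
                hap = int(rec.get_tag(hap_tag))
            except KeyError:
                hap = HAP_UNASSIGNED
            clip5 = clip3 = 0
            cig = rec.cigartuples
            if cig:
                if cig[0][0] in (4, 5):
                    clip5 = cig[0][1]
                if len(cig) > 1 and cig[-1][0] in (4, 5):
                    clip3 = cig[-1][1]
            mate_mapped = not rec.mate_is_unmapped and rec.next_reference_name is not None
            n_yielded += 1
            yield BarcodedAlignment(
                chrom=rec.reference_name,
                pos=rec.reference_start,
                end=rec.reference_end,
                mapq=rec.mapping_quality,
                barcode=str(barcode),
                haplotype=hap,
                is_read1=rec.is_read1,
                mate_chrom=rec.next_reference_name if mate_mapped else None,
                mate_pos=rec.next_reference_start if mate_mapped else -1,
                mate_strand="-" if (mate_mapped and rec.mate_is_reverse) else "+",
                insert_size=rec.template_length,
                clip5=clip5,
                clip3=clip3,
                strand="-" if rec.is_reverse else "+",
                qname=rec.query_name,
            )
        if n_skipped > n_yielded:
            logger.warning(
                "%d records lacked the %s barcode tag (vs %d used); is this "
                "really a linked-read alignment file?",
                n_skipped, barcode_tag, n_yielded,
            )
    finally:
        af.close()


def alignments_to_table(
    records: Iterable[BarcodedAlignment],
    genome: GenomeIndex,
) -> pd.DataFrame:
    """Materialise a stream of alignments into the internal table.

    Barcodes and read names are factorised to integer codes
    (``barcode_id``, ``pair_id``); the barcode string lookup is stored in
    ``df.attrs["barcodes"]``.
    """
    rows = {c: [] for c in TABLE_COLUMNS}
    barcodes: list[str] = []
    qnames: list[str] = []
    for rec in records:
        rows["chrom_id"].append(genome.chrom_id(rec.chrom))
        rows["pos"].append(rec.pos)
        rows["end"].append(rec.end)
        rows["mapq"].append(rec.mapq)
        barcodes.append(rec.barcode)
        rows["hap"].append(rec.haplotype)
        rows["strand"].append(0 if rec.strand == "+" else 1)
        rows["is_read1"].append(rec.is_read1)
        rows["mate_chrom_id"].append(
            genome.chrom_id(rec.mate_chrom) if rec.mate_chrom is not None else -1)
        rows["mate_pos"].append(rec.mate_pos)
        rows["mate_strand"].append(0 if rec.mate_strand == "+" else 1)
        rows["insert_size"].append(rec.insert_size)
        rows["clip5"].append(rec.clip5)
        rows["clip3"].append(rec.clip3)
        qnames.append(rec.qname)
        rows["mol_id"].append(-1)
    bc_codes, bc_uniques = pd.factorize(np.asarray(barcodes))
    pair_codes, _ = pd.factorize(np.asarray(qnames))
    rows["barcode_id"] = bc_codes
    rows["pair_id"] = pair_codes
    df = pd.DataFrame({
        "chrom_id": np.asarray(rows["chrom_id"], dtype=np.int32),
        "pos": np.asarray(rows["pos"], dtype=np.int64),
        "end": np.asarray(rows["end"], dtype=np.int64),
        "mapq": np.asarray(rows["mapq"], dtype=np.int16),
        "barcode_id": np.asarray(rows["barcode_id"], dtype=np.int32),
        "hap": np.asarray(rows["hap"], dtype=np.int8),
        "strand": np.asarray(rows["strand"], dtype=np.int8),
        "is_read1": np.asarray(rows["is_read1"], dtype=bool),
        "mate_chrom_id": np.asarray(rows["mate_chrom_id"], dtype=np.int32),
        "mate_pos": np.asarray(rows["mate_pos"], dtype=np.int64),
        "mate_strand": np.asarray(rows["mate_strand"], dtype=np.int8),
        "insert_size": np.asarray(rows["insert_size"], dtype=np.int64),
        "clip5": np.asarray(rows["clip5"], dtype=np.int32),
        "clip3": np.asarray(rows["clip3"], dtype=np.int32),
        "pair_id": np.asarray(rows["pair_id"], dtype=np.int64),
        "mol_id": np.asarray(rows["mol_id"], dtype=np.int64),
    })
    df.attrs["barcodes"] = np.asarray(bc_uniques)
    return df


def load_alignment_table(
    path: str | os.PathLike,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    barcode_tag: str = "BX",
    hap_tag: str = "HP",
) -> tuple[pd.DataFrame, GenomeIndex]:
    """Read an alignment file into (table, genome index)."""
    import pysam

    with pysam.AlignmentFile(str(path)) as af:
        genome = GenomeIndex.from_alignment_file(af)
    table = alignments_to_table(
        read_alignments(path, min_mapq=min_mapq, barcode_tag=barcode_tag,
                        hap_tag=hap_tag),
        genome,
    )
    return table, genome


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

def estimate_gap_threshold(
    table: pd.DataFrame,
    provisional_gap: int = PROVISIONAL_GAP,
    min_gaps: int = 1000,
    percentile: float = 99.0,
) -> tuple[int, np.ndarray]:
    """Calibrate the gap threshold G from the data.

    Pass 1 chains same-barcode reads with the provisional 50 kb rule; G is
    then the 99th percentile (lower interpolation, deterministic) of all gap
    distances observed inside those provisional fragments.

    Returns ``(G, gaps)`` where ``gaps`` is the sampled gap distribution.
    """
    from .fragments import collapse_pairs, chain_events

    events = chain_events(collapse_pairs(table), provisional_gap)
    fid = events["frag_id"].to_numpy()
    starts = events["start"].to_numpy()
    same = fid[1:] == fid[:-1]
    gaps = (starts[1:] - starts[:-1])[same]
    if gaps.size < min_gaps:
        raise InsufficientDataError(
            f"insufficient data to calibrate G: {gaps.size} intra-fragment "
            f"gaps observed, need >= {min_gaps}"
        )
    G = int(np.percentile(gaps, percentile, method="lower"))
    if G <= 0:
        raise InsufficientDataError("degenerate gap distribution (G <= 0)")
    return G, gaps


def estimate_dataset_stats(
    table: pd.DataFrame,
    fragments: pd.DataFrame,
    genome: GenomeIndex,
    gap_threshold: int,
    gap_ecdf: np.ndarray,
    trim: float = 0.001,
) -> DatasetStats:
    """Complete the dataset statistics given reconstructed fragments.

    ``lambda_rate`` inverts the mean intra-fragment gap distance of the
    provisional (50 kb) pass: under the Poisson read-generation model the
    gaps are Exp(lambda), so 1/mean(gap) is the maximum-likelihood rate and
    is unbiased to within the negligible 50 kb truncation. (The naive
    reads/span ratio over final fragments is inflated >10% by event widths
    and two-read fragments.) Insert moments are computed on proper forward-
    reverse pairs after trimming the extreme ``trim`` quantiles on both ends.
    """
    multi = fragments[fragments["n_reads"] >= 2]
    span = int((multi["R"] - multi["L"]).sum())
    if span <= 0:
        raise InsufficientDataError("zero total fragment span")
    mean_gap = float(np.asarray(gap_ecdf, dtype=np.float64).mean())
    if mean_gap <= 0:
        raise InsufficientDataError("degenerate gap distribution")
    lambda_rate = 1.0 / mean_gap

    counts = np.bincount(fragments["barcode_id"].to_numpy())
    n_ifp = int((counts.astype(np.int64) * (counts - 1) // 2).sum())

    n_rp = int(table["pair_id"].nunique())

    proper = (
        (table["insert_size"] > 0)
        & (table["mate_chrom_id"] == table["chrom_id"])
        & (table["strand"] == 0)
        & (table["mate_strand"] == 1)
    )
    ins = table.loc[proper, "insert_size"].to_numpy(dtype=np.float64)
    if ins.size < 10:
        raise InsufficientDataError("too few proper pairs for insert statistics")
    lo, hi = np.quantile(ins, [trim, 1.0 - trim])
    ins = ins[(ins >= lo) & (ins <= hi)]
    insert_mu = float(ins.mean())
    insert_sigma = float(ins.std(ddof=1))

    read_bases = (table["end"] - table["pos"]).to_numpy()
    mean_depth = float(read_bases.sum()) / genome.total_length
    hap = table["hap"].to_numpy()
    hap_depths = tuple(
        float(read_bases[hap == h].sum()) / genome.total_length for h in (1, 2)
    )

    return DatasetStats(
        gap_threshold=int(gap_threshold),
        gap_ecdf=np.asarray(gap_ecdf),
        lambda_rate=lambda_rate,
        n_ifp=n_ifp,
        n_rp=n_rp,
        insert_mu=insert_mu,
        insert_sigma=insert_sigma,
        mean_depth=mean_depth,
        hap_depths=hap_depths,
    )
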