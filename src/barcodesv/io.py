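"""Readers and writers for the standard interchange formats.

Final calls go out as BEDPE (one junction pair per line) and VCF 4.2 with
symbolic ALT alleles (<DEL>, <DUP>, <INV>; translocations as a pair of
breakend records). The simulator's alignment tables round-trip through
sorted, indexed BAM via pysam so the CLI consumes exactly what an aligner
would produce.
"""
from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import GenomeIndex
from .merge import SVCall
from .smalldel import SmallDeletionCall

BEDPE_COLUMNS = ("chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "sv_type", "n_support")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bedpe(calls: Sequence[SVCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for i, c in enumerate(calls):
            fh.write("\t".join(map(str, (
                c.chrom1, c.pos1, c.pos1 + 1, c.chrom2, c.pos2, c.pos2 + 1,
                f"{c.sv_type}_{i}", f"{c.combined_score:.2f}", c.sv_type,
                c.n_support))) + "\n")


def read_bedpe(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BEDPE of junction pairs into the evaluation frame
    (sv_type, chrom1, pos1, chrom2, pos2)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            sv_type = f[8] if len(f) > 8 else "DEL"
            rows.append((sv_type, f[0], int(f[1]), f[3], int(f[4])))
    return pd.DataFrame(rows, columns=["sv_type", "chrom1", "pos1",
                                       "chrom2", "pos2"])


def write_truth_bedpe(truth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tvaf"
                 "\tsv_type\n")
        for i, t in enumerate(truth):
            fh.write("\t".join(map(str, (
                t.chrom1, t.pos1, t.pos1 + 1, t.chrom2, t.pos2, t.pos2 + 1,
                f"truth_{i}", t.vaf, t.sv_type))) + "\n")


def write_fragments_bed(fragments: pd.DataFrame, genome: GenomeIndex,
                        path: str | os.PathLike) -> None:
    names = np.asarray(genome.names)
    with open(path, "w") as fh:
        for row in fragments.itertuples(index=False):
            fh.write(f"{names[row.chrom_id]}\t{row.L}\t{row.R}\t"
                     f"BC{row.barcode_id}\t{row.n_reads}\n")


def write_vcf(calls: Sequence[SVCall],
              small_calls: Sequence[SmallDeletionCall],
              genome: GenomeIndex, path: str | os.PathLike) -> None:
    """VCF 4.2 with symbolic SV records; positions are converted to
    1-based at this boundary."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=barcodesv\n")
        for name, length in zip(genome.names, genome.lengths):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for alt, desc in (("DEL", "Deletion"), ("DUP", "Duplication"),
                          ("INV", "Inversion")):
            fh.write(f"##ALT=<ID={alt},Description=\"{desc}\">\n")
        for info in (
            'SVTYPE,1,String,"SV type"',
            'END,1,Integer,"End position"',
            'CHR2,1,String,"Partner chromosome"',
            'POS2,1,Integer,"Partner position"',
            'PE,1,Integer,"Discordant read pairs"',
            'SR,1,Integer,"Split reads"',
            'BX_SUPPORT,1,Integer,"Supporting fragment pairs"',
            'SCORE1,1,Float,"Type 1 confidence score"',
            'SCORE2A,1,Float,"Type 2 score at breakpoint 1"',
            'SCORE2B,1,Float,"Type 2 score at breakpoint 2"',
            'COMBINED,1,Float,"Combined confidence score"',
            'VAF,1,Float,"Supporting-fragment fraction"',
            'HAP,1,Integer,"Haplotype of the event"',
            'EVIDENCE,1,String,"Evidence class"',
            'REFINED,0,Flag,"Breakpoints refined by split reads"',
        ):
            i, n, t, d = info.split(",", 3)
            fh.write(f"##INFO=<ID={i},Number={n},Type={t},Description={d}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")

        k = 0
        for c in calls:
            k += 1
            common = (f"PE={c.n_discordant};SR={c.n_split};"
                      f"BX_SUPPORT={c.n_support};SCORE1={c.score1:.2f};"
                      f"SCORE2A={c.score2a:.2f};SCORE2B={c.score2b:.2f};"
                      f"COMBINED={c.combined_score:.2f};EVIDENCE={c.evidence}")
            if c.vaf_estimate is not None:
                common += f";VAF={c.vaf_estimate:.3f}"
            if c.refined:
                common += ";REFINED"
            if c.sv_type == "TRA":
                fh.write(f"{c.chrom1}\t{c.pos1 + 1}\tsv{k}a\tN\t"
                         f"N[{c.chrom2}:{c.pos2 + 1}[\t.\tPASS\t"
                         f"SVTYPE=BND;CHR2={c.chrom2};POS2={c.pos2 + 1};"
                         f"{common}\n")
                fh.write(f"{c.chrom2}\t{c.pos2 + 1}\tsv{k}b\tN\t"
                         f"]{c.chrom1}:{c.pos1 + 1}]N\t.\tPASS\t"
                         f"SVTYPE=BND;CHR2={c.chrom1};POS2={c.pos1 + 1};"
                         f"{common}\n")
            else:
                fh.write(f"{c.chrom1}\t{c.pos1 + 1}\tsv{k}\tN\t<{c.sv_type}>"
                         f"\t.\tPASS\tSVTYPE={c.sv_type};END={c.pos2};"
                         f"{common}\n")
        for c in small_calls:
            k += 1
            fh.write(f"{c.chrom}\t{c.start + 1}\tsv{k}\tN\t<DEL>\t.\tPASS\t"
                     f"SVTYPE=DEL;END={c.end};EVIDENCE={c.evidence};"
                     f"HAP={c.haplotype}\n")


def small_calls_to_svcalls(small_calls: Sequence[SmallDeletionCall]
                           ) -> list[SVCall]:
    """View small-deletion calls as SVCall records (for BEDPE output and
    evaluation)."""
    out = []
    for c in small_calls:
        score = 300.0 if c.p_value <= 0 else -float(np.log10(max(c.p_value, 1e-300)))
        out.append(SVCall(
            sv_type="DEL", chrom1=c.chrom, pos1=c.start,
            chrom2=c.chrom, pos2=c.end, score1=score,
            evidence=c.evidence))
    return out


# ---------------------------------------------------------------------------
# BAM round-trip for the simulator
# ---------------------------------------------------------------------------

def write_alignment_file(table: pd.DataFrame, genome: GenomeIndex,
                         path: str | os.PathLike, phased: bool = True) -> None:
    """Write an alignment table as a coordinate-sorted, indexed BAM with BX
    (barcode) and HP (haplotype) tags.

    Reads are given a synthetic CIGAR of soft clips around a full match
    (the table carries no per-base alignment) and placeholder sequence.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(l)}
               for n, l in zip(genome.names, genome.lengths)],
    }
    tmp = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for row in table.itertuples(index=False):
            a = pysam.AlignedSegment()
            a.query_name = f"rp{row.pair_id:010d}"
            a.reference_id = int(row.chrom_id)
            a.reference_start = int(row.pos)
            a.mapping_quality = int(row.mapq)
            aligned = int(row.end - row.pos)
            cig = []
            if row.clip5 > 0:
                cig.append((4, int(row.clip5)))
            cig.append((0, aligned))
            if row.clip3 > 0:
                cig.append((4, int(row.clip3)))
            a.cigartuples = cig
            total = aligned + int(row.clip5) + int(row.clip3)
            a.query_sequence = "N" * total
            a.query_qualities = pysam.qualitystring_to_array("I" * total)
            a.is_paired = True
            a.is_read1 = bool(row.is_read1)
            a.is_read2 = not row.is_read1
            a.is_reverse = bool(row.strand == 1)
            a.mate_is_reverse = bool(row.mate_strand == 1)
            if row.mate_chrom_id >= 0:
                a.next_reference_id = int(row.mate_chrom_id)
                a.next_reference_start = int(row.mate_pos)
            else:
                a.mate_is_unmapped = True
            a.template_length = int(row.insert_size)
            a.set_tag("BX", f"BC{row.barcode_id:08d}-1")
            if phased and row.hap > 0:
                a.set_tag("HP", int(row.hap))
            a.set_tag("MI", int(row.mol_id))
            bam.write(a)
    pysam.sort("-o", str(path), tmp)
    os.unlink(tmp)
    pysam.index(str(path))
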