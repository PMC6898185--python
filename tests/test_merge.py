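"""Evidence combination, breakpoint refinement and VAF estimation."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from barcodesv.dataset import DatasetStats, GenomeIndex
from barcodesv.merge import (SVCall, estimate_vaf, merge_evidence,
                             refine_breakpoints)
from barcodesv.type1 import TypeOneCall, call_type1
from barcodesv.type2 import (SimilarityModel, apply_similarity,
                             call_type2_breakpoints, scan_twin_windows)

from conftest import make_read_table

GENOME = GenomeIndex(("chr1",), np.array([10_000_000]))


def _stats(**kw):
    base = dict(gap_threshold=4600, gap_ecdf=np.array([1000.0]),
                lambda_rate=1e-3, n_ifp=10_000, n_rp=100_000,
                insert_mu=400.0, insert_sigma=50.0, mean_depth=30.0)
    base.update(kw)
    return DatasetStats(**base)


def _t1call(pos1, pos2, score1=6.0, sv_type="DEL"):
    return TypeOneCall(
        sv_type=sv_type, chrom1="chr1", pos1=pos1, chrom2="chr1", pos2=pos2,
        lin_b1=pos1, lin_b2=pos2, plane="RL", n_support=10,
        p1=1e-9, p_adjusted1=10.0 ** -score1, p2=None, p_adjusted2=None,
        score1=score1, frag1_rows=np.arange(10), frag2_rows=np.arange(10, 20),
        passed=True)


class TestMergeEvidence:
    def test_unmatched_breakpoints_contribute_zero(self):
        empty = pd.DataFrame({"chrom_id": [], "pos": [], "score2": []})
        out = merge_evidence([_t1call(10_000, 500_000)], empty, GENOME,
                             match_dist=5000)
        assert out[0].combined_score == out[0].score1

    def test_combined_score_is_additive(self):
        cands = pd.DataFrame({
            "chrom_id": np.array([0, 0]),
            "pos": np.array([10_100, 499_800]),
            "score2": np.array([3.0, 2.0]),
        })
        out = merge_evidence([_t1call(10_000, 500_000, score1=6.0)], cands,
                             GENOME, match_dist=5000)
        c = out[0]
        assert (c.score2a, c.score2b) == (3.0, 2.0)
        assert c.combined_score == pytest.approx(11.0)
        assert c.combined_score >= c.score1

    def test_match_distance_is_enforced(self):
        cands = pd.DataFrame({"chrom_id": [0], "pos": [40_000],
                              "score2": [5.0]})
        out = merge_evidence([_t1call(10_000, 500_000)], cands, GENOME,
                             match_dist=5000)
        assert out[0].score2a == 0.0


class TestRefinement:
    def _discordant_table(self, b1=100_000, b2=300_000, n=6):
        """Discordant forward-reverse pairs around a deletion, no clips."""
        reads = []
        rng = np.random.default_rng(13)
        for i in range(n):
            p = b1 - 400 + int(rng.integers(0, 250))
            mp = b2 + int(rng.integers(0, 300))
            span = mp + 100 - p
            reads.append(dict(chrom_id=0, pos=p, end=p + 100, barcode_id=i,
                              pair_id=2 * i, strand=0, mate_chrom_id=0,
                              mate_pos=mp, mate_strand=1, insert_size=span))
            reads.append(dict(chrom_id=0, pos=mp, end=mp + 100, barcode_id=i,
                              pair_id=2 * i, strand=1, mate_chrom_id=0,
                              mate_pos=p, mate_strand=0, insert_size=-span))
        return make_read_table(reads, GENOME)

    def test_no_short_read_support_leaves_call_unchanged(self):
        table = self._discordant_table()
        call = SVCall(sv_type="DEL", chrom1="chr1", pos1=5_000_000,
                      chrom2="chr1", pos2=6_000_000, score1=8.0, n_support=9)
        out = refine_breakpoints(call, table, _stats(), GENOME)
        assert (out.pos1, out.pos2) == (5_000_000, 6_000_000)
        assert not out.refined and out.n_discordant == 0

    def test_discordant_only_recenters_to_innermost(self):
        table = self._discordant_table()
        call = SVCall(sv_type="DEL", chrom1="chr1", pos1=99_000,
                      chrom2="chr1", pos2=301_000, score1=8.0, n_support=9)
        out = refine_breakpoints(call, table, _stats(), GENOME)
        assert not out.refined            # no split reads
        assert out.n_discordant == 6
        ends = table.loc[table["strand"].to_numpy() == 0, "end"]
        mps = table.loc[table["strand"].to_numpy() == 0, "mate_pos"]
        assert out.pos1 == ends.max()     # innermost coordinates
        assert out.pos2 == mps.min()
        # few-hundred-bp resolution around the true junctions
        assert abs(out.pos1 - 100_000) < 500
        assert abs(out.pos2 - 300_000) < 500

    def test_split_reads_give_exact_breakpoints(self, del_vaf1):
        truth = del_vaf1.truth[0]
        call = SVCall(sv_type="DEL", chrom1="chr1", pos1=truth.pos1 - 7,
                      chrom2="chr1", pos2=truth.pos2 + 13, score1=20.0,
                      n_support=100)
        out = refine_breakpoints(call, del_vaf1.table, del_vaf1.stats,
                                 del_vaf1.genome)
        assert out.refined
        assert (out.pos1, out.pos2) == (truth.pos1, truth.pos2)
        assert out.n_split >= 4 and out.n_discordant >= 4

    def test_idempotent(self, del_vaf1):
        truth = del_vaf1.truth[0]
        call = SVCall(sv_type="DEL", chrom1="chr1", pos1=truth.pos1 - 7,
                      chrom2="chr1", pos2=truth.pos2 + 13, score1=20.0,
                      n_support=100)
        once = refine_breakpoints(call, del_vaf1.table, del_vaf1.stats,
                                  del_vaf1.genome)
        twice = refine_breakpoints(once, del_vaf1.table, del_vaf1.stats,
                                   del_vaf1.genome)
        assert (once.pos1, once.pos2) == (twice.pos1, twice.pos2)
        assert once.refined == twice.refined

    def test_never_moves_beyond_search_radius(self, del_vaf1):
        truth = del_vaf1.truth[0]
        radius = 10_000
        call = SVCall(sv_type="DEL", chrom1="chr1", pos1=truth.pos1 - 5000,
                      chrom2="chr1", pos2=truth.pos2 + 5000, score1=20.0,
                      n_support=100)
        out = refine_breakpoints(call, del_vaf1.table, del_vaf1.stats,
                                 del_vaf1.genome, search_radius=radius)
        assert abs(out.pos1 - call.pos1) <= radius
        assert abs(out.pos2 - call.pos2) <= radius


class TestVAF:
    def test_ratio_definition(self):
        # 10 supporting pairs vs 90 spanning non-supporting fragments/side
        frags = pd.DataFrame({
            "chrom_id": np.zeros(200, dtype=np.int32),
            "L": np.concatenate([np.full(90, 90_000), np.full(90, 490_000),
                                 np.full(20, 1_000_000)]),
            "R": np.concatenate([np.full(90, 110_000), np.full(90, 510_000),
                                 np.full(20, 1_000_500)]),
            "barcode_id": np.arange(200, dtype=np.int32),
            "n_reads": np.full(200, 5),
        })
        call = SVCall(sv_type="DEL", chrom1="chr1", pos1=100_000,
                      chrom2="chr1", pos2=500_000, score1=9.0, n_support=10,
                      frag1_rows=np.arange(180, 190),
                      frag2_rows=np.arange(190, 200))
        out = estimate_vaf(call, frags, GENOME)
        assert out.vaf_estimate == pytest.approx(0.10)

    def test_zero_denominator_leaves_vaf_absent(self):
        frags = pd.DataFrame({"chrom_id": np.array([], dtype=np.int32),
                              "L": np.array([], dtype=np.int64),
                              "R": np.array([], dtype=np.int64),
                              "barcode_id": np.array([], dtype=np.int32),
                              "n_reads": np.array([], dtype=np.int64)})
        call = SVCall(sv_type="DEL", chrom1="chr1", pos1=100, chrom2="chr1",
                      pos2=200, score1=1.0, n_support=0)
        assert estimate_vaf(call, frags, GENOME).vaf_estimate is None

    def test_homozygous_simulation_approaches_one(self, del_vaf1):
        calls = call_type1(del_vaf1.fragments, del_vaf1.genome,
                           del_vaf1.stats)
        c = [c for c in calls if c.sv_type == "DEL"][0]
        sv = SVCall(sv_type=c.sv_type, chrom1=c.chrom1, pos1=c.pos1,
                    chrom2=c.chrom2, pos2=c.pos2, score1=c.score1,
                    n_support=c.n_support, frag1_rows=c.frag1_rows,
                    frag2_rows=c.frag2_rows)
        # pipeline order: refine to the exact junction, then estimate
        sv = refine_breakpoints(sv, del_vaf1.table, del_vaf1.stats,
                                del_vaf1.genome)
        out = estimate_vaf(sv, del_vaf1.fragments, del_vaf1.genome)
        assert out.vaf_estimate >= 0.9


class TestFullMerge:
    def test_deletion_matched_at_both_ends(self, del_vaf1):
        t1 = call_type1(del_vaf1.fragments, del_vaf1.genome, del_vaf1.stats)
        scores = apply_similarity(
            scan_twin_windows(del_vaf1.table, del_vaf1.genome,
                              window=del_vaf1.G),
            SimilarityModel(mode="simple"))
        t2 = call_type2_breakpoints(scores)
        merged = merge_evidence(t1, t2, del_vaf1.genome,
                                match_dist=del_vaf1.G)
        c = [c for c in merged if c.sv_type == "DEL"][0]
        assert c.score2a > 0 and c.score2b > 0
        assert c.combined_score == pytest.approx(
            c.score1 + c.score2a + c.score2b)
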