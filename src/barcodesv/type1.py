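"""Type 1 evidence: enriched same-barcode fragment-endpoint pairs.

A molecule spanning an SV junction reconstructs into two same-barcode
fragments whose facing endpoints co-locate near the two breakpoints. Every
same-barcode fragment pair contributes one point per endpoint plane --
RL = (R(F1), L(F2)), LR, RR, LL -- in head-to-tail linear genome
coordinates. Points from independent molecules that merely share a barcode
are uniform over the L x L plane, while true supporting pairs pile up
inside a G x G square whose corner is the breakpoint pair, so a cluster of
n points is scored by two tests:

* barcode coincidence -- the binomial tail probability of seeing >= n
  independent same-barcode pairs inside one G x G square, Bonferroni-
  adjusted over the ~ (L/G)^2 testable squares;
* gap lengths (colinear RL geometry only) -- under the rival hypothesis
  that the two fragments are one molecule whose middle simply went
  unsequenced, the mean of n reference gaps is Gamma(n, n*lambda); a mean
  gap too long for the Poisson read process rejects it.

A call survives when both applicable adjusted p-values fall below the
threshold; its confidence score is -log10 of the larger one.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .dataset import DatasetStats, GenomeIndex

PLANES = ("RL", "LR", "RR", "LL")

#: Floor for p-values before -log10 (keeps scores finite).
P_FLOOR = 1e-300


@dataclasses.dataclass(frozen=True)
class TypeOneParams:
    min_support: int = 5            # minimum points (and barcodes) per cluster
    p_threshold: float = 1e-5
    adjust_mode: str = "bonferroni"  # or "printed"
    square_step: int = 100           # moving-square stride (bp)
    min_separation_factor: float = 2.0  # suppress |x - y| < factor * G
    molecule_gap_factor: float = 3.0  # suppress facing gaps < factor * G
    min_sv_size: int = 0             # optional extra same-chromosome gate
    boundary_margin: int | None = None  # endpoint mask near chrom edges; None -> G


@dataclasses.dataclass
class TypeOneCall:
    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    lin_b1: int
    lin_b2: int
    plane: str
    n_support: int
    p1: float
    p_adjusted1: float
    p2: float | None
    p_adjusted2: float | None
    score1: float
    frag1_rows: np.ndarray
    frag2_rows: np.ndarray
    passed: bool


def enumerate_fragment_pairs(fragments: pd.DataFrame,
                             genome: GenomeIndex) -> pd.DataFrame:
    """All unordered same-barcode fragment pairs, canonically ordered.

    Output columns: fragment row indices ``i1``/``i2`` (the fragment with
    the smaller linear midpoint is F1), linear endpoints ``l1 r1 l2 r2``,
    ``barcode_id`` and both chromosome ids. A barcode with k fragments
    yields C(k, 2) rows.
    """
    bc = fragments["barcode_id"].to_numpy()
    order = np.argsort(bc, kind="stable")
    bcs = bc[order]
    bnd = np.flatnonzero(np.r_[True, bcs[1:] != bcs[:-1]])
    sizes = np.diff(np.r_[bnd, len(bcs)])

    i1_parts, i2_parts = [], []
    triu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for a, k in zip(bnd, sizes):
        if k < 2:
            continue
        if k not in triu_cache:
            triu_cache[k] = np.triu_indices(k, 1)
        iu, ju = triu_cache[k]
        idx = order[a:a + k]
        i1_parts.append(idx[iu])
        i2_parts.append(idx[ju])
    if not i1_parts:
        return pd.DataFrame({c: np.array([], dtype=np.int64)
                             for c in ("i1", "i2", "l1", "r1", "l2", "r2",
                                       "barcode_id", "chrom1", "chrom2")})
    i1 = np.concatenate(i1_parts)
    i2 = np.concatenate(i2_parts)

    off = genome.offsets[fragments["chrom_id"].to_numpy()]
    linL = off + fragments["L"].to_numpy()
    linR = off + fragments["R"].to_numpy()
    mid = (linL + linR) // 2
    swap = mid[i1] > mid[i2]
    i1, i2 = np.where(swap, i2, i1), np.where(swap, i1, i2)

    chrom = fragments["chrom_id"].to_numpy()
    return pd.DataFrame({
        "i1": i1, "i2": i2,
        "l1": linL[i1], "r1": linR[i1],
        "l2": linL[i2], "r2": linR[i2],
        "barcode_id": bc[i1],
        "chrom1": chrom[i1], "chrom2": chrom[i2],
    })


def plane_coords(pairs: pd.DataFrame, plane: str) -> tuple[np.ndarray, np.ndarray]:
    if plane == "RL":
        return pairs["r1"].to_numpy(), pairs["l2"].to_numpy()
    if plane == "LR":
        return pairs["l1"].to_numpy(), pairs["r2"].to_numpy()
    if plane == "RR":
        return pairs["r1"].to_numpy(), pairs["r2"].to_numpy()
    if plane == "LL":
        return pairs["l1"].to_numpy(), pairs["l2"].to_numpy()
    raise ValueError(f"unknown plane {plane!r}")


def cluster_points(x: np.ndarray, y: np.ndarray, G: int,
                   min_support: int = 5) -> list[np.ndarray]:
    """Connected components under the Chebyshev-distance-< G relation.

    Uses a 2D k-d tree for the neighbour queries (no all-pairs scan);
    returns index arrays of the components with >= ``min_support`` points.
    """
    n = len(x)
    if n == 0:
        return []
    pts = np.column_stack([x, y]).astype(np.float64)
    tree = cKDTree(pts)
    # integer coordinates: radius G - 0.5 realises the strict "< G" rule
    edges = tree.query_pairs(r=G - 0.5, p=np.inf, output_type="ndarray")
    if len(edges):
        g = sparse.coo_matrix(
            (np.ones(len(edges), dtype=np.int8), (edges[:, 0], edges[:, 1])),
            shape=(n, n))
        _, labels = connected_components(g, directed=False)
    else:
        labels = np.arange(n)
    counts = np.bincount(labels)
    keep = np.flatnonzero(counts >= min_support)
    order = np.argsort(labels, kind="stable")
    bnd = np.searchsorted(labels[order], keep)
    return [order[b:b + counts[c]] for b, c in zip(bnd, keep)]


def best_square(x: np.ndarray, y: np.ndarray, G: int,
                step: int = 100) -> np.ndarray:
    """Boolean mask of the points inside the best G x G moving square.

    When the cluster bounding box already fits in G x G all points are
    retained. Otherwise a G x G square is slid on a ``step`` grid over the
    bounding box to maximise the number of contained points; ties prefer
    the smallest y0 - x0 (tightest breakpoint span).
    """
    if (x.max() - x.min() <= G) and (y.max() - y.min() <= G):
        return np.ones(len(x), dtype=bool)
    x0s = np.arange(x.min(), max(x.max() - G, x.min()) + step, step)
    y0s = np.arange(y.min(), max(y.max() - G, y.min()) + step, step)
    # keep the grid tractable for pathological clusters
    while len(x0s) * len(y0s) > 250_000:
        step *= 2
        x0s = x0s[::2]
        y0s = y0s[::2]
    ys = np.sort(y)
    best = (-1, np.inf, None)
    for x0 in x0s:
        in_x = (x >= x0) & (x <= x0 + G)
        if in_x.sum() == 0:
            continue
        ysub = np.sort(y[in_x])
        counts = (np.searchsorted(ysub, y0s + G, side="right")
                  - np.searchsorted(ysub, y0s, side="left"))
        j = int(np.argmax(counts))
        cand = (counts[j], y0s[j] - x0, (x0, y0s[j]))
        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    x0, y0 = best[2]
    return (x >= x0) & (x <= x0 + G) & (y >= y0) & (y <= y0 + G)


def predict_breakpoints(x: np.ndarray, y: np.ndarray, plane: str) -> tuple[int, int]:
    """Breakpoint pair from the square's corner, per endpoint geometry.

    For RL (deletion) geometry the supporting constraints are
    b1 - G <= R(F1) <= b1 and b2 <= L(F2) <= b2 + G, so the estimate is the
    right-bottom vertex (max x, min y); the other planes use the vertex
    that makes the analogous one-sided G-band hold for their endpoint
    types.
    """
    if plane == "RL":
        return int(x.max()), int(y.min())
    if plane == "LR":
        return int(x.min()), int(y.max())
    if plane == "RR":
        return int(x.max()), int(y.max())
    if plane == "LL":
        return int(x.min()), int(y.min())
    raise ValueError(f"unknown plane {plane!r}")


def test_barcode_coincidence(n: int, n_ifp: int, G: int, L: int,
                             adjust_mode: str = "bonferroni"
                             ) -> tuple[float, float]:
    """Binomial tail test of n same-barcode pairs landing in one G x G square.

    ``p1`` is the probability of >= n successes in ``n_ifp`` trials with
    success probability (G/L)^2. The adjustment multiplies by the number of
    distinct testable squares (L/G)^2, capped at 1 ("bonferroni"); the
    "printed" mode multiplies by (G/L)^2 instead.
    """
    if n > n_ifp:
        raise ValueError("n cannot exceed the number of independent pairs")
    if not 0 < G < L:
        raise ValueError("need 0 < G < L")
    p_hit = (G / L) ** 2
    p1 = float(stats.binom.sf(n - 1, n_ifp, p_hit)) if n > 0 else 1.0
    if adjust_mode == "bonferroni":
        p_adj = min(1.0, p1 / p_hit)
    elif adjust_mode == "printed":
        p_adj = p1 * p_hit
    else:
        raise ValueError(f"unknown adjust_mode {adjust_mode!r}")
    return p1, p_adj


def test_gap_lengths(gaps: np.ndarray, lambda_rate: float,
                     n_rp: int) -> tuple[float, float]:
    """Gamma tail test of the mean reference gap between paired endpoints.

    Under the one-molecule null each gap is Exp(lambda), so the mean of n
    gaps is Gamma(n, n*lambda); ``p2`` is its survival function at the
    observed mean, adjusted by the N_rp / n multiplicity factor.
    """
    gaps = np.asarray(gaps, dtype=np.float64)
    n = len(gaps)
    if n == 0:
        raise ValueError("no positive gaps to test")
    g_bar = gaps.mean()
    p2 = float(stats.gamma.sf(g_bar, a=n, scale=1.0 / (n * lambda_rate)))
    p_adj = min(1.0, p2 * n_rp / n)
    return p2, p_adj


def score_from_pvalues(p_adjusted1: float,
                       p_adjusted2: float | None) -> float:
    """Confidence score 1 = -log10 of the largest applicable adjusted p."""
    worst = p_adjusted1 if p_adjusted2 is None else max(p_adjusted1, p_adjusted2)
    return -math.log10(max(worst, P_FLOOR))


def classify_sv_type(plane: str, chrom1: int, chrom2: int) -> str:
    if chrom1 != chrom2:
        return "TRA"
    return {"RL": "DEL", "LR": "DUP", "RR": "INV", "LL": "INV"}[plane]


def call_type1(fragments: pd.DataFrame, genome: GenomeIndex,
               dataset_stats: DatasetStats,
               params: TypeOneParams = TypeOneParams()) -> list[TypeOneCall]:
    """Scan all four endpoint planes and emit the surviving calls.

    Four guards tame artifacts that the uniform-plane null does not model:

    * same-chromosome pairs whose facing reference gap (L2 - R1 with F1
      leftmost) lies in [0, molecule_gap_factor * G) are suppressed in
      every plane: with G at the 99th gap percentile about half the
      molecules chance-split somewhere, and their two halves -- facing gap
      barely above G -- would otherwise seed clusters in all four planes
      (P(chance gap > 3G) ~ 1e-6, while true rearranged pairs face a gap
      at the SV scale);
    * same-chromosome points with |x - y| < min_separation_factor * G are
      suppressed (near-diagonal degeneracies);
    * endpoints within ``boundary_margin`` of a chromosome edge are masked
      (molecules cut by the reference boundary pile their endpoints there);
    * a cluster must draw its support from >= ``min_support`` distinct
      barcode partitions (points sharing one fragment, hence one barcode,
      are not independent evidence).

    RR and LL inversion calls with mutually consistent breakpoints are
    merged, and calls sharing a junction with a stronger call are removed.
    """
    G = dataset_stats.gap_threshold
    L = genome.total_length
    margin = params.boundary_margin if params.boundary_margin is not None else G
    pairs = enumerate_fragment_pairs(fragments, genome)
    if len(pairs) == 0:
        return []

    chrom_len = genome.lengths[fragments["chrom_id"].to_numpy()]
    fl = fragments["L"].to_numpy()
    fr = fragments["R"].to_numpy()
    ok_L = (fl >= margin) & (fl <= chrom_len - margin)
    ok_R = (fr >= margin) & (fr <= chrom_len - margin)
    i1 = pairs["i1"].to_numpy()
    i2 = pairs["i2"].to_numpy()
    endpoint_ok = {
        "RL": ok_R[i1] & ok_L[i2], "LR": ok_L[i1] & ok_R[i2],
        "RR": ok_R[i1] & ok_R[i2], "LL": ok_L[i1] & ok_L[i2],
    }
    pair_bc = pairs["barcode_id"].to_numpy()

    # chance-split suppression: facing gap of the pair in reference order
    same_chrom_pair = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    l1a, r1a = pairs["l1"].to_numpy(), pairs["r1"].to_numpy()
    l2a, r2a = pairs["l2"].to_numpy(), pairs["r2"].to_numpy()
    facing_gap = np.where(l1a <= l2a, l2a - r1a, l1a - r2a)
    split_like = (same_chrom_pair & (facing_gap >= 0)
                  & (facing_gap < params.molecule_gap_factor * G))

    calls: list[TypeOneCall] = []
    for plane in PLANES:
        x_all, y_all = plane_coords(pairs, plane)
        same_chrom = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
        sep = np.abs(x_all - y_all)
        keep = (~same_chrom | (sep >= params.min_separation_factor * G))
        keep &= ~split_like
        keep &= endpoint_ok[plane]
        if params.min_sv_size:
            keep &= ~same_chrom | (sep >= params.min_sv_size)
        sel = np.flatnonzero(keep)
        if sel.size == 0:
            continue
        x_s, y_s = x_all[sel], y_all[sel]
        for comp in cluster_points(x_s, y_s, G, params.min_support):
            mask = best_square(x_s[comp], y_s[comp], G, params.square_step)
            idx = sel[comp[mask]]
            n = len(idx)
            if n < params.min_support:
                continue
            if len(np.unique(pair_bc[idx])) < params.min_support:
                continue
            x, y = x_all[idx], y_all[idx]
            b1, b2 = predict_breakpoints(x, y, plane)
            c1, pos1 = genome.delinearize_endpoint(b1, plane[0])
            c2, pos2 = genome.delinearize_endpoint(b2, plane[1])

            p1, p_adj1 = test_barcode_coincidence(
                n, dataset_stats.n_ifp, G, L, params.adjust_mode)
            p2 = p_adj2 = None
            if plane == "RL" and c1 == c2:
                gaps = (y - x).astype(np.float64)
                gaps = gaps[gaps > 0]
                if len(gaps):
                    p2, p_adj2 = test_gap_lengths(
                        gaps, dataset_stats.lambda_rate, dataset_stats.n_rp)
            passed = p_adj1 < params.p_threshold and (
                p_adj2 is None or p_adj2 < params.p_threshold)
            if not passed:
                continue
            calls.append(TypeOneCall(
                sv_type=classify_sv_type(plane, c1, c2),
                chrom1=genome.names[c1], pos1=int(pos1),
                chrom2=genome.names[c2], pos2=int(pos2),
                lin_b1=b1, lin_b2=b2, plane=plane, n_support=n,
                p1=p1, p_adjusted1=p_adj1, p2=p2, p_adjusted2=p_adj2,
                score1=score_from_pvalues(p_adj1, p_adj2),
                frag1_rows=i1[idx],
                frag2_rows=i2[idx],
                passed=True))
    return deduplicate_calls(merge_inversion_calls(calls, G), G)


def count_supporting_pairs(fragments: pd.DataFrame, genome: GenomeIndex,
                           G: int, chrom1: str, b1: int,
                           chrom2: str, b2: int) -> int:
    """Same-barcode fragment pairs whose RL-plane point falls in the G x G
    square anchored at a known breakpoint pair (deletion geometry:
    b1 - G <= R(F1) <= b1 and b2 <= L(F2) <= b2 + G)."""
    lin1 = genome.linearize(chrom1, b1)
    lin2 = genome.linearize(chrom2, b2)
    off = genome.offsets[fragments["chrom_id"].to_numpy()]
    linL = off + fragments["L"].to_numpy()
    linR = off + fragments["R"].to_numpy()
    bc = fragments["barcode_id"].to_numpy()
    left = np.flatnonzero((linR >= lin1 - G) & (linR <= lin1))
    right = np.flatnonzero((linL >= lin2) & (linL <= lin2 + G))
    left_bcs = pd.Series(bc[left]).value_counts()
    right_bcs = pd.Series(bc[right]).value_counts()
    common = left_bcs.index.intersection(right_bcs.index)
    return int((left_bcs[common] * right_bcs[common]).sum())


def deduplicate_calls(calls: list[TypeOneCall], G: int) -> list[TypeOneCall]:
    """Keep at most one call per junction.

    Breakpoint pileups at a real junction seed satellite clusters in other
    planes (the junction's endpoint column paired with chance partners); a
    genomic junction can only participate in one rearrangement, so any call
    whose breakpoints come within G of a stronger call's breakpoints is
    dropped.
    """
    kept: list[TypeOneCall] = []
    for c in sorted(calls, key=lambda c: -c.score1):
        clash = any(
            min(abs(c.lin_b1 - k.lin_b1), abs(c.lin_b1 - k.lin_b2),
                abs(c.lin_b2 - k.lin_b1), abs(c.lin_b2 - k.lin_b2)) < G
            for k in kept)
        if not clash:
            kept.append(c)
    return kept


def merge_inversion_calls(calls: list[TypeOneCall], G: int) -> list[TypeOneCall]:
    """Fuse RR/LL inversion call pairs whose breakpoints agree within G.

    The merged call keeps the support-weighted mean breakpoints, the summed
    support and the stronger score (the two clusters test the same event
    from its two junctions).
    """
    out = [c for c in calls if c.sv_type != "INV"]
    invs = [c for c in calls if c.sv_type == "INV"]
    used = [False] * len(invs)
    for i, a in enumerate(invs):
        if used[i]:
            continue
        partner = None
        for j in range(i + 1, len(invs)):
            b = invs[j]
            if used[j] or a.plane == b.plane:
                continue
            if (abs(a.lin_b1 - b.lin_b1) < G and abs(a.lin_b2 - b.lin_b2) < G):
                partner = j
                break
        if partner is None:
            out.append(a)
            used[i] = True
            continue
        b = invs[partner]
        used[i] = used[partner] = True
        wa, wb = a.n_support, b.n_support
        lin1 = int(round((a.lin_b1 * wa + b.lin_b1 * wb) / (wa + wb)))
        lin2 = int(round((a.lin_b2 * wa + b.lin_b2 * wb) / (wa + wb)))
        stronger = a if a.score1 >= b.score1 else b
        off1 = lin1 - stronger.lin_b1
        off2 = lin2 - stronger.lin_b2
        out.append(dataclasses.replace(
            stronger,
            pos1=stronger.pos1 + off1, pos2=stronger.pos2 + off2,
            lin_b1=lin1, lin_b2=lin2,
            n_support=wa + wb,
            frag1_rows=np.concatenate([a.frag1_rows, b.frag1_rows]),
            frag2_rows=np.concatenate([a.frag2_rows, b.frag2_rows]),
        ))
    return out
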