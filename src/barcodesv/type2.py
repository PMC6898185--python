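"""Type 2 evidence: twin-window barcode-similarity scan.

Two adjacent windows on the genome are spanned by nearly the same set of
molecules, so they share most barcodes -- except across an SV breakpoint,
where the reads on the two sides come from different loci of the
rearranged genome and the shared-barcode fraction collapses. The scan
slides a twin-window boundary along the genome in 100 bp steps and records
per boundary: the distinct barcode counts m1/m2 of the two windows, the
shared count x, and a read-distance term d.

Two similarity models are available:

* ``simple`` -- S = 2x / (m1 + m2), the symmetric shared-barcode fraction,
  suited to WGS where coverage is uniform;
* ``regression`` -- S = x / (m1^a * m2^b) * n * exp(-alpha * d) with
  (a, b, alpha, n) fitted by least squares on log x so that S ~ 1 on null
  boundaries; the depth- and distance-aware form suited to capture data.

Breakpoint candidates are boundaries in the lowest 5th percentile of S;
each run of consecutive sub-threshold boundaries collapses to its minimum.
The reported p-value is empirical -- the fraction of all scanned
boundaries at least as dissimilar -- and score 2 is its -log10.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .dataset import GenomeIndex

logger = logging.getLogger(__name__)

DEFAULT_STEP = 100
DEFAULT_MIN_BARCODES = 10
WES_WINDOW = 40_000


@dataclasses.dataclass
class SimilarityModel:
    """Parameters of the twin-window similarity statistic."""

    mode: str = "simple"          # "simple" or "regression"
    a: float = 1.0
    b: float = 1.0
    alpha: float = 0.0            # per-bp decay of sharing with read distance
    n_lib: float = 1.0            # library constant

    def __post_init__(self) -> None:
        if self.mode not in ("simple", "regression"):
            raise ValueError(f"unknown similarity mode {self.mode!r}")
        if self.mode == "regression":
            if not (0 < self.a <= 1 and 0 < self.b <= 1):
                raise ValueError("exponents a, b must be in (0, 1]")
            if self.alpha < 0 or self.n_lib <= 0:
                raise ValueError("alpha must be >= 0 and n_lib > 0")

    def similarity(self, x, m1, m2, d) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        m1 = np.asarray(m1, dtype=np.float64)
        m2 = np.asarray(m2, dtype=np.float64)
        if self.mode == "simple":
            return 2.0 * x / (m1 + m2)
        d = np.asarray(d, dtype=np.float64)
        return (x / (m1 ** self.a * m2 ** self.b)
                * self.n_lib * np.exp(-self.alpha * d))


def scan_twin_windows(
    table: pd.DataFrame,
    genome: GenomeIndex,
    window: int,
    step: int = DEFAULT_STEP,
    min_barcodes: int = DEFAULT_MIN_BARCODES,
) -> pd.DataFrame:
    """Count barcodes around every twin-window boundary.

    Returns one row per retained boundary with columns
    (chrom_id, pos, m1, m2, x, d); boundaries whose windows hold fewer
    than ``min_barcodes`` distinct barcodes are skipped. The window length
    is rounded to a whole number of steps. ``d`` is the mean distance of
    left-window read positions to the boundary plus the same for the right
    window (sparse capture inflates it, which the regression model
    penalises).

    The counting is O(unique (barcode, bin) pairs): for each barcode the
    boundary ranges in which it is present in the left (right) window are
    decomposed into disjoint intervals keyed on consecutive read bins, and
    accumulated in difference arrays.
    """
    W = max(1, int(round(window / step)))
    chrom = table["chrom_id"].to_numpy()
    pos = table["pos"].to_numpy()
    bc = table["barcode_id"].to_numpy().astype(np.int64)

    out = []
    for cid in np.unique(chrom):
        m = chrom == cid
        cpos = pos[m]
        cbc = bc[m]
        nbins = int(genome.lengths[cid]) // step + 1
        t = cpos // step

        key = cbc * nbins + t
        key = np.unique(key)
        ub = key // nbins
        ut = key % nbins
        first = np.r_[True, ub[1:] != ub[:-1]]
        last = np.r_[ub[1:] != ub[:-1], True]
        prv = np.where(first, -W - 1, np.r_[0, ut[:-1]])
        nxt = np.where(last, nbins + W + 1, np.r_[ut[1:], 0])

        dm1 = np.zeros(nbins + 2, dtype=np.int64)
        dm2 = np.zeros(nbins + 2, dtype=np.int64)
        dx = np.zeros(nbins + 2, dtype=np.int64)

        # left window [k-W, k): counted at k where this bin is the last of
        # its barcode before k and within reach
        lo = ut + 1
        hi = np.minimum(ut + W, nxt)
        ok = hi >= lo
        lo_c = np.clip(lo[ok], 0, nbins)
        hi_c = np.clip(hi[ok], 0, nbins)
        np.add.at(dm1, lo_c, 1)
        np.add.at(dm1, hi_c + 1, -1)

        # right window [k, k+W): counted where this bin is the first of its
        # barcode at or after k
        lo = np.maximum(ut - W + 1, prv + 1)
        hi = ut
        ok = hi >= lo
        lo_c = np.clip(lo[ok], 0, nbins)
        hi_c = np.clip(hi[ok], 0, nbins)
        np.add.at(dm2, lo_c, 1)
        np.add.at(dm2, hi_c + 1, -1)

        # shared: the barcode straddles k via the consecutive bin pair
        # (t, nxt)
        has_next = nxt <= nbins
        lo = np.maximum(ut + 1, nxt - W + 1)[has_next]
        hi = np.minimum(ut + W, nxt)[has_next]
        ok = hi >= lo
        lo_c = np.clip(lo[ok], 0, nbins)
        hi_c = np.clip(hi[ok], 0, nbins)
        np.add.at(dx, lo_c, 1)
        np.add.at(dx, hi_c + 1, -1)

        m1 = np.cumsum(dm1)[:nbins + 1]
        m2 = np.cumsum(dm2)[:nbins + 1]
        xs = np.cumsum(dx)[:nbins + 1]

        cnt = np.bincount(t, minlength=nbins).astype(np.int64)
        psum = np.bincount(t, weights=cpos.astype(np.float64), minlength=nbins)
        ccnt = np.concatenate([[0], np.cumsum(cnt)])
        cpsum = np.concatenate([[0.0], np.cumsum(psum)])

        ks = np.arange(W, nbins - W + 1)
        lc = ccnt[ks] - ccnt[ks - W]
        rc = ccnt[np.minimum(ks + W, nbins)] - ccnt[ks]
        ls = cpsum[ks] - cpsum[ks - W]
        rs = cpsum[np.minimum(ks + W, nbins)] - cpsum[ks]
        bpos = ks.astype(np.float64) * step
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(lc > 0, bpos - ls / np.maximum(lc, 1), window) \
                + np.where(rc > 0, rs / np.maximum(rc, 1) - bpos, window)

        keep = (m1[ks] >= min_barcodes) & (m2[ks] >= min_barcodes)
        ksel = ks[keep]
        out.append(pd.DataFrame({
            "chrom_id": np.full(len(ksel), cid, dtype=np.int32),
            "pos": (ksel * step).astype(np.int64),
            "m1": m1[ksel],
            "m2": m2[ksel],
            "x": xs[ksel],
            "d": d[keep],
        }))
    if not out:
        return pd.DataFrame({c: np.array([], dtype=np.int64)
                             for c in ("chrom_id", "pos", "m1", "m2", "x", "d")})
    return pd.concat(out, ignore_index=True)


def fit_similarity_model(
    scores: pd.DataFrame,
    max_records: int = 100_000,
    min_records: int = 1000,
) -> SimilarityModel:
    """Fit the regression similarity model on presumed-null boundaries.

    Least squares of log x on (log m1, log m2, d, 1) over boundaries with
    x >= 1; the fitted model has S ~ 1 on typical null windows by
    construction. Falls back to simple mode (with a warning) when the data
    are too few, the design is degenerate, or the fitted parameters leave
    their admissible ranges.
    """
    sub = scores[scores["x"] >= 1]
    if len(sub) < min_records:
        logger.warning("too few boundaries (%d) to fit the similarity "
                       "model; falling back to simple mode", len(sub))
        return SimilarityModel(mode="simple")
    if len(sub) > max_records:
        idx = np.random.default_rng(0).choice(len(sub), max_records,
                                              replace=False)
        sub = sub.iloc[np.sort(idx)]
    X = np.column_stack([
        np.log(sub["m1"].to_numpy(dtype=np.float64)),
        np.log(sub["m2"].to_numpy(dtype=np.float64)),
        sub["d"].to_numpy(dtype=np.float64),
        np.ones(len(sub)),
    ])
    yv = np.log(sub["x"].to_numpy(dtype=np.float64))
    coef, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < X.shape[1]:
        logger.warning("rank-deficient similarity regression; "
                       "falling back to simple mode")
        return SimilarityModel(mode="simple")
    a, b, alpha, c = coef
    a = min(a, 1.0)
    b = min(b, 1.0)
    if alpha < 0 and alpha > -1e-6:
        alpha = 0.0
    if not (0 < a <= 1 and 0 < b <= 1) or alpha < 0:
        logger.warning("similarity regression outside the admissible "
                       "parameter region (a=%.3f b=%.3f alpha=%.2e); "
                       "falling back to simple mode", a, b, alpha)
        return SimilarityModel(mode="simple")
    return SimilarityModel(mode="regression", a=float(a), b=float(b),
                           alpha=float(alpha), n_lib=float(np.exp(-c)))


def apply_similarity(scores: pd.DataFrame, model: SimilarityModel) -> pd.DataFrame:
    scores = scores.copy()
    scores["S"] = model.similarity(scores["x"], scores["m1"], scores["m2"],
                                   scores["d"])
    return scores


def call_type2_breakpoints(
    scores: pd.DataFrame,
    percentile_threshold: float = 5.0,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Candidate breakpoints from the low tail of the similarity track.

    Boundaries with S below the ``percentile_threshold`` percentile are
    candidates; runs of consecutive sub-threshold boundaries collapse to
    the single minimum-S boundary (ties to the leftmost). Each candidate
    carries the empirical p-value (fraction of all boundaries with
    S <= S0) and score2 = -log10(p).
    """
    if len(scores) == 0:
        return scores.assign(p_empirical=[], score2=[])
    S = scores["S"].to_numpy(dtype=np.float64)
    thr = np.percentile(S, percentile_threshold)
    below = np.flatnonzero(S < thr)
    if below.size == 0:
        return scores.iloc[0:0].assign(p_empirical=[], score2=[])
    chrom = scores["chrom_id"].to_numpy()
    pos = scores["pos"].to_numpy()
    newrun = np.ones(below.size, dtype=bool)
    newrun[1:] = ((chrom[below[1:]] != chrom[below[:-1]])
                  | (pos[below[1:]] - pos[below[:-1]] != step))
    run_id = np.cumsum(newrun) - 1
    reps = []
    for r in range(run_id[-1] + 1):
        members = below[run_id == r]
        reps.append(members[np.argmin(S[members])])
    reps = np.asarray(reps)
    S_sorted = np.sort(S)
    p_emp = np.searchsorted(S_sorted, S[reps], side="right") / len(S)
    out = scores.iloc[reps].copy().reset_index(drop=True)
    out["p_empirical"] = p_emp
    out["score2"] = -np.log10(p_emp)
    return out
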