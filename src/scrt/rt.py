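"""Binary single-cell replication-timing profiles and pseudo-bulk RT.

Per-cell integer copy-number segments are re-binned to a coarser RT grid
(200 kb by default) by weighted median (weights = segment/bin overlap in
bp).  A median G1/G2 profile serves as the reference; each S-phase cell
is normalised as nCN = log2(CN200 / CNG), which is ~0 on unreplicated
bins and ~1 on replicated ones (doubled dose).  Binarization picks the
per-cell threshold th in [0, 1] minimising the squared distance between
nCN and its 0/1 assignment; since flipping a bin with value v as th
passes it changes the loss by 2v - 1, the loss is unimodal and the exact
minimiser can be found by evaluating the candidate thresholds given by
the data values themselves.

Quality control drops cells whose binary profile disagrees with most of
the population (simple-matching-coefficient distance >= 0.25 to at least
60% of the other cells).  The pseudo-bulk RT averages profiles within
replication-percentage intervals, trims extreme intervals until the
retained percentage distribution is roughly symmetric around 50%, and
averages the interval means (1 = early).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import weighted_median

DEFAULT_RT_BIN_SIZE = 200_000


def make_rt_bins(chrom_lengths, rt_bin_size: int = DEFAULT_RT_BIN_SIZE):
    """Tile chromosomes with RT-resolution bins."""
    from .bins import make_bins
    return make_bins(list(chrom_lengths), bin_size=rt_bin_size,
                     include_sex=True)[["chrom", "start", "end"]]


def chrom_lengths_from_bins(bins: pd.DataFrame):
    return [(c, int(g.end.max())) for c, g in bins.groupby("chrom",
                                                           sort=False)]


def rebin_cn(segments: pd.DataFrame, rt_bins: pd.DataFrame) -> np.ndarray:
    """Weighted-median copy number of one cell on the RT grid.

    Weights are the bp overlaps between the RT bin and the CN segments;
    an exactly even split resolves to the mean of the two straddling CN
    values.  Bins with no overlapping segment are NaN.
    """
    out = np.full(len(rt_bins), np.nan)
    by_chrom = {}
    for chrom, segs in segments.groupby("chrom", sort=False):
        segs = segs.sort_values("start")
        by_chrom[chrom] = (segs.start.to_numpy(), segs.end.to_numpy(),
                           segs.cn.to_numpy(dtype=float))
    for i, (chrom, start, end) in enumerate(
            zip(rt_bins.chrom, rt_bins.start, rt_bins.end)):
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        s_start, s_end, s_cn = entry
        # segments are sorted; find the overlapping run directly
        i0 = int(np.searchsorted(s_end, start, side="right"))
        i1 = int(np.searchsorted(s_start, end, side="left"))
        if i1 <= i0:
            continue
        if i1 - i0 == 1:                      # bin inside one segment
            out[i] = s_cn[i0]
            continue
        w = (np.minimum(s_end[i0:i1], end)
             - np.maximum(s_start[i0:i1], start)).clip(min=0)
        sel = w > 0
        if sel.any():
            out[i] = weighted_median(s_cn[i0:i1][sel], w[sel])
    return out


def cn200_matrix(segment_tables: dict, rt_bins: pd.DataFrame) -> pd.DataFrame:
    """Stack per-cell re-binned CN rows into a cells x bins DataFrame."""
    rows = {cid: rebin_cn(segs, rt_bins)
            for cid, segs in segment_tables.items()}
    cols = [f"{c}:{s}-{e}" for c, s, e in
            zip(rt_bins.chrom, rt_bins.start, rt_bins.end)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def g1g2_reference(cn200_g: pd.DataFrame) -> pd.Series:
    """Median G1/G2 copy-number profile; zero/undefined bins are masked."""
    cng = cn200_g.median(axis=0, skipna=True)
    cng[cng <= 0] = np.nan
    return cng


def normalize_s_cell(cn200_row: pd.Series, cng: pd.Series) -> pd.Series:
    """log2 ratio of an S-phase cell to the G1/G2 reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ncn = np.log2(cn200_row / cng)
    ncn[~np.isfinite(ncn)] = np.nan
    return ncn


def binarize(ncn_row: pd.Series):
    """Optimal 0/1 assignment of a normalised profile.

    Returns ``(binary_row, threshold, epsilon)``; the loss is
    sum (nCN - b)^2 with b = 1{nCN >= th}, minimised exactly over
    th in [0, 1] (candidates: 0, 1 and every data value in between).
    Missing bins stay missing in the output.
    """
    vals = ncn_row.to_numpy(dtype=float)
    defined = np.isfinite(vals)
    if not defined.any():
        raise ValueError("all bins missing; cannot binarize")
    v = vals[defined]
    cands = np.unique(np.concatenate([[0.0, 1.0],
                                      v[(v > 0.0) & (v < 1.0)]]))
    # vectorized loss over candidates
    ones = v[None, :] >= cands[:, None]
    eps = np.where(ones, (v[None, :] - 1.0) ** 2,
                   v[None, :] ** 2).sum(axis=1)
    k = int(np.argmin(eps))
    th = float(cands[k])
    binary = np.where(defined, (vals >= th).astype(float), np.nan)
    return pd.Series(binary, index=ncn_row.index), th, float(eps[k])


@dataclass
class RTMatrix:
    """Cells x RT-bins binary replication matrix with per-cell metadata."""
    scrt: pd.DataFrame                 # binary (0/1/NaN)
    ncn: pd.DataFrame                  # normalised log2 profiles
    thresholds: pd.Series              # per-cell thm
    replication_pct: pd.Series         # mean of binary profile per cell

    @property
    def cells(self):
        return list(self.scrt.index)


def build_rt_matrix(cn200_s: pd.DataFrame, cn200_g: pd.DataFrame,
                    groups: pd.Series | None = None,
                    max_missing_frac: float = 0.25) -> RTMatrix:
    """Normalise and binarize every S cell against its G1/G2 reference.

    ``groups`` optionally maps every cell (S and G1/G2) to a
    sub-population label; each S cell is then normalised against the
    median profile of its own group's G1/G2 cells, which is how
    sub-clonal CNV differences are kept out of the replication signal.
    Bins missing in at least ``max_missing_frac`` of S cells are masked
    matrix-wide.
    """
    ncn_rows = {}
    for cid in cn200_s.index:
        if groups is not None:
            g_cells = [g for g in cn200_g.index
                       if groups.get(g) == groups.get(cid)]
            if not g_cells:
                raise ValueError(f"no G1/G2 reference cells for group "
                                 f"of cell {cid!r}")
            cng = g1g2_reference(cn200_g.loc[g_cells])
        else:
            cng = g1g2_reference(cn200_g)
        ncn_rows[cid] = normalize_s_cell(cn200_s.loc[cid], cng)
    ncn = pd.DataFrame.from_dict(ncn_rows, orient="index")
    ncn = ncn.loc[cn200_s.index]

    missing = ncn.isna().mean(axis=0)
    ncn.loc[:, missing >= max_missing_frac] = np.nan

    scrt_rows, ths = {}, {}
    for cid in ncn.index:
        binary, th, _eps = binarize(ncn.loc[cid])
        scrt_rows[cid] = binary
        ths[cid] = th
    scrt = pd.DataFrame.from_dict(scrt_rows, orient="index").loc[ncn.index]
    pct = scrt.mean(axis=1, skipna=True)
    return RTMatrix(scrt=scrt, ncn=ncn, thresholds=pd.Series(ths),
                    replication_pct=pct)


# ---------------------------------------------------------------------------
# SMC filtering

def smc_distance_matrix(scrt: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - simple-matching-coefficient over shared defined bins."""
    x = scrt.to_numpy(dtype=float)
    defined = np.isfinite(x)
    x0 = np.nan_to_num(x)
    n = x.shape[0]
    both = defined.astype(float) @ defined.astype(float).T
    agree_11 = x0 @ x0.T
    agree_00 = ((1 - x0) * defined) @ ((1 - x0) * defined).T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - (agree_11 + agree_00) / both
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=scrt.index, columns=scrt.index)


def smc_filter(rtm: RTMatrix, max_distance: float = 0.25,
               population_frac: float = 0.6,
               pct_window: float | None = None):
    """Drop cells diverging by >= 25% from at least 60% of the others.

    With ``pct_window`` set, each cell is compared only against cells
    whose replication percentage lies within that window of its own:
    cells at opposite ends of S phase legitimately disagree on most
    bins, so for asynchronous populations an aberrant cell is one that
    diverges from its own stage, not from the whole of S phase.
    Returns ``(filtered RTMatrix, dropped cell ids)``.
    """
    dist = smc_distance_matrix(rtm.scrt).to_numpy()
    n = dist.shape[0]
    dropped = []
    if n > 1:
        compare = ~np.eye(n, dtype=bool)
        if pct_window is not None:
            pct = rtm.replication_pct.to_numpy(dtype=float)
            compare &= (np.abs(pct[:, None] - pct[None, :])
                        <= pct_window)
        far = ((dist >= max_distance) & compare).sum(axis=1)
        n_cmp = compare.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_far = np.where(n_cmp > 0, far / n_cmp, 0.0)
        dropped = [cid for cid, f in zip(rtm.scrt.index, frac_far)
                   if f >= population_frac]
    keep = [c for c in rtm.scrt.index if c not in dropped]
    out = RTMatrix(scrt=rtm.scrt.loc[keep], ncn=rtm.ncn.loc[keep],
                   thresholds=rtm.thresholds.loc[keep],
                   replication_pct=rtm.replication_pct.loc[keep])
    return out, dropped


# ---------------------------------------------------------------------------
# pseudo-bulk

def pseudo_bulk(rtm: RTMatrix, interval_width: float = 0.025,
                symmetry_tol: float = 0.05):
    """Average binary profiles into a population RT track (1 = early).

    Cells are grouped into replication-percentage intervals; extreme
    intervals on the heavier tail are dropped until the mean retained
    percentage is within ``symmetry_tol`` of 50%, and the remaining
    interval mean profiles are averaged with equal weight, so that the
    sampling of S-phase progression does not bias the track.
    Returns ``(track, n_cells_used)``.
    """
    if len(rtm.scrt) < 2:
        raise ValueError("pseudo-bulk needs at least 2 cells")
    pct = rtm.replication_pct
    idx = np.minimum((pct / interval_width).astype(int),
                     int(np.ceil(1 / interval_width)) - 1)
    intervals = sorted(idx.unique())
    while len(intervals) > 1:
        cells = pct.index[idx.isin(intervals)]
        mean_pct = float(pct.loc[cells].mean())
        if abs(mean_pct - 0.5) <= symmetry_tol:
            break
        if mean_pct > 0.5:
            intervals = intervals[:-1]
        else:
            intervals = intervals[1:]
    cells = pct.index[idx.isin(intervals)]
    means = []
    for iv in intervals:
        sel = pct.index[idx == iv]
        if len(sel) == 0:
            continue
        means.append(rtm.scrt.loc[sel].mean(axis=0, skipna=True))
    track = pd.concat(means, axis=1).mean(axis=1, skipna=True)
    return track, int(len(cells))
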