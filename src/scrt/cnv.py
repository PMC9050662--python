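"""Per-cell copy-number calling from binned read counts.

Pipeline per cell: raw counts on usable bins -> mappability and GC
correction -> intracellular bin-to-bin variability (DIMAPD, computed on a
500-kb aggregation across the whole population) -> per-chromosome
segmentation -> integer copy numbers by minimisation of a sine target
function over a candidate reads-per-copy value X, with ploidy limits
pruning implausible solutions.

The correction chain is
    rm_n = r_n / M_n
    R_n  = rm_n * median(rm) / median(rm | same GC class)
i.e. mappability division followed by a GC-class median rescaling that
leaves the genome-wide median invariant.  Corrections preserve zeros and
are equivariant under global scaling of a cell's counts.

Copy numbers come from
    chi(X) = sqrt( sum_n S_n * sin^2(pi * R_n / X) )
evaluated over X in the [5th, 95th] percentile range of segment counts;
every local minimum is a candidate solution, candidates whose implied
mean ploidy falls outside the configured limits are discarded, and
CN_n = round(R_n / X_min).  The gap in chi between the best and the
runner-up feasible minimum is reported as the ploidy confidence
(solutions with a gap < 2 are flagged unreliable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._utils import round_half_away

DEFAULT_MAPQ_MIN = 30
DEFAULT_MIN_READS = 200_000
PLOIDY_CONFIDENCE_RELIABLE = 2.0


@dataclass
class CellCounts:
    """One cell's binned read counts, aligned to a bin table."""
    cell_id: str
    raw: np.ndarray                      # per-bin integer counts
    total_reads: int = 0
    rpmb: float = np.nan                 # reads per Mb of usable genome
    corrected: np.ndarray | None = None  # filled by correct_counts


@dataclass
class DimapdRecord:
    cell_id: str
    mapd_c: float
    coverage_sqrt: float
    dimapd: float


@dataclass
class PloidySolution:
    x_min: float
    chi_curve: np.ndarray        # (n, 2) samples of (X, chi)
    ploidy: float
    ploidy_confidence: float
    reliable: bool = True
    candidates: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# counting

def _require(condition, message):
    if not condition:
        raise ValueError(message)


def count_reads(alignments, bins: pd.DataFrame,
                mapq_min: int = DEFAULT_MAPQ_MIN,
                cell_id: str | None = None) -> CellCounts:
    """Count high-quality reads of one cell into the bin table.

    ``alignments`` is a pysam.AlignmentFile (SAM/BAM) or an iterable of
    AlignedSegment.  Unmapped, secondary/supplementary, duplicate-flagged
    and low-MAPQ reads are skipped.  For read pairs mapping into the same
    bin the pair counts once; mates in different bins count
    independently (the mate is assumed to pass the same filters).
    """
    import pysam

    import os
    close = False
    if isinstance(alignments, (str, os.PathLike)):
        alignments = pysam.AlignmentFile(alignments)
        close = True
    header_contigs = None
    if isinstance(alignments, pysam.AlignmentFile):
        header_contigs = set(alignments.references)
        missing = sorted(set(bins.chrom.unique()) - header_contigs)
        if missing:
            raise ValueError(
                "bin table contigs absent from alignment header: "
                + ", ".join(missing))

    from .bins import _BinIndex
    bins = bins.reset_index(drop=True)
    index = _BinIndex(bins)
    widths = {}
    for chrom, grp in bins.groupby("chrom"):
        w = (grp.end - grp.start).to_numpy()
        widths[chrom] = int(np.max(w)) if len(w) else 0

    raw = np.zeros(len(bins), dtype=np.int64)
    total = 0
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_duplicate or read.mapping_quality < mapq_min:
            continue
        chrom = read.reference_name
        i = index.locate(chrom, read.reference_start)
        if i is None:
            continue
        if (read.is_paired and read.is_read2 and not read.mate_is_unmapped
                and read.next_reference_name == chrom):
            j = index.locate(chrom, read.next_reference_start)
            if j == i:
                continue  # pair already counted through the mate
        raw[i] += 1
        total += 1
    if close:
        alignments.close()

    usable_mb = float((bins.end - bins.start)[bins.usable].sum()) / 1e6
    rpmb = raw[bins.usable.to_numpy()].sum() / usable_mb if usable_mb else np.nan
    return CellCounts(cell_id=cell_id or "cell", raw=raw,
                      total_reads=int(total), rpmb=float(rpmb))


def cell_from_counts(cell_id: str, raw: np.ndarray,
                     bins: pd.DataFrame) -> CellCounts:
    """Wrap a pre-computed count vector (e.g. simulated) as CellCounts."""
    raw = np.asarray(raw, dtype=np.int64)
    _require(raw.size == len(bins), "count vector does not match bin table")
    usable = bins.usable.to_numpy()
    usable_mb = float((bins.end - bins.start)[bins.usable].sum()) / 1e6
    rpmb = raw[usable].sum() / usable_mb if usable_mb else np.nan
    return CellCounts(cell_id=cell_id, raw=raw, total_reads=int(raw.sum()),
                      rpmb=float(rpmb))


def filter_low_coverage(cells, min_reads: int = DEFAULT_MIN_READS):
    """Partition cells into (kept, discarded) by total read count."""
    kept = [c for c in cells if c.total_reads >= min_reads]
    discarded = [c for c in cells if c.total_reads < min_reads]
    return kept, discarded


# ---------------------------------------------------------------------------
# bias correction

def gc_classes(gc: np.ndarray, grid: float = 0.01,
               min_bins: int = 20) -> np.ndarray:
    """Round GC to a grid and merge sparse classes with their nearest
    neighbour so class medians stay stable."""
    cls = np.round(np.asarray(gc, dtype=float) / grid).astype(int)
    labels, counts = np.unique(cls, return_counts=True)
    labels = labels.tolist()
    counts = dict(zip(labels, counts))
    merged = {lab: lab for lab in labels}
    changed = True
    while changed:
        changed = False
        labs = sorted({merged[l] for l in labels})
        sizes = {}
        for l in labels:
            sizes[merged[l]] = sizes.get(merged[l], 0) + counts[l]
        for lab in labs:
            if sizes[lab] < min_bins and len(labs) > 1:
                others = [o for o in labs if o != lab]
                nearest = min(others, key=lambda o: abs(o - lab))
                for l in labels:
                    if merged[l] == lab:
                        merged[l] = nearest
                changed = True
                break
    return np.array([merged[c] for c in cls])


def correct_counts(cell: CellCounts, bins: pd.DataFrame,
                   gc_grid: float = 0.01,
                   min_bins_per_class: int = 20) -> CellCounts:
    """Mappability- and GC-correct a cell's raw counts (usable bins only)."""
    usable = bins.usable.to_numpy()
    _require(usable.any(), "no usable bins")
    raw = cell.raw[usable].astype(float)
    if raw.sum() == 0:
        raise ValueError(f"no signal: cell {cell.cell_id} has zero counts "
                         "on usable bins")
    mapp = bins.mappability.to_numpy()[usable]
    _require(np.all(mapp > 0), "usable bin with non-positive mappability")
    rm = raw / mapp

    gc = bins.gc.to_numpy()[usable]
    pool = ~bins.is_remainder.to_numpy()[usable]   # remainder bins: corrected
    cls = gc_classes(gc, grid=gc_grid, min_bins=min_bins_per_class)
    global_med = np.median(rm[pool]) if pool.any() else np.median(rm)
    corrected = np.empty_like(rm)
    for lab in np.unique(cls):
        sel = cls == lab
        ref = sel & pool
        med = np.median(rm[ref]) if ref.any() else np.median(rm[sel])
        factor = global_med / med if med > 0 else 0.0
        corrected[sel] = rm[sel] * factor

    full = np.full(cell.raw.size, np.nan)
    full[usable] = corrected
    return CellCounts(cell_id=cell.cell_id, raw=cell.raw,
                      total_reads=cell.total_reads, rpmb=cell.rpmb,
                      corrected=full)


# ---------------------------------------------------------------------------
# DIMAPD

def aggregate_counts(raw: np.ndarray, bins: pd.DataFrame,
                     width: int = 500_000):
    """Sum raw counts into coarse bins; returns (chrom labels, counts)."""
    key = bins.start.to_numpy() // width
    chroms = bins.chrom.to_numpy()
    df = pd.DataFrame({"chrom": chroms, "key": key, "n": raw})
    agg = df.groupby(["chrom", "key"], sort=True)["n"].sum().reset_index()
    return agg.chrom.to_numpy(), agg.n.to_numpy().astype(float)


def _mapdc(chroms: np.ndarray, counts: np.ndarray, genome_mb: float):
    """MAPD scaled by sqrt coverage for one cell (500-kb aggregation)."""
    mean = counts.mean()
    if mean == 0:
        return 0.0, 0.0
    diffs = []
    for chrom in pd.unique(chroms):
        c = counts[chroms == chrom]
        if c.size >= 2:
            diffs.append(np.diff(c) * -1.0)  # R_i - R_{i+1}
    if not diffs:
        return 0.0, float(np.sqrt(counts.sum() / genome_mb))
    d = np.concatenate(diffs) / mean
    mapd = float(np.median(np.abs(d - np.median(d))))
    cov = float(np.sqrt(counts.sum() / genome_mb))
    return mapd * cov, cov


def compute_dimapd(cells, bins: pd.DataFrame,
                   genome_size_mb: float | None = None,
                   agg_width: int = 500_000) -> list[DimapdRecord]:
    """Depth-independent bin-to-bin variability for a population of cells.

    MAPDC (median absolute deviation of neighbouring-bin differences,
    scaled by root coverage) grows linearly with root coverage; the
    linear trend is fitted across cells by ordinary least squares and
    removed, centring the statistic at 1 for the quiet majority.
    Requires at least two cells, since the trend is population-level.
    """
    cells = list(cells)
    if len(cells) < 2:
        raise ValueError("DIMAPD needs >= 2 cells (population-level "
                         "coverage regression); supply the coefficients "
                         "manually for single-cell use")
    if genome_size_mb is None:
        genome_size_mb = float((bins.end - bins.start).sum()) / 1e6
    mapdc = np.empty(len(cells))
    cov = np.empty(len(cells))
    for i, cell in enumerate(cells):
        chroms, counts = aggregate_counts(cell.raw, bins, width=agg_width)
        mapdc[i], cov[i] = _mapdc(chroms, counts, genome_size_mb)
    dc = cov - np.median(cov)
    if np.allclose(dc, 0):
        # regression through a point: the intercept absorbs the level
        a, b = 0.0, float(np.median(mapdc))
    else:
        # robust fit: the trend belongs to the quiet (G1/G2) majority,
        # and replicating cells are exactly the outliers being scored
        from scipy.stats import theilslopes
        a, b, _lo, _hi = theilslopes(mapdc, dc)
    dimapd = 1.0 + mapdc - a * dc - b
    return [DimapdRecord(cell_id=c.cell_id, mapd_c=float(m),
                         coverage_sqrt=float(cv), dimapd=float(d))
            for c, m, cv, d in zip(cells, mapdc, cov, dimapd)]


# ---------------------------------------------------------------------------
# segmentation

def _sse_split(x):
    """Best single split of x by least squares; returns (k, sse0, sse1)."""
    n = x.size
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    total, total2 = cs[-1], cs2[-1]
    sse0 = total2 - total * total / n
    ks = np.arange(1, n)
    left = cs[:-1]
    left2 = cs2[:-1]
    sse_l = left2 - left * left / ks
    nr = n - ks
    right = total - left
    right2 = total2 - left2
    sse_r = right2 - right * right / nr
    sse = sse_l + sse_r
    k = int(np.argmin(sse))
    return k + 1, float(sse0), float(sse[k])


def _binseg(x: np.ndarray, penalty: float, min_size: int = 3):
    """Recursive least-squares binary segmentation.

    A split is accepted when the Gaussian log-likelihood-ratio statistic
    n*log(sse0/sse1) exceeds ``penalty``.  Returns sorted breakpoints
    (interior indices).
    """
    out = []

    def recurse(lo, hi):
        n = hi - lo
        if n < 2 * min_size:
            return
        seg = x[lo:hi]
        k, sse0, sse1 = _sse_split(seg)
        if k < min_size or n - k < min_size:
            # best split too close to an edge; try best interior split
            cs = np.cumsum(seg)
            cs2 = np.cumsum(seg * seg)
            ks = np.arange(min_size, n - min_size + 1)
            if ks.size == 0:
                return
            left = cs[ks - 1]
            left2 = cs2[ks - 1]
            sse_l = left2 - left * left / ks
            right = cs[-1] - left
            right2 = cs2[-1] - left2
            sse_r = right2 - right * right / (n - ks)
            sse = sse_l + sse_r
            j = int(np.argmin(sse))
            k, sse1 = int(ks[j]), float(sse[j])
        if sse0 <= 1e-12:
            return
        ratio = sse0 / max(sse1, 1e-12 * sse0)
        stat = n * np.log(ratio)
        if stat <= penalty:
            return
        out.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, x.size)
    return sorted(out)


def _cbs_stat(x, stride: int = 1, i_range=None, j_range=None):
    """Max circular (arc vs complement) mean-shift statistic.

    The statistic is |mean(arc) - mean(complement)| * sqrt(m(n-m)/n),
    i.e. the absolute two-sample z numerator; arcs are evaluated on a
    ``stride`` grid (with exact local refinement done by the caller).
    ``i_range``/``j_range`` restrict the arc edges for refinement.
    """
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    if i_range is None:
        lefts = np.arange(0, n, stride)
    else:
        lefts = np.arange(max(i_range[0], 0), min(i_range[1], n - 1) + 1)
    if j_range is None:
        rights = np.arange(stride, n + 1, stride)
        if rights.size == 0 or rights[-1] != n:
            rights = np.append(rights, n)
    else:
        rights = np.arange(max(j_range[0], 1), min(j_range[1], n) + 1)
    if lefts.size == 0 or rights.size == 0:
        return 0.0, None
    m = (rights[None, :] - lefts[:, None]).astype(float)
    seg = cs[rights][None, :] - cs[lefts][:, None]
    valid = (m > 0) & (m < n)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (np.abs(seg / m - (total - seg) / (n - m))
                * np.sqrt(m * (n - m) / n))
    stat[~valid] = 0.0
    k = int(np.argmax(stat))
    i, j = divmod(k, rights.size)
    best = float(stat[i, j])
    if best <= 0.0:
        return 0.0, None
    return best, (int(lefts[i]), int(rights[j]))


def _robust_sigma(x):
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d)))
                 / np.sqrt(2.0))


def _cbs(x: np.ndarray, min_size: int = 3, threshold_margin: float = 2.0,
         stride: int = 5):
    """Circular binary segmentation with an analytic threshold.

    A segment is split at the edges of the most outlying arc when the
    arc statistic exceeds sigma * (sqrt(2 log n) + margin), sigma being
    a robust (successive-difference) noise scale estimated per segment.
    Arc edges found on the stride grid are refined exactly in a local
    window.  Unlike greedy single-split segmentation this detects
    short elevated domains inside alternating signals, which is the
    structure replicating S-phase cells actually have.
    """
    out = []

    def recurse(lo, hi):
        n = hi - lo
        if n < 2 * min_size:
            return
        seg = x[lo:hi]
        if np.ptp(seg) == 0:
            return
        sigma = _robust_sigma(seg)
        use_stride = 1 if n <= 600 else stride
        stat, ij = _cbs_stat(seg, stride=use_stride)
        if ij is None:
            return
        if use_stride > 1:
            i0, j0 = ij
            stat, ij = _cbs_stat(
                seg, i_range=(i0 - use_stride, i0 + use_stride),
                j_range=(j0 - use_stride, j0 + use_stride))
            if ij is None:
                return
        if sigma <= 0:
            sigma = 1e-12 * max(np.ptp(seg), 1.0)
        if stat <= sigma * (np.sqrt(2 * np.log(n)) + threshold_margin):
            return
        i, j = ij
        cuts = sorted({c for c in (i, j) if 0 < c < n})
        if not cuts:
            return
        edges = [0] + cuts + [n]
        for c in cuts:
            out.append(lo + c)
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(lo + a, lo + b)

    recurse(0, x.size)
    return sorted(set(out))


def segment_profile(cell: CellCounts, bins: pd.DataFrame,
                    method: str = "cbs",
                    penalty_mult: float = 5.0,
                    min_size: int = 3,
                    seed=0) -> pd.DataFrame:
    """Segment a cell's corrected counts chromosome by chromosome.

    The default is a circular (arc-based) segmentation, which resolves
    the short alternating replicated/unreplicated domains of S-phase
    cells; ``method='bic'`` selects a greedy least-squares binary
    segmentation with a log-likelihood-ratio penalty instead.  Returns
    a segment table with the per-segment mean corrected count
    (``mean_count``), the genomic size of the usable bins it covers
    (``size``), and ``cn`` unset (NaN) until the ploidy solver runs.
    """
    _require(cell.corrected is not None, "run correct_counts first")
    usable = bins.usable.to_numpy()
    rows = []
    for chrom, grp in bins[usable].groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        x = cell.corrected[idx]
        widths = (grp.end - grp.start).to_numpy()
        if x.size < 2:
            breaks = []
        elif method == "bic":
            penalty = penalty_mult * np.log(max(x.size, 2))
            breaks = _binseg(x, penalty, min_size=min_size)
        elif method == "cbs":
            breaks = _cbs(x, min_size=min_size)
        else:
            raise ValueError(f"unknown segmentation method {method!r}")
        edges = [0] + list(breaks) + [x.size]
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append({
                "chrom": chrom,
                "start": int(grp.start.iloc[a]),
                "end": int(grp.end.iloc[b - 1]),
                "n_bins": b - a,
                "mean_count": float(np.mean(x[a:b])),
                "size": int(widths[a:b].sum()),
                "cn": np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# copy-number / ploidy solver

def chi(X, counts, sizes):
    """Target function: weighted root sum of squared sines."""
    X = np.atleast_1d(np.asarray(X, dtype=float))
    s = np.sin(np.pi * counts[None, :] / X[:, None]) ** 2
    val = np.sqrt((sizes[None, :] * s).sum(axis=1))
    return val if val.size > 1 else float(val[0])


def mean_ploidy(segments: pd.DataFrame) -> float:
    """Segment-size-weighted mean copy number."""
    _require(segments.cn.notna().all(), "cn not set on all segments")
    sizes = segments["size"].to_numpy(dtype=float)
    return float((sizes * segments.cn.to_numpy()).sum() / sizes.sum())


def estimate_cn(segments: pd.DataFrame,
                ploidy_limits: tuple[float, float] = (1.0, 8.0),
                grid_points: int = 2000,
                target_ploidy: float | None = None):
    """Assign integer copy numbers by chi minimisation.

    Returns ``(segments_with_cn, PloidySolution)``.  In
    closest-to-target mode (``target_ploidy`` set) the feasible minimum
    whose implied ploidy is nearest the target wins instead of the
    global one.
    """
    _require(len(segments) >= 1, "no segments")
    counts = segments.mean_count.to_numpy(dtype=float)
    sizes = segments["size"].to_numpy(dtype=float)
    # inclusive reading of the percentile window: order statistics, not
    # interpolated quantiles, so small segment sets keep their extreme
    # candidate X values (a 3-segment cell can still reach X = min count)
    lo = float(np.percentile(counts, 5, method="lower"))
    hi = float(np.percentile(counts, 95, method="higher"))
    if hi <= lo or not np.isfinite(hi - lo):
        xs = np.array([max(lo, 1e-9)])
    else:
        xs = np.linspace(max(lo, 1e-9), hi, grid_points)
    curve = chi(xs, counts, sizes)
    curve = np.atleast_1d(curve)

    # local minima on the grid (plateau-safe), endpoints included
    cand_x = []
    if xs.size == 1:
        cand_x = [float(xs[0])]
    else:
        for i in range(xs.size):
            left = curve[i - 1] if i > 0 else np.inf
            right = curve[i + 1] if i < xs.size - 1 else np.inf
            if curve[i] <= left and curve[i] <= right:
                lo_b = xs[max(i - 1, 0)]
                hi_b = xs[min(i + 1, xs.size - 1)]
                if hi_b > lo_b:
                    res = minimize_scalar(
                        lambda X: chi(X, counts, sizes),
                        bounds=(lo_b, hi_b), method="bounded",
                        options={"xatol": 1e-10 * hi_b})
                    cand_x.append(float(res.x))
                else:
                    cand_x.append(float(xs[i]))
    # deduplicate refined minima
    cand_x = sorted(set(np.round(cand_x, 12)))

    def _evaluate(xs_cand):
        evaluated = []
        for x in xs_cand:
            cn = round_half_away(counts / x)
            seg = segments.copy()
            seg["cn"] = cn
            p = mean_ploidy(seg)
            c = chi(np.array([x]), counts, sizes)
            feasible = (ploidy_limits[0] <= p <= ploidy_limits[1]) and p > 0
            evaluated.append({"x": x, "chi": float(np.atleast_1d(c)[0]),
                              "ploidy": p, "feasible": feasible})
        return evaluated

    candidates = _evaluate(cand_x)
    feas = [c for c in candidates if c["feasible"]]
    best_overall = min((c["chi"] for c in candidates), default=np.inf)
    best_feas = min((c["chi"] for c in feas), default=np.inf)
    if cand_x and best_feas > best_overall:
        # the globally best reads-per-copy unit is infeasible (or none
        # is feasible): chi is near-periodic in the unit, so evaluate
        # the octaves of the detected minima — a cell early or late in
        # S phase can have its true unit just outside the percentile
        # count window while a harmonic of it sits inside
        seen = {round(c["x"], 9) for c in candidates}
        harmonics = sorted({round(x * f, 12) for x in cand_x
                            for f in (0.5, 2.0)}
                           - seen)
        extra = _evaluate([x for x in harmonics if x > 0])
        candidates.extend(extra)
        feas = [c for c in candidates if c["feasible"]]
    if not feas:
        sol = PloidySolution(x_min=np.nan,
                             chi_curve=np.column_stack([xs, curve]),
                             ploidy=np.nan, ploidy_confidence=np.nan,
                             reliable=False, candidates=candidates)
        raise NoFeasiblePloidyError(
            "no feasible chi minimum within ploidy limits "
            f"{ploidy_limits}", sol)
    if target_ploidy is not None:
        feas.sort(key=lambda c: (abs(c["ploidy"] - target_ploidy), c["chi"]))
    else:
        feas.sort(key=lambda c: c["chi"])
    best = feas[0]
    runner = min((c["chi"] for c in feas[1:]), default=np.inf)
    confidence = runner - best["chi"]
    out = segments.copy()
    out["cn"] = round_half_away(counts / best["x"])
    sol = PloidySolution(
        x_min=best["x"],
        chi_curve=np.column_stack([xs, curve]),
        ploidy=best["ploidy"],
        ploidy_confidence=float(confidence),
        reliable=bool(confidence >= PLOIDY_CONFIDENCE_RELIABLE),
        candidates=candidates,
    )
    return out, sol


class NoFeasiblePloidyError(ValueError):
    """Raised when no chi minimum yields a ploidy within limits.

    Carries the evaluated chi curve for inspection."""

    def __init__(self, message, solution: PloidySolution):
        super().__init__(message)
        self.solution = solution


def call_cell(cell: CellCounts, bins: pd.DataFrame,
              ploidy_limits=(1.0, 8.0), target_ploidy=None,
              seg_method="cbs", seed=0):
    """correct -> segment -> solve, returning (segments, solution)."""
    corrected = correct_counts(cell, bins)
    segs = segment_profile(corrected, bins, method=seg_method, seed=seed)
    return estimate_cn(segs, ploidy_limits=ploidy_limits,
                       target_ploidy=target_ploidy)
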