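"""Cell-cycle staging: S vs G1/G2 calls and the S-progression correction.

Replicating cells have elevated bin-to-bin variability (DIMAPD): adjacent
bins replicate asynchronously, so mid-S cells sit far above the quiet
G1/G2 bulk.  Assuming the majority of cells are G1/G2, a Gaussian is
fitted robustly (median / MAD) to the DIMAPD distribution and cells in
the extreme upper tail are called S phase.  Sorted designs can instead
inject phase labels from metadata, and a manual threshold (with an
optional "unknown" gate) is available for enriched populations.

The integer copy-number solver introduces a two-branch artefact in
S phase: cells early in S are called at a ploidy slightly above the
G1/G2 value, while late-S cells lock onto a doubled reads-per-copy unit
and are called *below* it, approaching the G1/G2 ploidy from the left as
replication completes.  ``correct_s_progression`` rescales the second
branch by a multiplicative factor chosen so that the corrected S ploidy
distribution preferentially reunites into a single mode above the G1/G2
median with maximal spread (interquartile range); when no factor
achieves monomodality the spread is minimised instead (bimodal mode).
The per-cell replication fraction is then
(corrected ploidy - G1/G2 ploidy) / G1/G2 ploidy, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm

from ._utils import check_seed

DEFAULT_ALPHA = 0.01
DEFAULT_RPMB_PER_HAPLOID = 160.0


@dataclass
class PhaseCall:
    cell_id: str
    phase: str              # "S" | "G1G2" | "unknown"
    source: str             # "auto" | "manual" | "metadata"
    dimapd_threshold: float = np.nan


@dataclass
class SCorrection:
    mode: str                       # "monomodal" | "bimodal" | "manual"
    first_branch_shift: float
    second_branch_shift: float
    g1g2_ploidy: float
    corrected_ploidy: pd.Series = field(default=None)
    replication_fraction: pd.Series = field(default=None)
    cell_shifts: pd.Series = field(default=None)  # per-cell multiplier


@dataclass
class CoverageThreshold:
    rpmb_per_haploid: float
    curve: pd.DataFrame | None = None   # (target_rpmb, fraction_within_5pct)


# ---------------------------------------------------------------------------
# phase calling

def call_phase_auto(dimapds, alpha: float = DEFAULT_ALPHA) -> list[PhaseCall]:
    """Label cells with outlying DIMAPD as S phase.

    A Gaussian is fitted robustly to the bulk of the DIMAPD values
    (location = median, scale = 1.4826 * MAD) and cells above the
    one-sided (1 - alpha) quantile are called S.
    """
    dimapds = list(dimapds)
    vals = np.array([d.dimapd for d in dimapds], dtype=float)
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    scale = 1.4826 * mad
    if scale <= 0 or not np.isfinite(scale):
        import warnings
        warnings.warn("degenerate DIMAPD distribution (zero spread); "
                      "no S-phase cells called")
        threshold = np.inf
    else:
        threshold = med + norm.ppf(1 - alpha) * scale
    return [PhaseCall(cell_id=d.cell_id,
                      phase="S" if d.dimapd > threshold else "G1G2",
                      source="auto", dimapd_threshold=float(threshold))
            for d in dimapds]


def call_phase_manual(dimapds, ploidies: pd.Series | None = None,
                      s_threshold: float = np.inf,
                      unknown_gate: tuple | None = None) -> list[PhaseCall]:
    """Threshold DIMAPD by hand; cells inside the unknown gate are
    excluded downstream.

    ``unknown_gate`` is ``(ploidy_min, ploidy_max, dimapd_min,
    dimapd_max)`` in the ploidy-vs-DIMAPD plane (closed box).
    """
    if not np.isfinite(s_threshold):
        raise ValueError("s_threshold must be finite")
    out = []
    for d in dimapds:
        phase = "S" if d.dimapd > s_threshold else "G1G2"
        if unknown_gate is not None and ploidies is not None:
            pmin, pmax, dmin, dmax = unknown_gate
            p = ploidies.get(d.cell_id, np.nan)
            if pmin <= p <= pmax and dmin <= d.dimapd <= dmax:
                phase = "unknown"
        out.append(PhaseCall(cell_id=d.cell_id, phase=phase,
                             source="manual",
                             dimapd_threshold=float(s_threshold)))
    return out


def apply_phase_metadata(cell_ids, metadata: pd.DataFrame):
    """Overwrite phases from a (cell_id, phase) metadata table.

    Returns ``(calls, unmatched_cell_ids)``.  Conflicting duplicate rows
    raise; redundant duplicates are tolerated.
    """
    if metadata.duplicated("cell_id").any():
        dup = metadata[metadata.duplicated("cell_id", keep=False)]
        conflicts = dup.groupby("cell_id")["phase"].nunique()
        bad = conflicts[conflicts > 1].index.tolist()
        if bad:
            raise ValueError(f"conflicting phase metadata for cells: {bad}")
        metadata = metadata.drop_duplicates("cell_id")
    lookup = dict(zip(metadata.cell_id, metadata.phase))
    calls, unmatched = [], []
    for cid in cell_ids:
        if cid in lookup:
            phase = str(lookup[cid])
            if phase not in ("S", "G1G2", "unknown"):
                raise ValueError(f"unknown phase label {phase!r} for {cid}")
            calls.append(PhaseCall(cell_id=cid, phase=phase,
                                   source="metadata"))
        else:
            unmatched.append(cid)
    return calls, unmatched


# ---------------------------------------------------------------------------
# S-progression correction

def _n_modes(values, valley_frac: float = 0.75) -> int:
    """Count well-separated modes of a Gaussian KDE.

    Two local maxima only count as distinct modes when the valley
    between them drops below ``valley_frac`` of the lower peak;
    small ripples on a broad hump are not modes."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or np.ptp(values) == 0:
        return 1
    try:
        kde = gaussian_kde(values)     # Scott bandwidth
    except np.linalg.LinAlgError:
        return 1
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 256)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = [i + 1 for i in np.nonzero(interior)[0]
             if dens[i + 1] > 0.05 * dens.max()]
    if len(peaks) <= 1:
        return 1
    modes = 1
    for a, b in zip(peaks[:-1], peaks[1:]):
        valley = dens[a:b + 1].min()
        if valley < valley_frac * min(dens[a], dens[b]):
            modes += 1
    return modes


def correct_s_progression(s_ploidies: pd.Series, g_ploidies: pd.Series,
                          first_branch_shift: float | None = None,
                          second_branch_shift: float | None = None,
                          shift_grid=None) -> SCorrection:
    """Rescale the second S-phase branch back above the G1/G2 ploidy.

    Cells with ploidy below the G1/G2 median form the second branch.
    Unless shifts are given manually, the second-branch multiplier is
    searched over a grid; feasible candidates (all corrected S ploidies
    at or above the G1/G2 median) that yield a monomodal corrected
    distribution are ranked by descending interquartile range, with a
    bimodal minimum-spread fallback.
    """
    if len(s_ploidies) == 0 or len(g_ploidies) == 0:
        raise ValueError("both S and G1/G2 populations are required")
    pg = float(np.median(g_ploidies))
    branch2 = s_ploidies < pg
    s1 = first_branch_shift if first_branch_shift is not None else 1.0

    manual = (first_branch_shift is not None
              or second_branch_shift is not None)
    if second_branch_shift is not None:
        s2, mode = float(second_branch_shift), "manual"
    elif not branch2.any():
        s2, mode = 1.0, "monomodal"   # identity correction
    else:
        if shift_grid is None:
            shift_grid = np.arange(1.0, 3.0001, 0.01)
        best = None
        for cand in shift_grid:
            corr = pd.concat([s_ploidies[~branch2] * s1,
                              s_ploidies[branch2] * cand])
            feasible = corr.min() >= pg * (1 - 1e-9)
            if not feasible:
                continue
            iqr = float(np.subtract(*np.percentile(corr, [75, 25])))
            mono = _n_modes(corr.to_numpy()) == 1
            key = (0, -iqr) if mono else (1, iqr)
            if best is None or key < best[0]:
                best = (key, float(cand), mono)
        if best is None:
            # nothing feasible on the grid; push the branch just past pg
            s2 = float(pg / s_ploidies[branch2].min())
            mode = "bimodal"
        else:
            _, s2, mono = best
            mode = "monomodal" if mono else "bimodal"
    if manual:
        mode = "manual"

    shifts = pd.Series(np.where(branch2, s2, s1), index=s_ploidies.index)
    corrected = s_ploidies.astype(float) * shifts
    frac = ((corrected - pg) / pg).clip(lower=0.0, upper=1.0)
    return SCorrection(mode=mode, first_branch_shift=float(s1),
                       second_branch_shift=float(s2), g1g2_ploidy=pg,
                       corrected_ploidy=corrected,
                       replication_fraction=frac,
                       cell_shifts=shifts)


def apply_shift_to_segments(segments: pd.DataFrame, shift: float,
                            x_min: float | None = None) -> pd.DataFrame:
    """Re-derive a cell's segment copy numbers at the corrected unit.

    Second-branch S cells were solved at a doubled reads-per-copy unit,
    which both halves their ploidy and collapses odd copy numbers onto
    half-integers before rounding.  Given the solver's ``x_min`` the
    copy numbers are re-rounded from the segment counts at the
    corrected unit ``x_min / h``, restoring the doubled dose on
    replicated regions; without it the integer CNs are simply rescaled.
    Because the branch artefact is a unit locked onto an integer
    multiple of the true reads-per-copy value, ``h`` is the fitted
    shift snapped to its nearest integer harmonic — the solver's own
    ``x_min`` then self-calibrates the correction, insulating the copy
    numbers from small errors in the fitted shift.
    """
    from ._utils import round_half_away
    out = segments.copy()
    if x_min is not None and np.isfinite(x_min) and x_min > 0:
        h = max(round(float(shift)), 1)
        out["cn"] = round_half_away(
            out.mean_count.to_numpy(dtype=float) * h / x_min)
    else:
        out["cn"] = out.cn.astype(float) * float(shift)
    return out


# ---------------------------------------------------------------------------
# coverage threshold by down-sampling

def flag_mis_unit_cells(ncn: "pd.DataFrame", threshold: float = 0.5,
                        margin: float = 1.5,
                        min_frac: float = 0.05) -> list:
    """Find S cells normalised at the wrong (half) reads-per-copy unit.

    A genuinely early cell deviates from the G1/G2 reference upward
    (replicated bins near +1); a dose-complete cell whose solver unit
    locked onto the doubled value deviates downward (its unreplicated
    bins sit at half the reference, near -1).  Cells whose mass below
    ``-threshold`` exceeds ``margin`` times the mass above
    ``+threshold`` (and at least ``min_frac`` of defined bins) need
    their unit doubled; the ploidy-median branch rule misses them when
    their called ploidy lands marginally above the G1/G2 median.
    """
    neg = (ncn < -threshold).sum(axis=1)
    pos = (ncn > threshold).sum(axis=1)
    n = ncn.notna().sum(axis=1).clip(lower=1)
    flagged = (neg > margin * pos) & (neg / n > min_frac)
    return list(ncn.index[flagged])


def downsample_counts(raw: np.ndarray, n_target: int, rng) -> np.ndarray:
    """Subsample reads without replacement across bins."""
    raw = np.asarray(raw, dtype=np.int64)
    total = int(raw.sum())
    if n_target >= total:
        return raw.copy()
    return rng.multivariate_hypergeometric(raw, n_target,
                                           method="marginals")


def coverage_threshold_by_downsampling(
        cells, bins, target_rpmbs=None, n_reps: int = 3, seed=0,
        ploidy_limits=(1.0, 8.0), within: float = 0.05,
        min_fraction: float = 0.75) -> CoverageThreshold:
    """Find the coverage at which ploidy estimation remains stable.

    Reads of each (high-coverage) cell are subsampled without
    replacement to each target RPMb and the ploidy is re-estimated; the
    threshold is the smallest target at which at least
    ``min_fraction`` (75%) of cells stay within ``within`` (5%) of
    their full-coverage ploidy.  Without down-sampling data the default
    of 160 RPMb per haploid genome applies.
    """
    from . import cnv as _cnv

    if not cells or target_rpmbs is None or len(list(target_rpmbs)) == 0:
        return CoverageThreshold(rpmb_per_haploid=DEFAULT_RPMB_PER_HAPLOID,
                                 curve=None)
    rng = check_seed(seed)
    cells = list(cells)
    usable_mb = float((bins.end - bins.start)[bins.usable].sum()) / 1e6
    originals = {}
    for cell in cells:
        _segs, sol = _cnv.call_cell(cell, bins,
                                    ploidy_limits=ploidy_limits)
        originals[cell.cell_id] = sol.ploidy
    rows = []
    for target in sorted(target_rpmbs):
        n_target = int(round(target * usable_mb))
        ok = 0
        n_eval = 0
        for cell in cells:
            if cell.rpmb < target:
                continue
            within_reps = []
            for _ in range(n_reps):
                sub = downsample_counts(cell.raw, n_target, rng)
                c = _cnv.cell_from_counts(cell.cell_id, sub, bins)
                try:
                    _s, sol = _cnv.call_cell(c, bins,
                                             ploidy_limits=ploidy_limits)
                    dev = abs(sol.ploidy - originals[cell.cell_id]) \
                        / originals[cell.cell_id]
                    within_reps.append(dev <= within)
                except _cnv.NoFeasiblePloidyError:
                    within_reps.append(False)
            n_eval += 1
            if within_reps and np.mean(within_reps) >= 0.5:
                ok += 1
        frac = ok / n_eval if n_eval else np.nan
        rows.append({"target_rpmb": float(target),
                     "fraction_within_5pct": frac})
    curve = pd.DataFrame(rows)
    passing = curve[curve.fraction_within_5pct >= min_fraction]
    if passing.empty:
        rpmb = float(curve.target_rpmb.max())
    else:
        rpmb = float(passing.target_rpmb.min())
    med_ploidy = float(np.median(list(originals.values())))
    return CoverageThreshold(rpmb_per_haploid=rpmb / med_ploidy, curve=curve)


def rpmb_per_haploid(rpmb: float, ploidy: float) -> int:
    """Reads per Mb per haploid genome, integer-rounded."""
    return int(round(rpmb / ploidy))
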