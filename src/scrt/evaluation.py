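"""Reproducibility harness: benchmark quantities the package recomputes.

Every function here rebuilds its inputs from the simulator (or from
closed-form constructions), runs the relevant part of the analysis and
returns measured quantities; nothing is cached or hard-coded.  The
test-suite asserts tolerances on these numbers and the acceptance
script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import cnv, rt, staging, synth
from . import heterogeneity as het
from . import variability as var
from .bins import make_bins


# ---------------------------------------------------------------------------
# closed-form / in-text arithmetic

def ploidy_of_80_autosomes() -> float:
    """Mean ploidy of a karyotype carrying 80 autosomes over 22 types."""
    segs = pd.DataFrame({
        "chrom": [f"chr{i}" for i in range(22)],
        "start": 0, "end": 1, "n_bins": 1, "mean_count": 1.0,
        "size": 1.0, "cn": [4] * 14 + [3] * 8})
    assert segs.cn.sum() == 80
    return cnv.mean_ploidy(segs)


def rpmb_per_haploid_425_at_364() -> int:
    """Coverage threshold in reads/Mb per haploid genome."""
    return staging.rpmb_per_haploid(425, 3.64)


def default_coverage_threshold() -> float:
    """Fallback threshold when no down-sampling has been run."""
    return staging.coverage_threshold_by_downsampling(
        [], None).rpmb_per_haploid


def min_reads_boundary() -> dict:
    """Partition behaviour at the read-count filter boundary."""
    cells = [cnv.CellCounts("low", np.array([1]), total_reads=199_999),
             cnv.CellCounts("ok", np.array([1]), total_reads=200_000)]
    kept, discarded = cnv.filter_low_coverage(cells)
    return {"kept_at_200000": int(len(kept)),
            "discarded_below": int(len(discarded))}


# ---------------------------------------------------------------------------
# oracle-equivalence gaps

def binarization_oracle_gap(seed, n_cells: int = 100,
                            n_bins: int = 500) -> float:
    """Max |loss(module) - loss(1e-3 exhaustive grid)| over random cells.

    Cells are drawn from the bimodal nCN mixture the normalisation
    actually produces (unreplicated mass near 0, replicated near 1).
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, 1001)
    worst = 0.0
    for _ in range(n_cells):
        frac = rng.uniform(0.1, 0.9)
        n1 = int(frac * n_bins)
        v = np.concatenate([rng.normal(0.0, 0.15, n_bins - n1),
                            rng.normal(1.0, 0.15, n1)])
        row = pd.Series(v)
        _b, _th, eps = rt.binarize(row)
        losses = np.where(v[None, :] >= grid[:, None],
                          (v[None, :] - 1.0) ** 2,
                          v[None, :] ** 2).sum(axis=1)
        worst = max(worst, abs(eps - losses.min()))
    return float(worst)


def chi_oracle_gap(seed, n_sets: int = 10) -> float:
    """Max excess of the solver's chi over a 40k-point dense grid."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_sets):
        cns = rng.integers(1, 6, size=15)
        counts = cns * 60.0 + rng.normal(0, 1.5, 15)
        sizes = rng.uniform(1, 5, 15)
        segs = pd.DataFrame({"chrom": "c", "start": 0, "end": 1,
                             "n_bins": 1, "mean_count": counts,
                             "size": sizes, "cn": np.nan})
        _s, sol = cnv.estimate_cn(segs, ploidy_limits=(0.5, 10.0))
        lo = np.percentile(counts, 5, method="lower")
        hi = np.percentile(counts, 95, method="higher")
        xs = np.linspace(lo, hi, 40_000)
        curve = np.atleast_1d(cnv.chi(xs, counts, sizes))
        got = float(np.atleast_1d(cnv.chi(np.array([sol.x_min]),
                                          counts, sizes))[0])
        worst = max(worst, got - float(curve.min()))
    return float(worst)


def dimapd_bruteforce_gap() -> float:
    """|module MAPDC - literal evaluation| on a toy 500-kb vector."""
    per500 = np.array([100, 200, 100, 200])
    raw = np.repeat(per500 // 25, 25)
    starts = np.arange(100) * 20_000
    bins = pd.DataFrame({"chrom": "chr1", "start": starts,
                         "end": starts + 20_000, "gc": 0.45,
                         "mappability": 1.0, "blacklisted": False,
                         "is_remainder": False, "usable": True})
    cells = [cnv.cell_from_counts("a", raw, bins),
             cnv.cell_from_counts("b", np.full(100, 6), bins)]
    recs = cnv.compute_dimapd(cells, bins)
    gmb = 2.0
    r = per500.astype(float)
    d = (r[:-1] - r[1:]) / r.mean()
    expected = np.median(np.abs(d - np.median(d))) * np.sqrt(r.sum() / gmb)
    return float(abs(recs[0].mapd_c - expected))


# ---------------------------------------------------------------------------
# T_width closed forms and the bootstrap

def _front_population(rng, kind, n_cells, n_bins=200, scale=1.0):
    t = rng.uniform(0, 1, n_cells)
    if kind == "linear":
        p = t
    else:
        p = 1.0 / (1.0 + np.exp(-(t * 10 - 5) / scale))
    rows = (np.arange(n_bins)[None, :] < (p * n_bins)[:, None])
    scrt = pd.DataFrame(rows.astype(float),
                        index=[f"c{i}" for i in range(n_cells)])
    scrt.columns = [f"b{j}" for j in range(n_bins)]
    return scrt, pd.Series(t, index=scrt.index)


def twidth_closed_forms(seed, n_cells: int = 10_000) -> dict:
    """Estimated vs analytic T_width for reference replication fronts."""
    rng = np.random.default_rng(seed)
    scrt, pct = _front_population(rng, "linear", n_cells)
    linear = var.twidth(scrt, pct, list(scrt.columns)).t_width
    scrt, pct = _front_population(rng, "logistic", n_cells, scale=1.0)
    logistic = var.twidth(scrt, pct, list(scrt.columns)).t_width
    return {"linear_h": float(linear), "linear_expected_h": 5.0,
            "logistic_h": float(logistic),
            "logistic_expected_h": float(2 * np.log(3))}


def compare_tw_null(seed, n_meta: int = 20, n_iter: int = 500) -> dict:
    """Bootstrap calibration under the null: random splits of
    homogeneous bins should rarely give small p."""
    rng = np.random.default_rng(seed)
    scrt, pct = _front_population(rng, "logistic", 500, n_bins=40)
    noisy = scrt.to_numpy().copy()
    flip = rng.random(noisy.shape) < 0.1
    noisy[flip] = 1 - noisy[flip]
    scrt = pd.DataFrame(noisy, index=scrt.index, columns=scrt.columns)
    ps = []
    for rep in range(n_meta):
        cols = rng.permutation(scrt.columns)
        res = var.compare_tw(scrt, pct, list(cols[:20]), list(cols[20:]),
                             n_iter=n_iter, seed=int(rng.integers(2**31)))
        ps.append(res.p)
    ps = np.array(ps)
    return {"fraction_p_ge_05": float(np.mean(ps >= 0.05)),
            "min_p": float(ps.min())}


def compare_tw_power(seed, n_iter: int = 10_000) -> dict:
    """Power: 1-h vs 5-h T_width fronts, 50 bins per group."""
    rng = np.random.default_rng(seed)
    n_cells = 1500
    t = rng.uniform(0, 1, n_cells)
    s_tight = 1.0 / (2 * np.log(3))
    s_wide = 5.0 / (2 * np.log(3))
    pa = 1 / (1 + np.exp(-(t * 10 - 5) / s_tight))
    pb = 1 / (1 + np.exp(-(t * 10 - 5) / s_wide))
    a = rng.random((n_cells, 50)) < pa[:, None]
    b = rng.random((n_cells, 50)) < pb[:, None]
    scrt = pd.DataFrame(np.hstack([a, b]).astype(float),
                        index=[f"c{i}" for i in range(n_cells)])
    scrt.columns = [f"x{j}" for j in range(100)]
    pct = pd.Series(t, index=scrt.index)
    res = var.compare_tw(scrt, pct, list(scrt.columns[:50]),
                         list(scrt.columns[50:]), n_iter=n_iter,
                         seed=int(seed))
    return {"p": res.p, "t_width_tight_h": res.t_width_a,
            "t_width_wide_h": res.t_width_b}


# ---------------------------------------------------------------------------
# end-to-end synthetic recovery

def _two_clone_model(ectopic_rate, seed):
    rt_bins = make_bins(list(synth.DEFAULT_CHROMS), bin_size=200_000,
                        include_sex=True)
    p1 = synth.default_clone_profile(rt_bins)
    p2 = synth.with_chrom_gain(p1, rt_bins, "chr3")
    return synth.TruthModel(ectopic_rate=ectopic_rate,
                            clones=[(0.5, p1), (0.5, p2)],
                            seed=int(seed)), rt_bins


def run_recovery(seed, n_cells: int = 300, ectopic_rate: float = 0.03,
                 embed: bool = False,
                 ploidy_limits=(1.5, 8.0)) -> dict:
    """Full-chain recovery on a two-clone stochastic population.

    The automatic DIMAPD classifier stages the cells (scored against
    truth as precision/recall/F1) and the scRT chain runs on the cells
    it calls — the asynchronous-population workflow.  This matters for
    the stochasticity metrics: S cells that have essentially completed
    replication are solved at the G1/G2 dose, would enter the early
    stage gate with empty profiles, and are exactly the cells the
    classifier (correctly, by dose) leaves in the G1/G2 pool.  Clone
    labels come from the simulator, standing in for manual embedding
    gates.
    """
    model, rt_bins = _two_clone_model(ectopic_rate, seed)
    sim = synth.simulate_population(model, n_cells)
    truth = sim.truth

    cells = {c: cnv.cell_from_counts(c, sim.counts.loc[c].to_numpy(),
                                     sim.bins) for c in sim.counts.index}
    dim = cnv.compute_dimapd(cells.values(), sim.bins)
    calls = staging.call_phase_auto(dim)
    pred = pd.Series({c.cell_id: c.phase for c in calls})
    truth_s = truth.phase == "S"
    pred_s = pred.loc[truth.index] == "S"
    tp = int((truth_s & pred_s).sum())
    fp = int((~truth_s & pred_s).sum())
    fn = int((truth_s & ~pred_s).sum())
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)

    segs_all, sols = {}, {}
    for cid, cell in cells.items():
        segs, sol = cnv.call_cell(cell, sim.bins,
                                  ploidy_limits=ploidy_limits)
        segs_all[cid] = segs
        sols[cid] = sol
    ploidy = pd.Series({c: s.ploidy for c, s in sols.items()})
    g_ids = truth.index[truth.phase == "G1G2"]
    g_err = ((ploidy[g_ids] - truth.true_base_ploidy[g_ids]).abs()
             / truth.true_base_ploidy[g_ids])

    s_cells = list(pred.index[pred == "S"])
    g_cells = list(pred.index[pred == "G1G2"])
    corr = staging.correct_s_progression(ploidy[s_cells],
                                         ploidy[g_cells])
    shifts = corr.cell_shifts.copy()
    groups = truth.clone.astype(str)
    cn200_g = rt.cn200_matrix({c: segs_all[c] for c in g_cells}, rt_bins)
    for _ in range(2):
        s_segs = {c: staging.apply_shift_to_segments(
            segs_all[c], shifts[c], x_min=sols[c].x_min)
            for c in s_cells}
        cn200_s = rt.cn200_matrix(s_segs, rt_bins)
        rtm = rt.build_rt_matrix(cn200_s, cn200_g, groups=groups)
        flagged = staging.flag_mis_unit_cells(rtm.ncn)
        if not flagged:
            break
        shifts.loc[flagged] = shifts.loc[flagged] * 2.0
    rtm, dropped = rt.smc_filter(rtm, pct_window=0.1)
    track, n_used = rt.pseudo_bulk(rtm)
    rho = spearmanr(track, sim.rt_track_truth.loc[track.index],
                    nan_policy="omit")[0]
    oos = het.out_of_schedule(rtm.scrt, rtm.replication_pct, track)

    out = {
        "phase_f1": float(f1),
        "phase_precision": float(precision),
        "phase_recall": float(recall),
        "g1g2_ploidy_error_pct": float(100 * g_err.median()),
        "pseudobulk_truth_spearman": float(rho),
        "ectopic_rate_injected_pct": float(100 * ectopic_rate),
        "early_event_rate_pct": float(100 * oos.early_event_rate),
        "late_event_rate_pct": float(100 * oos.late_event_rate),
        "n_cells": int(n_cells),
        "n_s_cells": int(len(s_cells)),
        "n_pseudobulk_cells": int(n_used),
    }
    if embed:
        from sklearn.metrics import silhouette_score
        emb = het.embed_cells(pd.concat([cn200_s, cn200_g]),
                              method="umap", kind="cnv",
                              seed=int(seed))
        labels = (truth.loc[emb.index].clone.astype(str) + "_"
                  + truth.loc[emb.index].phase)
        out["embedding_four_group_silhouette"] = float(
            silhouette_score(emb[["x", "y"]].to_numpy(),
                             labels.to_numpy()))
        g_emb = emb.loc[g_cells]
        out["embedding_clone_silhouette_g1g2"] = float(
            silhouette_score(g_emb[["x", "y"]].to_numpy(),
                             truth.loc[g_cells].clone.to_numpy()))
    return out
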