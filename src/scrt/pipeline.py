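"""End-to-end orchestration: counts -> CNV -> staging -> scRT -> RT track.

``run_pipeline`` consumes a bin annotation and a cells x bins count
matrix (both TSV), runs every enabled stage in pipeline order and writes
the artefacts plus a provenance record (config, seeds, package version)
into the output directory.  Reruns with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cnv, io, rt, staging
from . import heterogeneity as het
from . import variability as var


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the published defaults."""
    bins_path: str = ""
    counts_path: str = ""
    output_dir: str = "scrt_out"
    phase_metadata_path: str | None = None

    min_reads: int = cnv.DEFAULT_MIN_READS
    mapq_min: int = cnv.DEFAULT_MAPQ_MIN
    dimapd_alpha: float = staging.DEFAULT_ALPHA
    dimapd_threshold: float | None = None     # manual override
    # lower limit 1.5 rejects the degenerate half-unit solutions the
    # solver otherwise reaches for near-uniform profiles; adjust per
    # dataset (e.g. raise for strongly aneuploid lines)
    ploidy_limits: tuple = (1.5, 8.0)
    target_ploidy: float | None = None
    rt_bin_size: int = rt.DEFAULT_RT_BIN_SIZE
    interval_width: float = 0.025
    s_length_h: float = var.DEFAULT_S_LENGTH_H
    stage_gates: dict = field(default_factory=lambda: dict(
        het.STAGE_GATES))
    seed: int = 0

    do_variability: bool = True
    do_stochasticity: bool = True
    do_embedding: bool = False      # optional: pulls in umap/tsne cost

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["stage_gates"] = {k: list(v) for k, v in d["stage_gates"].items()}
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offenders."""

    def __init__(self, stage, message, offenders=None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.offenders = offenders or []


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    bins = io.read_bins(config.bins_path)
    counts = io.read_counts(config.counts_path)
    if len(counts.columns) != len(bins):
        raise StageError("input", "count matrix does not match bin table")

    # --- CNV calling ------------------------------------------------------
    cells = [cnv.cell_from_counts(cid, counts.loc[cid].to_numpy(), bins)
             for cid in counts.index]
    kept, discarded = cnv.filter_low_coverage(cells, config.min_reads)
    if not kept:
        raise StageError("cnv", "no cells pass the read-count filter",
                         [c.cell_id for c in discarded])
    if len(kept) < 2:
        raise StageError("cnv", "need >= 2 cells for DIMAPD")
    dimapds = cnv.compute_dimapd(kept, bins)

    seg_tables, qc_rows, x_mins = {}, [], {}
    dim_by_cell = {d.cell_id: d for d in dimapds}
    for cell in kept:
        try:
            segs, sol = cnv.call_cell(cell, bins,
                                      ploidy_limits=config.ploidy_limits,
                                      target_ploidy=config.target_ploidy,
                                      seed=config.seed)
        except cnv.NoFeasiblePloidyError as exc:
            raise StageError("cnv", f"ploidy solving failed for "
                             f"{cell.cell_id}: {exc}", [cell.cell_id])
        seg_tables[cell.cell_id] = segs
        x_mins[cell.cell_id] = sol.x_min
        qc_rows.append({
            "cell_id": cell.cell_id,
            "total_reads": cell.total_reads,
            "rpmb": cell.rpmb,
            "dimapd": dim_by_cell[cell.cell_id].dimapd,
            "ploidy": sol.ploidy,
            "ploidy_confidence": sol.ploidy_confidence,
        })
    qc = pd.DataFrame(qc_rows).set_index("cell_id", drop=False)
    qc.to_csv(out / "per_cell_qc.tsv", sep="\t", index=False,
              float_format="%.6g")

    # --- staging ----------------------------------------------------------
    if config.phase_metadata_path:
        meta = io.read_phase_metadata(config.phase_metadata_path)
        calls, unmatched = staging.apply_phase_metadata(list(qc.cell_id),
                                                        meta)
        if unmatched:
            raise StageError("whoiswho",
                             "cells missing from phase metadata", unmatched)
    elif config.dimapd_threshold is not None:
        calls = staging.call_phase_manual(
            dimapds, qc.ploidy, s_threshold=config.dimapd_threshold)
    else:
        calls = staging.call_phase_auto(dimapds,
                                        alpha=config.dimapd_alpha)
    phase = pd.Series({c.cell_id: c.phase for c in calls})
    s_cells = phase.index[phase == "S"]
    g_cells = phase.index[phase == "G1G2"]
    if len(s_cells) == 0 or len(g_cells) == 0:
        raise StageError("diagnostic", "need both S and G1/G2 cells "
                         f"(got {len(s_cells)} S, {len(g_cells)} G1/G2)")
    corr = staging.correct_s_progression(qc.ploidy.loc[s_cells],
                                         qc.ploidy.loc[g_cells])
    diag = phase.to_frame("phase")
    diag["ploidy"] = qc.ploidy
    diag.loc[s_cells, "corrected_ploidy"] = corr.corrected_ploidy
    diag.loc[s_cells, "replication_fraction"] = corr.replication_fraction
    diag.to_csv(out / "phases.tsv", sep="\t", index_label="cell_id",
                float_format="%.6g")

    # --- scRT -------------------------------------------------------------
    lengths = rt.chrom_lengths_from_bins(bins)
    rt_bins = rt.make_rt_bins(lengths, config.rt_bin_size)
    cn200_g = rt.cn200_matrix({c: seg_tables[c] for c in g_cells}, rt_bins)
    shifts = corr.cell_shifts.copy()
    for _ in range(2):
        s_segs = {c: staging.apply_shift_to_segments(seg_tables[c],
                                                     shifts[c],
                                                     x_min=x_mins[c])
                  for c in s_cells}
        cn200_s = rt.cn200_matrix(s_segs, rt_bins)
        rtm = rt.build_rt_matrix(cn200_s, cn200_g)
        # dose-complete cells missed by the ploidy-median branch rule
        # show up with predominantly negative normalised profiles;
        # double their unit and rebuild
        flagged = staging.flag_mis_unit_cells(rtm.ncn)
        if not flagged:
            break
        shifts.loc[flagged] = shifts.loc[flagged] * 2.0
    rtm, dropped = rt.smc_filter(rtm, pct_window=0.1)
    if len(rtm.scrt) < 2:
        raise StageError("rt", "fewer than 2 cells survive SMC filtering",
                         dropped)
    track, n_used = rt.pseudo_bulk(rtm,
                                   interval_width=config.interval_width)
    io.write_matrix(rtm.scrt, out / "scrt_matrix.tsv")
    io.write_bedgraph(track, out / "pseudobulk_rt.bedGraph")

    report = {
        "n_cells": len(cells),
        "n_discarded_low_coverage": len(discarded),
        "n_s_cells": int(len(s_cells)),
        "n_g1g2_cells": int(len(g_cells)),
        "n_smc_dropped": len(dropped),
        "n_cells_pseudobulk": n_used,
        "s_correction_mode": corr.mode,
        "second_branch_shift": corr.second_branch_shift,
    }

    # --- optional analyses ------------------------------------------------
    if config.do_variability:
        cats = var.categorize_bins(track, var.RT_CATEGORIES_2)
        if cats["early"] and cats["late"]:
            cmp_res = var.compare_tw(rtm.scrt, rtm.replication_pct,
                                     cats["early"], cats["late"],
                                     seed=config.seed,
                                     s_length_h=config.s_length_h,
                                     names=("early", "late"))
            report["twidth_early_h"] = cmp_res.t_width_a
            report["twidth_late_h"] = cmp_res.t_width_b
            report["twidth_p"] = cmp_res.p

    if config.do_stochasticity:
        try:
            oos = het.out_of_schedule(rtm.scrt, rtm.replication_pct,
                                      track, config.stage_gates)
            oos.per_cell.to_csv(out / "out_of_schedule.tsv", sep="\t",
                                index=False, float_format="%.6g")
            report["early_event_rate"] = oos.early_event_rate
            report["late_event_rate"] = oos.late_event_rate
            ipls = het.extract_ipls(rtm.scrt, rtm.replication_pct,
                                    config.stage_gates)
            io.write_bedgraph(ipls, out / "ipls.bedGraph")
        except ValueError:
            report["stochasticity"] = "skipped: empty stage gates"

    if config.do_embedding:
        emb = het.embed_cells(pd.concat([cn200_s, cn200_g]),
                              method="umap", kind="cnv",
                              seed=config.seed)
        emb.to_csv(out / "embedding.tsv", sep="\t",
                   index_label="cell_id", float_format="%.6g")

    io.write_json({"config": config.to_dict(), "version": __version__,
                   "report": report}, out / "run_report.json")
    return out
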