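"""Shared fixtures: small ground-truthed populations and helpers.

Everything is generated programmatically and seeded; the "chain"
fixtures run the full analysis once per session so the many assertions
about its outputs stay cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scrt import cnv, rt, staging, synth


SMALL_CHROMS = (("chr1", 20_000_000), ("chr2", 20_000_000),
                ("chr3", 20_000_000))


def make_uniform_bins(n_bins=60, width=20_000, chrom="chr1",
                      gc=0.45, mappability=1.0):
    """A single-chromosome usable bin table for unit tests."""
    starts = np.arange(n_bins) * width
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + width,
        "gc": gc, "mappability": mappability,
        "blacklisted": False, "is_remainder": False, "usable": True,
    })


@pytest.fixture(scope="session")
def small_sim():
    """~140-cell S-phase-enriched population on a 60-Mb toy genome."""
    model = synth.TruthModel(chrom_lengths=SMALL_CHROMS, s_frac=0.4,
                             ectopic_rate=0.02, seed=11)
    return synth.simulate_population(model, 140)


class Chain:
    """Container for the products of a full analysis run."""

    def __init__(self, sim, ploidy_limits=(1.5, 8.0)):
        self.sim = sim
        truth = sim.truth
        self.truth = truth
        cells = {c: cnv.cell_from_counts(c, sim.counts.loc[c].to_numpy(),
                                         sim.bins)
                 for c in sim.counts.index}
        self.cells = cells
        self.dimapds = cnv.compute_dimapd(cells.values(), sim.bins)
        self.segs, self.sols = {}, {}
        for cid, cell in cells.items():
            segs, sol = cnv.call_cell(cell, sim.bins,
                                      ploidy_limits=ploidy_limits)
            self.segs[cid] = segs
            self.sols[cid] = sol
        self.ploidy = pd.Series({c: s.ploidy for c, s in self.sols.items()})
        # truth-labelled staging (the FACS-metadata route) so RT-level
        # assertions are not confounded by phase-calling errors
        self.s_cells = list(truth.index[truth.phase == "S"])
        self.g_cells = list(truth.index[truth.phase == "G1G2"])
        self.correction = staging.correct_s_progression(
            self.ploidy[self.s_cells], self.ploidy[self.g_cells])
        self.rt_bins = rt.make_rt_bins(
            rt.chrom_lengths_from_bins(sim.bins))
        s_segs = {c: staging.apply_shift_to_segments(
            self.segs[c], self.correction.cell_shifts[c],
            x_min=self.sols[c].x_min) for c in self.s_cells}
        self.cn200_s = rt.cn200_matrix(s_segs, self.rt_bins)
        self.cn200_g = rt.cn200_matrix(
            {c: self.segs[c] for c in self.g_cells}, self.rt_bins)
        groups = truth.clone.astype(str)
        self.rtm = rt.build_rt_matrix(self.cn200_s, self.cn200_g,
                                      groups=groups)
        self.rtm, self.smc_dropped = rt.smc_filter(self.rtm,
                                                   pct_window=0.1)
        self.track, self.n_pseudobulk = rt.pseudo_bulk(self.rtm)


@pytest.fixture(scope="session")
def small_chain(small_sim):
    return Chain(small_sim)
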