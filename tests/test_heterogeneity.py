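"""Embeddings, gating, stage-resolved probabilities and out-of-schedule
events."""

import numpy as np
import pandas as pd
import pytest

from scrt import heterogeneity as het
from scrt.rt import RTMatrix


def _mask_matrix(sim):
    """Ground-truth binary masks of the S cells as an scRT matrix."""
    s_cells = sim.truth.index[sim.truth.phase == "S"]
    scrt = sim.replicated.loc[s_cells].astype(float)
    pct = scrt.mean(axis=1)
    return scrt, pct


class TestEmbedding:
    def _two_clones(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        base = np.full(120, 2.0)
        gained = base.copy()
        gained[:40] = 3.0                  # disjoint CNV on one chromosome
        rows = [base + rng.normal(0, 0.05, 120) for _ in range(n // 2)]
        rows += [gained + rng.normal(0, 0.05, 120) for _ in range(n // 2)]
        return pd.DataFrame(rows, index=[f"c{i}" for i in range(n)])

    def test_clones_separate_with_high_silhouette(self):
        from sklearn.metrics import silhouette_score
        mat = self._two_clones()
        emb = het.embed_cells(mat, method="umap", kind="cnv", seed=3)
        labels = [0] * 20 + [1] * 20
        assert silhouette_score(emb.to_numpy(), labels) > 0.5

    def test_identical_cells_collapse(self):
        mat = pd.DataFrame(np.tile(np.full(50, 2.0), (15, 1)),
                           index=[f"c{i}" for i in range(15)])
        emb = het.embed_cells(mat, method="tsne", seed=1, n_iter=260)
        spread = emb.to_numpy().std(axis=0).max()
        # all points coincide up to embedding jitter
        assert spread < 50  # t-SNE scale units; no structure to spread

    def test_deterministic_given_seed(self):
        mat = self._two_clones(seed=5)
        e1 = het.embed_cells(mat, method="tsne", seed=42, n_iter=260)
        e2 = het.embed_cells(mat, method="tsne", seed=42, n_iter=260)
        assert np.array_equal(e1.to_numpy(), e2.to_numpy())

    def test_seed_required_and_min_cells(self):
        mat = self._two_clones()
        with pytest.raises(ValueError, match="seed"):
            het.embed_cells(mat, method="umap")
        with pytest.raises(ValueError, match="10 cells"):
            het.embed_cells(mat.iloc[:5], method="umap", seed=0)


class TestGating:
    def _embedding(self):
        pts = [(0, 0), (1, 0), (5, 5), (6, 5), (10, 0)]
        return pd.DataFrame(pts, columns=["x", "y"],
                            index=[f"c{i}" for i in range(5)])

    def test_gate_covering_all_single_label(self):
        labels = het.gate_subpopulations(
            self._embedding(), {"all": (-1, 11, -1, 6)})
        assert set(labels) == {"all"}

    def test_disjoint_gates_partition(self):
        labels = het.gate_subpopulations(
            self._embedding(),
            {"left": (-1, 2, -1, 1), "mid": (4, 7, 4, 6)})
        assert labels.tolist() == ["left", "left", "mid", "mid", "none"]

    def test_boundary_point_inside_closed_gate(self):
        labels = het.gate_subpopulations(
            self._embedding(), {"g": (0, 1, 0, 0)})
        assert labels.tolist() == ["g", "g", "none", "none", "none"]

    def test_polygon_gate(self):
        poly = [(4, 4), (7, 4), (7, 6), (4, 6)]
        labels = het.gate_subpopulations(self._embedding(), {"p": poly})
        assert labels.tolist() == ["none", "none", "p", "p", "none"]

    def test_stable_under_point_order(self):
        emb = self._embedding()
        gates = {"g": (-1, 2, -1, 1)}
        l1 = het.gate_subpopulations(emb, gates)
        l2 = het.gate_subpopulations(emb.iloc[::-1], gates)
        assert l1.sort_index().equals(l2.sort_index())


@pytest.fixture(scope="module")
def s_rich_masks():
    """All-S population with plenty of cells per stage gate.

    No out-of-schedule events are injected here: these tests probe
    recovery of the firing-time landscape, and the flat ectopic floor
    (tested separately) only adds rank noise on the late half."""
    from scrt import synth
    model = synth.TruthModel(
        chrom_lengths=(("chr1", 20_000_000), ("chr2", 20_000_000),
                       ("chr3", 20_000_000)),
        s_frac=1.0, ectopic_rate=0.0, seed=19)
    sim = synth.simulate_population(model, 250)
    scrt, pct = _mask_matrix(sim)
    return sim, scrt, pct


@pytest.fixture(scope="module")
def deterministic_masks():
    """No temporal jitter and no ectopic firing: nested fronts."""
    from scrt import synth
    model = synth.TruthModel(
        chrom_lengths=(("chr1", 20_000_000), ("chr2", 20_000_000),
                       ("chr3", 20_000_000)),
        s_frac=1.0, firing_noise=0.0, ectopic_rate=0.0, seed=23)
    sim = synth.simulate_population(model, 120)
    scrt, pct = _mask_matrix(sim)
    return sim, scrt, pct


class TestStageProbability:
    def test_direct_fraction(self):
        scrt = pd.DataFrame(np.zeros((40, 1)),
                            index=[f"c{i}" for i in range(40)],
                            columns=["b"])
        scrt.iloc[:2, 0] = 1.0
        pct = pd.Series(0.1, index=scrt.index)
        sp = het.stage_probability(scrt, pct, "early")
        assert sp.probability["b"] == pytest.approx(0.05)
        assert sp.n_cells == 40

    def test_empty_stage_errors(self):
        scrt = pd.DataFrame(np.zeros((5, 2)),
                            index=[f"c{i}" for i in range(5)])
        pct = pd.Series(0.5, index=scrt.index)
        with pytest.raises(ValueError, match="empty stage"):
            het.stage_probability(scrt, pct, "late")

    def test_probabilities_monotone_across_stages(self,
                                                  deterministic_masks):
        # without temporal noise the fronts are nested, so stage
        # probabilities are monotone at every single bin
        _sim, scrt, pct = deterministic_masks
        early = het.stage_probability(scrt, pct, "early").probability
        mid = het.stage_probability(scrt, pct, "mid").probability
        late = het.stage_probability(scrt, pct, "late").probability
        assert ((mid - early) >= -1e-9).all()
        assert ((late - mid) >= -1e-9).all()

    def test_early_probability_tracks_population_rt(self, s_rich_masks):
        from scipy.stats import spearmanr
        sim, scrt, pct = s_rich_masks
        early = het.stage_probability(scrt, pct, "early").probability
        rho = spearmanr(early, sim.rt_track_truth)[0]
        assert rho >= 0.8


class TestIpls:
    def test_recovers_truth_firing_order(self, s_rich_masks):
        from scipy.stats import spearmanr
        sim, scrt, pct = s_rich_masks
        ipls = het.extract_ipls(scrt, pct)
        assert (ipls.dropna() >= 0).all()
        rho = spearmanr(ipls, 1 - sim.rt_truth)[0]
        assert rho >= 0.9

    def test_no_early_cells_errors(self):
        scrt = pd.DataFrame(np.ones((5, 3)),
                            index=[f"c{i}" for i in range(5)])
        pct = pd.Series(0.9, index=scrt.index)
        with pytest.raises(ValueError):
            het.extract_ipls(scrt, pct)


class TestOutOfSchedule:
    def _deterministic(self, n_cells=30, n_bins=40, seed=0):
        """No stochastic firing: replication front follows the RT rank
        exactly, so out-of-schedule events are structurally absent."""
        rng = np.random.default_rng(seed)
        pct = np.sort(rng.uniform(0.02, 0.98, n_cells))
        order = np.arange(n_bins)            # bin j fires at j/n
        rows = (order[None, :] < (pct[:, None] * n_bins))
        scrt = pd.DataFrame(rows.astype(float),
                            index=[f"c{i}" for i in range(n_cells)])
        scrt.columns = [f"b{j}" for j in range(n_bins)]
        track = pd.Series(1 - order / n_bins, index=scrt.columns)
        return scrt, pd.Series(pct, index=scrt.index), track

    def test_deterministic_truth_has_no_events(self):
        scrt, pct, track = self._deterministic()
        res = het.out_of_schedule(scrt, pct, track)
        assert res.early_event_rate == 0.0
        assert res.late_event_rate == 0.0

    def test_recurrence_counts_distinct_cells(self):
        scrt, pct, track = self._deterministic()
        late_bin = track.index[track < 0.5][-1]
        early_cells = pct.index[pct <= 0.3][:2]
        scrt.loc[early_cells, late_bin] = 1.0
        res = het.out_of_schedule(scrt, pct, track)
        assert res.recurrence[late_bin] == 2

    def test_injected_rate_recovered(self, small_sim):
        # the generator injects 2% fully out-of-schedule firings
        scrt, pct = _mask_matrix(small_sim)
        track = pd.Series(1 - small_sim.rt_truth,
                          index=small_sim.rt_truth.index)
        res = het.out_of_schedule(scrt, pct, track)
        assert res.early_event_rate == pytest.approx(0.02, abs=0.01)

    def test_events_not_clustered_into_large_domains(self, small_sim):
        scrt, pct = _mask_matrix(small_sim)
        track = pd.Series(1 - small_sim.rt_truth,
                          index=small_sim.rt_truth.index)
        res = het.out_of_schedule(scrt, pct, track)
        assert res.run_lengths and np.median(res.run_lengths) <= 2
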