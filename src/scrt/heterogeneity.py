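"""Sub-population discovery and replication stochasticity.

Cells are embedded in 2-D either from their genome-wide copy-number
profiles (raw values) or from binary replication profiles through
pairwise simple-matching-coefficient distances; t-SNE (perplexity =
max(n/50, 10), theta 0.25, 5000 iterations) and UMAP are supported and
every embedding is deterministic given its seed.  Sub-populations are
then gated manually in the embedding (rectangles or polygons, closed
boundaries); automatic clustering is deliberately out of scope.

Stochasticity is quantified stage-wise: cells are gated into early
(<=30% replicated), mid (40-60%) and late (>=70%) S-phase stages and the
per-bin replication probability is computed within each stage.  G1/G2
cells pushed through the same binarization serve as the noise floor.
Out-of-schedule events are bins replicated far ahead of, or behind,
their population RT: late bins (pseudo-bulk RT < 0.5) replicated in
early-stage cells and early bins (RT > 0.5) unreplicated in late-stage
cells.  The early-stage replication probability profile doubles as the
initiation landscape handed to downstream replication simulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGE_GATES = {"early": (0.0, 0.30), "mid": (0.40, 0.60),
               "late": (0.70, 1.0)}


# ---------------------------------------------------------------------------
# embeddings

def embed_cells(matrix: pd.DataFrame, method: str = "umap",
                kind: str = "cnv", seed=None,
                n_iter: int = 5000) -> pd.DataFrame:
    """2-D embedding of cells from CNV values or an scRT distance matrix.

    ``kind='cnv'`` treats ``matrix`` as cells x bins data;
    ``kind='rt-distance'`` treats it as a precomputed pairwise distance
    (e.g. from :func:`scrt.rt.smc_distance_matrix`).  A seed is
    mandatory: embeddings are stochastic and must be reproducible.
    """
    if seed is None:
        raise ValueError("embeddings require an explicit seed")
    if kind not in ("cnv", "rt-distance"):
        raise ValueError(f"unknown input kind {kind!r}")
    x = matrix.to_numpy(dtype=float)
    if kind == "cnv":
        x = np.nan_to_num(x, nan=np.nanmedian(x))
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 cells to embed")
    if float(np.nanstd(x)) == 0.0:
        # degenerate input (all cells identical): every embedding is a
        # single point; emit seeded jitter instead of feeding NaNs to
        # the optimisers
        rng = np.random.default_rng(int(seed))
        coords = rng.normal(0.0, 1e-6, size=(n, 2))
        return pd.DataFrame(coords, index=matrix.index,
                            columns=["x", "y"])
    if method == "tsne":
        from sklearn.manifold import TSNE
        perplexity = max(n / 50.0, 10.0)
        perplexity = min(perplexity, (n - 1) / 3.0)
        tsne = TSNE(n_components=2, perplexity=perplexity, angle=0.25,
                    max_iter=n_iter, random_state=int(seed),
                    metric="precomputed" if kind == "rt-distance"
                    else "euclidean",
                    init="random" if kind == "rt-distance" else "pca")
        coords = tsne.fit_transform(x)
    elif method == "umap":
        import umap
        reducer = umap.UMAP(n_components=2, random_state=int(seed),
                            metric="precomputed" if kind == "rt-distance"
                            else "euclidean")
        coords = reducer.fit_transform(x)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=matrix.index, columns=["x", "y"])


def _point_in_polygon(px, py, vertices):
    """Crossing-number containment test; boundary points count inside."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if (abs(cross) < 1e-12
                and min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12
                and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12):
            return True
        if (y1 > py) != (y2 > py):
            xin = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
            if px < xin:
                inside = not inside
    return inside


def gate_subpopulations(embedding: pd.DataFrame, gates: dict) -> pd.Series:
    """Label cells by gates drawn in the embedding.

    Gates map label -> rectangle ``(xmin, xmax, ymin, ymax)`` or polygon
    ``[(x, y), ...]``; boundaries are inclusive.  Cells outside every
    gate get the label ``"none"``; overlapping gates resolve to the
    first match in insertion order.
    """
    labels = pd.Series("none", index=embedding.index, dtype=object)
    for cid in embedding.index:
        px, py = float(embedding.at[cid, "x"]), float(embedding.at[cid, "y"])
        for name, gate in gates.items():
            gate = list(gate) if not isinstance(gate, tuple) else gate
            if (len(gate) == 4 and
                    all(np.isscalar(g) for g in gate)):
                xmin, xmax, ymin, ymax = gate
                hit = xmin <= px <= xmax and ymin <= py <= ymax
            else:
                hit = _point_in_polygon(px, py, list(gate))
            if hit:
                labels[cid] = name
                break
    return labels


# ---------------------------------------------------------------------------
# stage-resolved replication probability

@dataclass
class StageProbability:
    stage: str
    probability: pd.Series     # per-bin replication probability
    n_cells: int


def stage_cells(replication_pct: pd.Series, stage: str,
                gates: dict | None = None):
    gates = gates or STAGE_GATES
    if stage not in gates:
        raise ValueError(f"unknown stage {stage!r}; options {list(gates)}")
    lo, hi = gates[stage]
    return list(replication_pct.index[(replication_pct >= lo)
                                      & (replication_pct <= hi)])


def stage_probability(scrt: pd.DataFrame, replication_pct: pd.Series,
                      stage: str, gates: dict | None = None
                      ) -> StageProbability:
    """Per-bin replication probability among cells of one S-phase stage."""
    cells = stage_cells(replication_pct, stage, gates)
    if not cells:
        raise ValueError(f"empty stage {stage!r}: no cells in gate")
    prob = scrt.loc[cells].mean(axis=0, skipna=True)
    return StageProbability(stage=stage, probability=prob,
                            n_cells=len(cells))


def extract_ipls(scrt: pd.DataFrame, replication_pct: pd.Series,
                 gates: dict | None = None) -> pd.Series:
    """Initiation probability landscape for replication simulators.

    The probability of each bin being replicated in early S-phase cells
    (up to 30% replicated); non-negative by construction.
    """
    sp = stage_probability(scrt, replication_pct, "early", gates)
    return sp.probability


# ---------------------------------------------------------------------------
# out-of-schedule events

@dataclass
class OutOfScheduleResult:
    per_cell: pd.DataFrame       # cell_id, stage, n_events, n_eligible, rate
    recurrence: pd.Series        # per-bin count of distinct event cells
    run_lengths: list            # contiguous event-run lengths (bins)
    early_event_rate: float      # median per-cell rate, early stage
    late_event_rate: float       # median per-cell rate, late stage
    early_event_rate_pooled: float = np.nan
    late_event_rate_pooled: float = np.nan


def out_of_schedule(scrt: pd.DataFrame, replication_pct: pd.Series,
                    rt_track: pd.Series,
                    gates: dict | None = None) -> OutOfScheduleResult:
    """Detect bins replicating far out of their population schedule.

    Early events: pseudo-bulk-late bins (RT < 0.5) replicated in cells
    <= 30% through S.  Late events: pseudo-bulk-early bins (RT > 0.5)
    still unreplicated in cells >= 70% through S.  Event runs (lengths
    of consecutive event bins along the index) summarise whether events
    cluster into large domains.

    The headline per-stage rates are medians of the per-cell rates:
    cells that finished replication but were solved at the G1/G2 dose
    produce empty binary profiles, land in the early gate with a rate
    of exactly zero, and would otherwise dilute a pooled estimate.
    """
    rt = rt_track.reindex(scrt.columns)
    late_bins = rt.index[rt < 0.5]
    early_bins = rt.index[rt > 0.5]
    rows = []
    recurrence = pd.Series(0, index=scrt.columns, dtype=int)
    run_lengths = []

    def _runs(event_mask: pd.Series):
        arr = event_mask.to_numpy()
        lengths, run = [], 0
        for v in arr:
            if v:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
        return lengths

    for stage, sign in (("early", 1.0), ("late", 0.0)):
        cells = stage_cells(replication_pct, stage, gates)
        bins_ = late_bins if stage == "early" else early_bins
        for cid in cells:
            row = scrt.loc[cid, bins_]
            defined = row.notna()
            events = (row == sign) & defined
            rows.append({"cell_id": cid, "stage": stage,
                         "n_events": int(events.sum()),
                         "n_eligible": int(defined.sum()),
                         "rate": float(events.sum() / defined.sum())
                         if defined.any() else np.nan})
            recurrence.loc[bins_] += events.astype(int)
            run_lengths.extend(_runs(events))
    per_cell = pd.DataFrame(rows)

    def _pooled(stage):
        sub = per_cell[per_cell.stage == stage]
        tot = sub.n_eligible.sum()
        return float(sub.n_events.sum() / tot) if tot else np.nan

    def _median(stage):
        sub = per_cell[per_cell.stage == stage]
        return float(sub.rate.median()) if len(sub) else np.nan

    return OutOfScheduleResult(per_cell=per_cell, recurrence=recurrence,
                               run_lengths=run_lengths,
                               early_event_rate=_median("early"),
                               late_event_rate=_median("late"),
                               early_event_rate_pooled=_pooled("early"),
                               late_event_rate_pooled=_pooled("late"))
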