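"""Readers and writers for the plain-text formats the pipeline touches.

Bin annotations, count matrices, QC tables and scRT matrices travel as
TSV; RT tracks as 4-column bedGraph (1 = early); per-cell segments and
blacklists as BED.  Bin identifiers are ``chrom:start-end`` with 0-based
half-open coordinates, so every table round-trips losslessly.
"""

from __future__ import annotations

import json
import re

import numpy as np
import pandas as pd

_BIN_ID = re.compile(r"^(.+):(\d+)-(\d+)$")


def bin_ids(bins: pd.DataFrame) -> list[str]:
    return [f"{c}:{s}-{e}" for c, s, e in
            zip(bins.chrom, bins.start, bins.end)]


def parse_bin_ids(ids) -> pd.DataFrame:
    rows = []
    for b in ids:
        m = _BIN_ID.match(b)
        if not m:
            raise ValueError(f"malformed bin id {b!r}")
        rows.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bins(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", index=False)


def read_bins(path) -> pd.DataFrame:
    bins = pd.read_csv(path, sep="\t")
    for col in ("blacklisted", "is_remainder", "usable"):
        if col in bins:
            bins[col] = bins[col].astype(bool)
    return bins


def write_counts(counts: pd.DataFrame, path) -> None:
    """Cells x bins count matrix, cells as rows."""
    counts.to_csv(path, sep="\t", index_label="cell_id")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    df.index.name = None
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="cell_id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    df.index.name = None
    return df


def write_bedgraph(track: pd.Series, path) -> None:
    """4-column bedGraph from a Series indexed by bin ids (NaN skipped)."""
    coords = parse_bin_ids(track.index)
    with open(path, "w") as fh:
        for (c, s, e), v in zip(coords.itertuples(index=False),
                                track.to_numpy()):
            if np.isfinite(v):
                fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     comment="#")
    idx = [f"{c}:{s}-{e}" for c, s, e in
           zip(df.chrom, df.start, df.end)]
    return pd.Series(df.value.to_numpy(), index=idx)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return df


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    cols = segments[["chrom", "start", "end", "cn"]].copy()
    cols["cn"] = cols.cn.astype(int)
    cols.to_csv(path, sep="\t", header=False, index=False)


def write_replicated_bed(scrt_row: pd.Series, path) -> None:
    """Per-cell BED of replicated intervals (consecutive bins merged)."""
    coords = parse_bin_ids(scrt_row.index)
    with open(path, "w") as fh:
        cur = None
        for (c, s, e), v in zip(coords.itertuples(index=False),
                                scrt_row.to_numpy()):
            if v == 1.0:
                if cur and cur[0] == c and cur[2] == s:
                    cur = (c, cur[1], e)
                else:
                    if cur:
                        fh.write(f"{cur[0]}\t{cur[1]}\t{cur[2]}\n")
                    cur = (c, s, e)
            else:
                if cur:
                    fh.write(f"{cur[0]}\t{cur[1]}\t{cur[2]}\n")
                    cur = None
        if cur:
            fh.write(f"{cur[0]}\t{cur[1]}\t{cur[2]}\n")


def read_phase_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"cell_id", "phase"}.issubset(df.columns):
        raise ValueError("phase metadata needs cell_id and phase columns")
    return df


def read_gates(path) -> dict:
    with open(path) as fh:
        gates = json.load(fh)
    return {k: tuple(v) if (len(v) == 4 and np.isscalar(v[0]))
            else [tuple(p) for p in v]
            for k, v in gates.items()}


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
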