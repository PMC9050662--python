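"""Fixed-width genomic bins: coordinates, GC content and mappability.

The bin table is the coordinate backbone of the whole pipeline.  Bins are
0-based half-open (BED convention) and tile each chromosome contiguously;
the last bin of a chromosome may be shorter than the nominal width and is
flagged (``is_remainder``) so it can be excluded from GC-correction median
pools downstream.

Mappability is estimated by simulation: uniform 1X reads are generated
from the reference (one read per ``read_length`` stride, so the number of
source reads per bin is exact), sequencing errors are injected as random
substitutions, and the reads are mapped back with a pluggable aligner.
The mappability of bin *n* is the ratio of reads mapped into the bin to
reads generated from it.  A bundled k-mer seed-and-verify mapper (best
hit, ties broken uniformly at random under a fixed seed) keeps the whole
procedure free of external binaries; any callable with the same signature
can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import check_seed

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

#: mappability window outside which a bin is excluded from analysis
MAPPABILITY_MIN = 0.8
MAPPABILITY_MAX = 1.5

BIN_COLUMNS = ["chrom", "start", "end", "gc", "mappability",
               "blacklisted", "is_remainder", "usable"]


@dataclass(frozen=True)
class ReadParams:
    """Parameters of the simulated sequencing reads.

    error_rate is the per-base substitution probability (default 0.1%,
    typical of short-read data); fragment_size only matters for
    paired-end layouts.
    """
    read_length: int = 50
    layout: str = "single-end"
    fragment_size: int = 300
    error_rate: float = 0.001

    def __post_init__(self):
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.layout not in ("single-end", "paired-end"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


def make_bins(genome_index: Sequence[tuple[str, int]],
              bin_size: int = 20_000,
              include_sex: bool = False) -> pd.DataFrame:
    """Tile chromosomes with fixed-width bins.

    Parameters
    ----------
    genome_index
        Sequence of ``(chrom, length)`` pairs, lengths in bp.
    bin_size
        Nominal bin width in bp (default 20 kb).
    include_sex
        Keep X/Y chromosomes; by default only autosomes are binned.
    """
    genome_index = list(genome_index)
    if not genome_index:
        raise ValueError("empty genome index")
    if bin_size < 1_000:
        raise ValueError("bin_size must be >= 1 kb")
    rows = []
    for chrom, length in genome_index:
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        if not include_sex and chrom in SEX_CHROMS:
            continue
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
        rows.append(df)
    if not rows:
        raise ValueError("no chromosomes retained (all sex chromosomes?)")
    bins = pd.concat(rows, ignore_index=True)
    bins["gc"] = np.nan
    bins["mappability"] = np.nan
    bins["blacklisted"] = False
    bins["is_remainder"] = (bins.end - bins.start) < bin_size
    bins["usable"] = False
    return bins


def _as_sequences(genome) -> Mapping[str, str]:
    """Accept a dict of strings or a pyfaidx.Fasta-like object."""
    if isinstance(genome, Mapping):
        return genome
    # pyfaidx.Fasta: indexable by name, records stringify to sequence
    return {name: str(genome[name][:]) for name in genome.keys()}


def gc_content(bins: pd.DataFrame, genome,
               max_ambiguous_frac: float = 0.5) -> pd.DataFrame:
    """Fill per-bin GC fraction from reference sequences.

    GC is computed over unambiguous bases only; bins whose sequence is at
    least ``max_ambiguous_frac`` ambiguous (N) get a missing GC and are
    unusable downstream.
    """
    seqs = _as_sequences(genome)
    out = bins.copy()
    gc_vals = np.full(len(out), np.nan)
    for chrom, grp in out.groupby("chrom", sort=False):
        if chrom not in seqs:
            raise KeyError(f"no sequence for chromosome {chrom!r}")
        seq = seqs[chrom].upper()
        for i, (start, end) in zip(grp.index, zip(grp.start, grp.end)):
            if end > len(seq):
                raise ValueError(
                    f"bin {chrom}:{start}-{end} beyond sequence end "
                    f"({len(seq)} bp)")
            sub = seq[start:end]
            n_gc = sub.count("G") + sub.count("C")
            n_at = sub.count("A") + sub.count("T")
            total = n_gc + n_at
            width = end - start
            if width == 0 or (width - total) / width >= max_ambiguous_frac \
                    or total == 0:
                continue
            gc_vals[out.index.get_loc(i)] = n_gc / total
    out["gc"] = gc_vals
    return out


# ---------------------------------------------------------------------------
# read simulation and the bundled k-mer mapper

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def simulate_reads(genome, params: ReadParams, seed):
    """Deterministically place 1X reads and inject substitution errors.

    One read starts every ``read_length`` bp (non-overlapping), which
    realizes 1X coverage with an exact, deterministic source count per
    bin.  Paired-end layouts additionally emit the distal mate of each
    fragment; every read is mapped and counted independently.

    Returns a list of ``(chrom, pos, read_codes)`` with reads as uint8
    arrays (A=0..T=3, 4=ambiguous).
    """
    rng = check_seed(seed)
    seqs = _as_sequences(genome)
    L = params.read_length
    reads = []
    for chrom, seq in seqs.items():
        codes = _encode(seq)
        starts = list(range(0, len(codes) - L + 1, L))
        if params.layout == "paired-end":
            mate_off = params.fragment_size - L
            starts += [s + mate_off for s in starts
                       if 0 <= s + mate_off <= len(codes) - L]
        for s in starts:
            read = codes[s:s + L].copy()
            if params.error_rate > 0:
                errs = np.nonzero(rng.random(L) < params.error_rate)[0]
                if errs.size:
                    shift = rng.integers(1, 4, size=errs.size).astype(np.uint8)
                    ok = read[errs] < 4
                    read[errs[ok]] = (read[errs[ok]] + shift[ok]) % 4
            reads.append((chrom, s, read))
    return reads


class KmerMapper:
    """Exact-seed, mismatch-tolerant best-hit read mapper.

    Indexes every k-mer of the reference as a 2-bit-packed integer; a
    read is located through up to three seeds, candidate loci are
    verified by Hamming distance, and the best (fewest mismatches) locus
    wins.  Equally good loci are broken uniformly at random with the
    supplied seed, which is what makes the mappability of an exactly
    duplicated region split evenly between its copies.
    """

    def __init__(self, genome, k: int = 21, max_mismatches: int = 5,
                 seed=0, ambiguous: str = "random"):
        self.k = int(k)
        if not 1 <= self.k <= 31:
            raise ValueError("k must be in [1, 31]")
        if ambiguous not in ("random", "drop"):
            raise ValueError("ambiguous must be 'random' or 'drop'")
        self.max_mismatches = int(max_mismatches)
        self.ambiguous = ambiguous
        self.rng = check_seed(seed)
        self._chroms = []
        self._codes = []
        kmers = []
        locs = []
        for ci, (chrom, seq) in enumerate(_as_sequences(genome).items()):
            codes = _encode(seq)
            self._chroms.append(chrom)
            self._codes.append(codes)
            if codes.size < self.k:
                continue
            km = self._pack(codes)
            valid = np.nonzero(km >= 0)[0]
            kmers.append(km[valid].astype(np.uint64))
            locs.append(np.stack([np.full(valid.size, ci), valid], axis=1))
        if kmers:
            kk = np.concatenate(kmers)
            ll = np.concatenate(locs)
            order = np.argsort(kk, kind="stable")
            self._kmers = kk[order]
            self._locs = ll[order]
        else:
            self._kmers = np.empty(0, dtype=np.uint64)
            self._locs = np.empty((0, 2), dtype=np.int64)

    def _pack(self, codes: np.ndarray) -> np.ndarray:
        """2-bit pack all k-mers; -1 where a window contains ambiguity."""
        k = self.k
        n = codes.size - k + 1
        vals = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for j in range(k):
            window = codes[j:j + n]
            vals = (vals << 2) | np.minimum(window, 3).astype(np.int64)
            bad |= window >= 4
        vals[bad] = -1
        return vals

    def _pack_one(self, codes: np.ndarray) -> int:
        if np.any(codes >= 4):
            return -1
        val = 0
        for c in codes:
            val = (val << 2) | int(c)
        return val

    def map_read(self, read: np.ndarray):
        """Return best ``(chrom, pos)`` or ``None`` if unmapped."""
        k = self.k
        L = read.size
        offsets = [0]
        if L >= 2 * k:
            offsets.append(k)
        if L >= 3 * k:
            offsets.append(2 * k)
        if L - k not in offsets and L > k:
            offsets.append(L - k)
        candidates = set()
        for off in offsets:
            key = self._pack_one(read[off:off + k])
            if key < 0:
                continue
            lo = np.searchsorted(self._kmers, np.uint64(key), side="left")
            hi = np.searchsorted(self._kmers, np.uint64(key), side="right")
            for ci, pos in self._locs[lo:hi]:
                candidates.add((int(ci), int(pos) - off))
        best, best_mm = [], self.max_mismatches + 1
        for ci, pos in candidates:
            codes = self._codes[ci]
            if pos < 0 or pos + L > codes.size:
                continue
            mm = int(np.count_nonzero(codes[pos:pos + L] != read))
            if mm < best_mm:
                best, best_mm = [(ci, pos)], mm
            elif mm == best_mm:
                best.append((ci, pos))
        if not best:
            return None
        if len(best) > 1:
            if self.ambiguous == "drop":
                return None      # multireads behave like MAPQ-filtered
            ci, pos = best[self.rng.integers(len(best))]
        else:
            ci, pos = best[0]
        return self._chroms[ci], pos

    def __call__(self, reads: Iterable[tuple[str, int, np.ndarray]]):
        for chrom, pos, read in reads:
            yield (chrom, pos), self.map_read(read)


def compute_mappability(bins: pd.DataFrame, genome,
                        read_params: ReadParams | None = None,
                        aligner: Callable | None = None,
                        seed=0) -> pd.DataFrame:
    """Fill per-bin mappability by read-simulation round trip.

    mappability(bin) = reads remapped into the bin / reads generated from
    it.  Bins with no source reads stay missing and unusable.  The
    ``aligner`` takes an iterable of ``(chrom, pos, read)`` and yields
    ``((chrom, pos), mapping-or-None)``; defaults to the bundled
    :class:`KmerMapper` on the same genome.
    """
    rng = check_seed(seed)
    params = read_params or ReadParams()
    seqs = _as_sequences(genome)
    for chrom in bins.chrom.unique():
        if chrom not in seqs:
            raise ValueError(f"genome lacks chromosome {chrom!r}")
    if aligner is None:
        aligner = KmerMapper({c: seqs[c] for c in bins.chrom.unique()},
                             seed=rng)
    reads = simulate_reads({c: seqs[c] for c in bins.chrom.unique()},
                           params, rng)

    out = bins.copy().reset_index(drop=True)
    index = _BinIndex(out)
    src = np.zeros(len(out), dtype=np.int64)
    dst = np.zeros(len(out), dtype=np.int64)
    for (chrom0, pos0), hit in aligner(reads):
        i0 = index.locate(chrom0, pos0)
        if i0 is not None:
            src[i0] += 1
        if hit is not None:
            chrom1, pos1 = hit
            i1 = index.locate(chrom1, pos1)
            if i1 is not None:
                dst[i1] += 1
    mapp = np.full(len(out), np.nan)
    nz = src > 0
    mapp[nz] = dst[nz] / src[nz]
    out["mappability"] = mapp
    return out


class _BinIndex:
    """Fast (chrom, pos) -> bin row lookup over a bin table."""

    def __init__(self, bins: pd.DataFrame):
        self._starts = {}
        self._rows = {}
        self._ends = {}
        for chrom, grp in bins.groupby("chrom", sort=False):
            self._starts[chrom] = grp.start.to_numpy()
            self._ends[chrom] = grp.end.to_numpy()
            self._rows[chrom] = grp.index.to_numpy()

    def locate(self, chrom, pos):
        starts = self._starts.get(chrom)
        if starts is None:
            return None
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j < 0 or pos >= self._ends[chrom][j]:
            return None
        return int(self._rows[chrom][j])


def apply_blacklist(bins: pd.DataFrame,
                    blacklist: pd.DataFrame) -> pd.DataFrame:
    """Flag bins overlapping any blacklist interval (chrom,start,end)."""
    out = bins.copy()
    flagged = out["blacklisted"].to_numpy().copy()
    for _, row in blacklist.iterrows():
        hit = ((out.chrom == row.chrom)
               & (out.start < int(row.end))
               & (out.end > int(row.start)))
        flagged |= hit.to_numpy()
    out["blacklisted"] = flagged
    return out


def finalize_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Set the ``usable`` flag from mappability, GC and blacklist."""
    out = bins.copy()
    mapp = out.mappability
    out["usable"] = (mapp.ge(MAPPABILITY_MIN) & mapp.le(MAPPABILITY_MAX)
                     & out.gc.notna() & ~out.blacklisted)
    return out


def build_bin_table(genome, bin_size: int = 20_000,
                    include_sex: bool = False,
                    read_params: ReadParams | None = None,
                    blacklist: pd.DataFrame | None = None,
                    seed=0,
                    compute_map: bool = True) -> pd.DataFrame:
    """Convenience: bins + GC + mappability + usability in one call."""
    seqs = _as_sequences(genome)
    idx = [(c, len(s)) for c, s in seqs.items()]
    bins = make_bins(idx, bin_size=bin_size, include_sex=include_sex)
    bins = gc_content(bins, seqs)
    if compute_map:
        bins = compute_mappability(bins, seqs, read_params, seed=seed)
    else:
        bins["mappability"] = 1.0
    if blacklist is not None:
        bins = apply_blacklist(bins, blacklist)
    return finalize_bins(bins)
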