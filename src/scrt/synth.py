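"""Ground-truthed synthetic single-cell WGS count data.

The generator emulates the statistical structure the pipeline consumes:
G1/G2 cells carry an integer clone copy-number profile; S-phase cells
additionally double the dose of every bin whose firing time has passed.
Firing times come from a smooth replication-timing landscape with
domains on the megabase scale, jittered per cell and per bin with a
temporal noise whose scale (default 0.12 of S-phase length) mirrors the
cell-to-cell RT variability observed in real single-cell data (T_width
around 2.5-2.8 h of a 10-h S phase corresponds to a Gaussian front of
sigma ~ 1.2 h).  A small ectopic rate sends bins completely out of
schedule - a late bin fires at S entry, an early bin not at all - which
is the ground truth against which out-of-schedule event recovery is
measured.  Read counts are Poisson (optionally over-dispersed) around a
rate proportional to dose x GC bias x mappability, scaled to a per-cell
coverage drawn in reads per megabase per haploid genome.

Everything is bit-reproducible given (model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_seed
from .bins import finalize_bins, make_bins

DEFAULT_CHROMS = (("chr1", 100_000_000), ("chr2", 100_000_000),
                  ("chr3", 100_000_000))


@dataclass
class TruthModel:
    """Parameters of the synthetic population.

    ``rt_truth`` is the per-RT-bin mean firing time in [0, 1]
    (0 = earliest); ``firing_noise`` the per-cell-per-bin temporal
    jitter (sd, same units); ``ectopic_rate`` the probability that a bin
    fires completely out of schedule.  ``clones`` is a list of
    ``(fraction, per-RT-bin integer CN profile)``; fractions must sum
    to 1.  Coverage is drawn uniformly from ``rpmb_per_haploid`` and
    translated into total reads through the cell's dose ploidy.
    """
    chrom_lengths: tuple = DEFAULT_CHROMS
    bin_size: int = 20_000
    rt_bin_size: int = 200_000
    rt_truth: np.ndarray | None = None
    firing_noise: float = 0.12
    ectopic_rate: float = 0.01
    clones: list | None = None
    s_frac: float = 0.20
    s_fraction_range: tuple = (0.05, 0.95)
    rpmb_per_haploid: tuple = (250.0, 450.0)
    gc_bias_strength: float = 0.5
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.clones is not None:
            total = sum(f for f, _p in self.clones)
            if not np.isclose(total, 1.0):
                raise ValueError("clone fractions must sum to 1")
        if self.rt_truth is not None:
            rt = np.asarray(self.rt_truth, dtype=float)
            if rt.min() < 0 or rt.max() > 1:
                raise ValueError("rt_truth values must lie in [0, 1]")


@dataclass
class SimulatedPopulation:
    bins: pd.DataFrame            # 20-kb bin table (gc, mappability, usable)
    rt_bins: pd.DataFrame         # RT-resolution bins
    counts: pd.DataFrame          # cells x 20-kb bins raw counts
    truth: pd.DataFrame           # per-cell labels and ground truth
    rt_truth: pd.Series           # firing time per RT bin (0 = early)
    rt_track_truth: pd.Series     # same landscape on the RT scale (1=early)
    replicated: pd.DataFrame      # S cells x RT bins ground-truth mask
    model: TruthModel = field(repr=False, default=None)


def _bin_ids(bins: pd.DataFrame):
    return [f"{c}:{s}-{e}" for c, s, e in
            zip(bins.chrom, bins.start, bins.end)]


def default_rt_landscape(rt_bins: pd.DataFrame, seed,
                         domain_bins: float = 3.0) -> np.ndarray:
    """Smooth firing-time landscape with sub-megabase timing domains.

    A Gaussian random field (moving-average smoothing, correlation
    length ``domain_bins`` RT bins) is rank-transformed to uniform
    [0, 1] per genome so early and late domains alternate and the
    replication front sweeps the full range of firing times.
    """
    rng = check_seed(seed)
    parts = []
    for _, grp in rt_bins.groupby("chrom", sort=False):
        n = len(grp)
        raw = rng.normal(size=n + 4 * int(domain_bins))
        kernel = np.exp(-0.5 * (np.arange(-2 * int(domain_bins),
                                          2 * int(domain_bins) + 1)
                                / domain_bins) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(raw, kernel, mode="same")
        parts.append(smooth[2 * int(domain_bins):2 * int(domain_bins) + n])
    x = np.concatenate(parts)
    ranks = np.argsort(np.argsort(x))
    return (ranks + 0.5) / x.size


def default_clone_profile(rt_bins: pd.DataFrame,
                          base_cn: int = 2) -> np.ndarray:
    """Aneuploid-but-plausible clone profile spanning several CN states.

    Each chromosome carries the base copy number plus one loss block and
    one gain block; the CN spread (1..4) is what lets the reads-per-copy
    solver anchor its unit, as in real tumour genomes.
    """
    cn = np.full(len(rt_bins), base_cn, dtype=float)
    patterns = [(1, 0.10, 0.25, 3, 0.60, 0.75),
                (1, 0.40, 0.50, 4, 0.70, 0.80),
                (1, 0.65, 0.80, 3, 0.05, 0.20)]
    for k, (_, grp) in enumerate(rt_bins.groupby("chrom", sort=False)):
        n = len(grp)
        lo_cn, a0, a1, hi_cn, b0, b1 = patterns[k % len(patterns)]
        idx = grp.index.to_numpy()
        cn[idx[int(a0 * n):int(a1 * n)]] = lo_cn
        cn[idx[int(b0 * n):int(b1 * n)]] = hi_cn
    return cn


def with_chrom_gain(profile: np.ndarray, rt_bins: pd.DataFrame,
                    chrom: str, gain: int = 1) -> np.ndarray:
    """Whole-chromosome gain on top of an existing clone profile."""
    out = profile.copy()
    sel = (rt_bins.chrom == chrom).to_numpy()
    out[sel] = out[sel] + gain
    return out


def _build_bins(model: TruthModel, rng) -> pd.DataFrame:
    bins = make_bins(list(model.chrom_lengths), bin_size=model.bin_size,
                     include_sex=True)
    gc = np.empty(len(bins))
    for _, grp in bins.groupby("chrom", sort=False):
        n = len(grp)
        frac = np.arange(n) / max(n - 1, 1)
        gc[grp.index] = 0.35 + 0.25 * frac + rng.normal(0, 0.01, size=n)
    bins["gc"] = np.clip(gc, 0.25, 0.75)
    bins["mappability"] = 1.0
    return finalize_bins(bins)


def simulate_population(model: TruthModel, n_cells: int,
                        seed=None) -> SimulatedPopulation:
    """Draw a ground-truthed population of single-cell count profiles."""
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if not model.chrom_lengths:
        raise ValueError("empty genome layout")
    rng = check_seed(model.seed if seed is None else seed)

    bins = _build_bins(model, rng)
    rt_bins = make_bins(list(model.chrom_lengths),
                        bin_size=model.rt_bin_size, include_sex=True)
    rt_bins = rt_bins[["chrom", "start", "end"]]
    rt_ids = _bin_ids(rt_bins)

    if model.rt_truth is not None:
        tau = np.asarray(model.rt_truth, dtype=float)
        if tau.size != len(rt_bins):
            raise ValueError("rt_truth length does not match RT bins")
    else:
        tau = default_rt_landscape(rt_bins, rng)

    clones = model.clones or [(1.0, default_clone_profile(rt_bins))]
    clone_fracs = np.array([f for f, _p in clones])
    clone_profiles = [np.asarray(p, dtype=float) for _f, p in clones]

    # map 20-kb bins onto their RT bin
    rt_index = np.empty(len(bins), dtype=int)
    for chrom, grp in bins.groupby("chrom", sort=False):
        sel_rt = rt_bins.chrom == chrom
        starts = rt_bins.start[sel_rt].to_numpy()
        base = np.nonzero(sel_rt.to_numpy())[0][0]
        rt_index[grp.index] = base + np.searchsorted(
            starts, grp.start.to_numpy(), side="right") - 1

    widths = (bins.end - bins.start).to_numpy(dtype=float)
    gc = bins.gc.to_numpy()
    gc_bias = 1.0 + model.gc_bias_strength * (gc - np.nanmean(gc))
    mapp = bins.mappability.to_numpy()
    genome_mb = widths.sum() / 1e6

    cells, truth_rows, rep_rows = [], [], {}
    count_rows = np.empty((n_cells, len(bins)), dtype=np.int64)
    for i in range(n_cells):
        cid = f"cell{i:04d}"
        clone = int(rng.choice(len(clones), p=clone_fracs))
        cn_rt = clone_profiles[clone]
        cn20 = cn_rt[rt_index]
        is_s = rng.random() < model.s_frac
        if is_s:
            s = float(rng.uniform(*model.s_fraction_range))
            tau_eff = tau + rng.normal(0, model.firing_noise,
                                       size=tau.size)
            ect = rng.random(tau.size) < model.ectopic_rate
            # out-of-schedule firing at the S-phase boundaries
            tau_eff[ect] = np.where(tau[ect] > 0.5, -1.0, 2.0)
            replicated = tau_eff <= s
            rep_rows[cid] = replicated.copy()
        else:
            s = np.nan
            replicated = np.zeros(tau.size, dtype=bool)
        rep20 = replicated[rt_index]
        dose = cn20 * (1.0 + rep20)
        base_ploidy = float((cn20 * widths).sum() / widths.sum())
        dose_ploidy = float((dose * widths).sum() / widths.sum())
        rep_frac = float((rep20 * widths).sum() / widths.sum())

        rpmb_h = float(rng.uniform(*model.rpmb_per_haploid))
        total_reads = rpmb_h * dose_ploidy * genome_mb
        w = dose * gc_bias * mapp * widths
        lam = total_reads * w / w.sum()
        if model.dispersion > 0:
            shape = 1.0 / model.dispersion
            lam = rng.gamma(shape, scale=np.maximum(lam, 1e-12) / shape)
        count_rows[i] = rng.poisson(lam)
        cells.append(cid)
        truth_rows.append({
            "cell_id": cid,
            "phase": "S" if is_s else "G1G2",
            "clone": clone,
            "s_fraction": s,
            "true_replication_fraction": rep_frac,
            "true_base_ploidy": base_ploidy,
            "true_dose_ploidy": dose_ploidy,
            "rpmb_per_haploid": rpmb_h,
        })

    counts = pd.DataFrame(count_rows, index=cells,
                          columns=_bin_ids(bins))
    truth = pd.DataFrame(truth_rows).set_index("cell_id", drop=False)
    replicated = pd.DataFrame.from_dict(rep_rows, orient="index",
                                        columns=rt_ids).astype(float) \
        if rep_rows else pd.DataFrame(columns=rt_ids)
    return SimulatedPopulation(
        bins=bins, rt_bins=rt_bins, counts=counts, truth=truth,
        rt_truth=pd.Series(tau, index=rt_ids),
        rt_track_truth=pd.Series(1.0 - tau, index=rt_ids),
        replicated=replicated, model=model)


# ---------------------------------------------------------------------------
# toy genomes for the binning/mappability machinery

def make_toy_genome(n_chroms: int = 2, chrom_length: int = 120_000,
                    bin_size: int = 20_000, seed=0,
                    gc_range: tuple = (0.30, 0.65),
                    repeat_block: tuple | None = None,
                    fasta_path=None):
    """Random genome with a controlled GC gradient and optional planted
    repeat.

    ``repeat_block = (src_chrom, src_start, length, dst_chrom,
    dst_start)`` copies a block verbatim, producing a known
    low-mappability region (each copy maps ~half the reads under random
    best-hit tie-breaking).  Returns a dict chrom -> sequence; if
    ``fasta_path`` is given the genome is also written as FASTA.
    """
    rng = check_seed(seed)
    bases = np.array(list("ACGT"))
    genome = {}
    for c in range(n_chroms):
        name = f"chr{c + 1}"
        frac = np.arange(chrom_length) / max(chrom_length - 1, 1)
        p_gc = gc_range[0] + (gc_range[1] - gc_range[0]) * frac
        is_gc = rng.random(chrom_length) < p_gc
        which = rng.integers(0, 2, size=chrom_length)
        codes = np.where(is_gc, 1 + which, 3 * which)  # C/G vs A/T
        genome[name] = "".join(bases[codes])
    if repeat_block is not None:
        src_chrom, src_start, length, dst_chrom, dst_start = repeat_block
        block = genome[src_chrom][src_start:src_start + length]
        s = genome[dst_chrom]
        genome[dst_chrom] = (s[:dst_start] + block
                             + s[dst_start + length:])
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for name, seq in genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
    return genome
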