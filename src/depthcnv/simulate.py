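"""Cohort simulator: binned Poisson coverage with known planted CNVs.

Emulates the statistical regime of off-target coverage from a capture assay:
~100 reads per 200 kb bin, per-sample library-size variation, a low-rank
multiplicative bias shared across samples (batch / chemistry effects), a
small fraction of hypervariable bins (tandem-repeat-like loci whose depth
varies far more than counting noise), and heterozygous CNVs planted at
relative dosage 0.5 (deletion) or 1.5 (duplication), or intermediate values
for mosaic events.

The expected count of sample s in bin b is

    lambda[s, b] = mean_reads_per_bin * scale[s] * exp(sum_k u_k[s] v_k[b])
                   * dosage[s, b] * h[s, b]

with counts drawn Poisson(lambda); h is lognormal noise confined to the
hypervariable bins.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binning import GenomeBinning, make_binning
from .coverage import CoverageMatrix

__all__ = ["PlantedCnv", "SimulationConfig", "simulate_cohort", "plant_random_cnvs"]

TRUTH_COLUMNS = ["sample", "chrom", "start", "end", "type", "dosage"]


@dataclass(frozen=True)
class PlantedCnv:
    """One ground-truth event: dosage 0.5/1.5 for het del/dup, else mosaic."""

    sample: str
    chrom: str
    start: int
    end: int
    dosage: float

    @property
    def type(self) -> str:
        return "DEL" if self.dosage < 1.0 else "DUP"


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 30
    chromosomes: tuple[tuple[str, int], ...] = (("1", 100_000_000), ("2", 60_000_000))
    bin_size: int = 200_000
    mean_reads_per_bin: float = 100.0
    sample_scale_sd: float = 0.1  # lognormal sd of library size
    bias_rank: int = 3
    bias_sd: float = 0.05  # sd of the bin-side bias loadings
    hypervariable_fraction: float = 0.02
    hypervariable_noise_sd: float = 0.5  # lognormal sigma in hypervariable bins
    cnvs: tuple[PlantedCnv, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mean_reads_per_bin <= 0:
            raise ValueError("mean_reads_per_bin must be positive")
        for cnv in self.cnvs:
            if cnv.dosage <= 0:
                raise ValueError(f"planted dosage must be positive: {cnv}")

    def sample_ids(self) -> list[str]:
        width = max(3, len(str(self.n_samples - 1)))
        return [f"S{i:0{width}d}" for i in range(self.n_samples)]


def _dosage_layer(config: SimulationConfig, binning: GenomeBinning, sample_ids) -> np.ndarray:
    """Planted relative dosage per sample x bin; 1 outside events.

    Events need not be bin-aligned: a partially covered bin gets dosage
    1 + (event_dosage - 1) * covered_fraction.
    """
    dosage = np.ones((len(sample_ids), binning.n_bins))
    index = {sid: i for i, sid in enumerate(sample_ids)}
    lengths = dict(binning.chromosomes)
    for cnv in config.cnvs:
        if cnv.sample not in index:
            raise ValueError(f"planted CNV names unknown sample {cnv.sample!r}")
        if cnv.chrom not in lengths:
            raise ValueError(f"planted CNV on unknown chromosome {cnv.chrom!r}")
        if not 0 <= cnv.start < cnv.end <= lengths[cnv.chrom]:
            raise ValueError(f"planted CNV outside chromosome bounds: {cnv}")
        sl = binning.chrom_slice(cnv.chrom)
        s = index[cnv.sample]
        for b in range(sl.start, sl.stop):
            lo = max(binning.starts[b], cnv.start)
            hi = min(binning.ends[b], cnv.end)
            if hi > lo:
                frac = (hi - lo) / (binning.ends[b] - binning.starts[b])
                dosage[s, b] *= 1.0 + (cnv.dosage - 1.0) * frac
    return dosage


def simulate_cohort(config: SimulationConfig) -> tuple[CoverageMatrix, pd.DataFrame]:
    """Draw a cohort count matrix and return it with its truth table.

    The truth table has columns ``sample chrom start end type dosage``; the
    same seed always reproduces the same matrix.
    """
    rng = np.random.default_rng(config.seed)
    binning = make_binning(config.chromosomes, config.bin_size)
    sample_ids = config.sample_ids()
    n, m = config.n_samples, binning.n_bins

    scale = np.exp(rng.normal(0.0, config.sample_scale_sd, size=n))
    log_bias = np.zeros((n, m))
    for _ in range(config.bias_rank):
        u = rng.normal(0.0, 1.0, size=n)
        v = rng.normal(0.0, config.bias_sd, size=m)
        log_bias += np.outer(u, v)
    hyper = np.ones((n, m))
    if config.hypervariable_fraction > 0:
        n_hyper = int(round(config.hypervariable_fraction * m))
        hyper_bins = rng.choice(m, size=n_hyper, replace=False)
        hyper[:, hyper_bins] = np.exp(
            rng.normal(0.0, config.hypervariable_noise_sd, size=(n, n_hyper))
        )
    dosage = _dosage_layer(config, binning, sample_ids)
    # partial terminal bins carry proportionally fewer reads
    width_frac = (binning.ends - binning.starts) / binning.bin_size
    lam = (
        config.mean_reads_per_bin
        * scale[:, None]
        * np.exp(log_bias)
        * hyper
        * dosage
        * width_frac[None, :]
    )
    counts = rng.poisson(lam)
    cov = CoverageMatrix(sample_ids=sample_ids, binning=binning, counts=counts)
    truth = pd.DataFrame(
        [(c.sample, c.chrom, c.start, c.end, c.type, c.dosage) for c in config.cnvs],
        columns=TRUTH_COLUMNS,
    )
    return cov, truth


def plant_random_cnvs(
    config: SimulationConfig,
    *,
    n_del: int,
    n_dup: int,
    min_bins: int = 6,
    max_bins: int = 25,
    del_dosage: float = 0.5,
    dup_dosage: float = 1.5,
    seed: int | None = None,
) -> SimulationConfig:
    """Return a config with bin-aligned heterozygous CNVs planted at random.

    Events are assigned to random samples and loci, at most one event per
    sample per chromosome so planted events never overlap.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    binning = make_binning(config.chromosomes, config.bin_size)
    sample_ids = config.sample_ids()
    occupied: set[tuple[str, str]] = set()
    cnvs = list(config.cnvs)
    specs = [del_dosage] * n_del + [dup_dosage] * n_dup
    for dosage in specs:
        for _ in range(10_000):
            sample = sample_ids[rng.integers(len(sample_ids))]
            chrom, length = config.chromosomes[rng.integers(len(config.chromosomes))]
            if (sample, chrom) in occupied:
                continue
            n_bins_chrom = length // config.bin_size  # keep clear of partial tail
            span = int(rng.integers(min_bins, max_bins + 1))
            if span >= n_bins_chrom:
                continue
            first = int(rng.integers(0, n_bins_chrom - span))
            start = first * config.bin_size
            end = (first + span) * config.bin_size
            cnvs.append(PlantedCnv(sample, chrom, start, end, dosage))
            occupied.add((sample, chrom))
            break
        else:
            raise RuntimeError("could not place planted CNV without overlap")
    return replace(config, cnvs=tuple(cnvs))
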