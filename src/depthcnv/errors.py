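"""Per-cell dosage error model: multiplicative sample x bin noise with a
Poisson floor.

The standard deviation of the relative dosage in sample s, bin b is modelled
as

    sigma[s, b] = max( sd_bin[b] * sd_sample[s] / mean_sd,  1/sqrt(N[s, b]) )

where sd_bin is the across-sample sd of dosage at that bin (how variable the
locus is), sd_sample is the across-bin sd of that sample (how noisy the
sample is), mean_sd is the cohort mean of sd_sample (so an average-noise
sample gets sigma ~ sd_bin), and N[s, b] is the expected raw read count of
the cell.  1/sqrt(N) is the relative sd of a Poisson count — a theoretical
minimum random error the dosage can have — and bounds sigma from below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CoverageMatrix
from .normalize import DosageMatrix

__all__ = ["ErrorMatrix", "poisson_floor", "estimate_errors"]


@dataclass
class ErrorMatrix:
    """Estimated dosage sd per sample x active bin, plus its components."""

    sigma: np.ndarray  # samples x active bins, > 0
    sd_bin: np.ndarray
    sd_sample: np.ndarray
    mean_sd: float
    floor: np.ndarray  # Poisson floor, same shape as sigma

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
            raise ValueError("sigma must be finite and positive everywhere")


def poisson_floor(expected_reads) -> np.ndarray:
    """Relative sd of a Poisson count with the given expectation: 1/sqrt(N)."""
    expected = np.asarray(expected_reads, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected read count must be positive")
    return 1.0 / np.sqrt(expected)


def estimate_errors(
    d: DosageMatrix,
    counts: CoverageMatrix,
    *,
    model: str = "multiplicative",
) -> ErrorMatrix:
    """Estimate sigma for every active cell of a dosage matrix.

    ``model="multiplicative"`` (default) applies the sample x bin model above;
    ``model="poisson"`` uses the Poisson floor alone (the naive counting-noise
    assumption, kept for ablation).  Expected reads per cell are taken from
    the *raw* counts — Poisson noise is a property of counting, not of the
    denoised dosage: sample mean count over active bins times the bin's
    relative depth.
    """
    if model not in ("multiplicative", "poisson"):
        raise ValueError(f"unknown error model {model!r}")
    n_samples = len(d.sample_ids)
    if n_samples < 3:
        raise ValueError(
            "error estimation needs at least 3 samples; analyse a larger cohort"
        )
    sub = counts.counts[:, d.active_mask].astype(float)
    sample_mean = sub.mean(axis=1)  # reads per bin per sample
    rel_depth = (sub / sample_mean[:, None]).mean(axis=0)  # bin relative depth
    expected = sample_mean[:, None] * rel_depth[None, :]
    floor = poisson_floor(np.maximum(expected, 1e-12))

    sd_bin = d.dosage.std(axis=0, ddof=1)
    sd_sample = d.dosage.std(axis=1, ddof=1)
    mean_sd = float(sd_sample.mean())
    if model == "poisson" or mean_sd == 0.0:
        modelled = np.zeros_like(floor)
    else:
        modelled = sd_sample[:, None] * sd_bin[None, :] / mean_sd
    sigma = np.maximum(modelled, floor)
    return ErrorMatrix(
        sigma=sigma, sd_bin=sd_bin, sd_sample=sd_sample, mean_sd=mean_sd, floor=floor
    )
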