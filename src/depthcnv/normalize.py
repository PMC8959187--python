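"""Two-step dosage normalization and SVD denoising of the coverage matrix.

Raw per-bin counts are converted to *relative dosage* d: first each sample's
counts are divided by that sample's mean over active bins (removing library
size), then each bin's column is divided by its across-sample mean (removing
locus-specific capture efficiency / mappability).  A diploid-normal cell then
sits at d = 1, a heterozygous deletion at ~0.5 and a heterozygous duplication
at ~1.5.

Residual structure shared across samples — batch, chemistry or handling
effects — is low-rank, so it is removed by discarding the largest singular
components of the log-dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .binning import GenomeBinning
from .coverage import CoverageMatrix

__all__ = ["DosageMatrix", "select_active_bins", "normalize_dosage", "svd_denoise"]

#: Dosage floor applied before taking logs; keeps log finite for zero-count
#: cells while preserving a strong-deletion signal.
DOSAGE_FLOOR = 0.01


@dataclass
class DosageMatrix:
    """Relative dosage d, samples x active bins (1.0 = diploid-normal)."""

    sample_ids: list[str]
    binning: GenomeBinning
    active_mask: np.ndarray  # bool per full bin
    dosage: np.ndarray  # samples x n_active
    normalized: bool = True
    svd_denoised: bool = False
    n_discarded_vectors: int = 0

    def __post_init__(self) -> None:
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.active_mask.shape != (self.binning.n_bins,):
            raise ValueError("active_mask must have one entry per bin")
        if self.dosage.shape != (len(self.sample_ids), int(self.active_mask.sum())):
            raise ValueError("dosage shape must be samples x active bins")

    @property
    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.active_mask)


def select_active_bins(counts: CoverageMatrix, min_mean_count: float = 1.0) -> np.ndarray:
    """Bins whose mean raw count across samples reaches ``min_mean_count``.

    Bins failing the threshold (unmappable or empty regions) carry no dosage
    and never contribute evidence to a call.
    """
    mask = counts.counts.mean(axis=0) >= min_mean_count
    if not mask.any():
        raise ValueError("no active bins: every bin is below the mean-count threshold")
    return mask


def normalize_dosage(counts: CoverageMatrix, active_mask: np.ndarray) -> DosageMatrix:
    """Two-step normalization: by sample mean, then by bin mean.

    Step 1 divides each sample's counts by that sample's mean over active
    bins; step 2 divides each bin's column of step-1 values by its mean over
    samples.  The result has bin-wise mean exactly 1 and is invariant to
    uniform scaling of any sample's counts.
    """
    if counts.n_samples < 2:
        raise ValueError("normalization needs at least 2 samples")
    active_mask = np.asarray(active_mask, dtype=bool)
    sub = counts.counts[:, active_mask].astype(float)
    sample_mean = sub.mean(axis=1)
    zero = np.flatnonzero(sample_mean <= 0)
    if zero.size:
        names = ", ".join(counts.sample_ids[i] for i in zero)
        raise ValueError(f"sample(s) with zero total count over active bins: {names}")
    step1 = sub / sample_mean[:, None]
    d = step1 / step1.mean(axis=0)[None, :]
    return DosageMatrix(
        sample_ids=list(counts.sample_ids),
        binning=counts.binning,
        active_mask=active_mask,
        dosage=d,
    )


def svd_denoise(d: DosageMatrix, n_discard: int = 5) -> DosageMatrix:
    """Remove the ``n_discard`` largest singular components of log dosage.

    The SVD is taken on L = log d (samples x active bins, natural log, with
    dosage floored at `DOSAGE_FLOOR`); the rank-``n_discard`` reconstruction
    built from the largest singular values is subtracted and the residual is
    exponentiated back to the dosage scale.  ``n_discard=0`` is the identity.
    """
    if n_discard == 0:
        return replace(d, dosage=d.dosage.copy())
    n_samples, n_active = d.dosage.shape
    if not 0 <= n_discard < min(n_samples, n_active):
        raise ValueError(
            f"n_discard={n_discard} must be < min(samples, active bins) "
            f"= {min(n_samples, n_active)}"
        )
    L = np.log(np.maximum(d.dosage, DOSAGE_FLOOR))
    U, S, Vt = np.linalg.svd(L, full_matrices=False)
    low_rank = (U[:, :n_discard] * S[:n_discard]) @ Vt[:n_discard]
    return replace(
        d,
        dosage=np.exp(L - low_rank),
        svd_denoised=True,
        n_discarded_vectors=n_discard,
    )
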