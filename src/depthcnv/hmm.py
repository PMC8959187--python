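"""Three-state HMM segmentation of dosage into deletion/duplication calls.

Per bin, one-sided Gaussian tail probabilities measure how compatible the
observed dosage d (with estimated sd sigma) is with each copy-number
hypothesis: P(d <= 0.5) for a heterozygous deletion, P(d >= 1.5) for a
heterozygous duplication, and P(d <= 1) or P(d >= 1) for normal dosage.
These tails are used directly as emission weights of a 3-state HMM
(DEL, NORM, DUP) with a small, symmetric switch probability; the Viterbi
path segments the genome and maximal DEL/DUP runs become calls.

In the default non-mosaic mode the deletion tail only exceeds the normal
tail once d crosses 0.75 (the midpoint of 0.5 and 1.0), and likewise 1.25
for duplications, so intermediate dosages — mosaic events or noise — never
accumulate evidence.  Mosaic mode replaces the CNV tails with the
probability of d being away from 1 in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "HmmConfig",
    "Emissions",
    "CnvCall",
    "normal_cdf",
    "emissions",
    "viterbi",
    "segment_calls",
    "score_call",
]

# State indices, fixed throughout.
DEL, NORM, DUP = 0, 1, 2
STATE_NAMES = ("DEL", "NORM", "DUP")
# Tie-break preference at equal score: NORM first, then DEL, then DUP.
_PREFERENCE = np.array([NORM, DEL, DUP])

_P_MIN, _P_MAX = 1e-300, 1.0 - 1e-16


@dataclass(frozen=True)
class HmmConfig:
    """Transition probability and calling mode of the 3-state HMM."""

    transition_prob: float = 1e-5
    mosaic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.transition_prob < 0.5:
            raise ValueError("transition probability must lie in (0, 0.5)")


@dataclass
class Emissions:
    """One-sided tail probabilities per cell; not a partition of unity.

    Stored as log probabilities so that the ordering of deeply underflowing
    tails survives: comparing P(d<=0.5) with P(d<=1) at small sigma is what
    gates non-mosaic calls, and both can be far below float-min.
    """

    log_p_del: np.ndarray
    log_p_norm: np.ndarray
    log_p_dup: np.ndarray

    @property
    def p_del(self) -> np.ndarray:
        return np.clip(np.exp(self.log_p_del), _P_MIN, _P_MAX)

    @property
    def p_norm(self) -> np.ndarray:
        return np.clip(np.exp(self.log_p_norm), _P_MIN, _P_MAX)

    @property
    def p_dup(self) -> np.ndarray:
        return np.clip(np.exp(self.log_p_dup), _P_MIN, _P_MAX)

    def stacked(self) -> np.ndarray:
        """(..., 3) probability array ordered (DEL, NORM, DUP)."""
        return np.stack([self.p_del, self.p_norm, self.p_dup], axis=-1)

    def log_stacked(self) -> np.ndarray:
        """(..., 3) log-probability array ordered (DEL, NORM, DUP)."""
        return np.stack([self.log_p_del, self.log_p_norm, self.log_p_dup], axis=-1)


def normal_cdf(z) -> np.ndarray:
    """Standard normal CDF, clamped away from 0 and 1 for log safety."""
    return np.clip(ndtr(np.asarray(z, dtype=float)), _P_MIN, _P_MAX)


def emissions(d, sigma, mosaic: bool = False) -> Emissions:
    """Tail probabilities of each copy-number hypothesis given (d, sigma)."""
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if mosaic:
        lp_del = log_ndtr((1.0 - d) / sigma)
        lp_dup = log_ndtr((d - 1.0) / sigma)
    else:
        lp_del = log_ndtr((0.5 - d) / sigma)
        lp_dup = log_ndtr((d - 1.5) / sigma)
    lp_norm = log_ndtr(-np.abs(d - 1.0) / sigma)
    return Emissions(log_p_del=lp_del, log_p_norm=lp_norm, log_p_dup=lp_dup)


def _log_transition(t: float) -> np.ndarray:
    stay = np.log1p(-2.0 * t)
    switch = np.log(t)
    M = np.full((3, 3), switch)
    np.fill_diagonal(M, stay)
    return M


def _argmax_pref(scores: np.ndarray) -> np.ndarray:
    """Argmax over the last axis with NORM > DEL > DUP preference at ties."""
    reordered = scores[..., _PREFERENCE]
    return _PREFERENCE[np.argmax(reordered, axis=-1)]


def viterbi(
    emission_probs: np.ndarray,
    config: HmmConfig = HmmConfig(),
    *,
    log: bool = False,
) -> np.ndarray:
    """Maximum-a-posteriori state path for one emission sequence.

    ``emission_probs`` is (n_bins, 3) ordered (DEL, NORM, DUP); the initial
    distribution is (t, 1-2t, t) and the transition matrix has stay
    probability 1-2t.  Computed in log space; ties break toward NORM, then
    DEL.
    """
    paths = viterbi_batch(np.asarray(emission_probs)[None], config, log=log)
    return paths[0]


def viterbi_batch(
    emission_probs: np.ndarray,
    config: HmmConfig = HmmConfig(),
    *,
    log: bool = False,
) -> np.ndarray:
    """Viterbi over a batch of sequences sharing one transition model.

    ``emission_probs`` is (n_seq, n_bins, 3); returns (n_seq, n_bins) int
    state paths.  Vectorized over sequences, which is what makes whole-cohort
    calling cheap.  With ``log=True`` the input is taken as log emission
    weights directly, preserving the ordering of underflowing tails.
    """
    em = np.asarray(emission_probs, dtype=float)
    if em.ndim != 3 or em.shape[-1] != 3:
        raise ValueError("emission_probs must be (n_seq, n_bins, 3)")
    n_seq, n_bins, _ = em.shape
    if n_bins == 0:
        raise ValueError("empty emission sequence")
    log_em = em if log else np.log(np.clip(em, _P_MIN, None))
    t = config.transition_prob
    log_T = _log_transition(t)  # [prev, cur]
    log_init = np.log(np.array([t, 1.0 - 2.0 * t, t]))

    V = log_init[None, :] + log_em[:, 0, :]  # (n_seq, 3)
    back = np.empty((n_seq, n_bins, 3), dtype=np.int8)
    for i in range(1, n_bins):
        cand = V[:, :, None] + log_T[None, :, :]  # (n_seq, prev, cur)
        best_prev = _argmax_pref(np.swapaxes(cand, 1, 2))  # (n_seq, cur)
        back[:, i, :] = best_prev
        V = np.take_along_axis(cand, best_prev[:, None, :], axis=1)[:, 0, :] + log_em[:, i, :]

    states = np.empty((n_seq, n_bins), dtype=np.int64)
    states[:, -1] = _argmax_pref(V)
    for i in range(n_bins - 1, 0, -1):
        states[:, i - 1] = np.take_along_axis(
            back[:, i, :], states[:, i][:, None], axis=1
        )[:, 0]
    return states


@dataclass
class CnvCall:
    """One called deletion or duplication event."""

    sample_id: str
    chrom: str
    start: int  # 0-based half-open, bin-aligned
    end: int
    type: str  # "DEL" or "DUP"
    n_bins: int  # active bins supporting the call
    mean_dosage: float
    quality: float  # phred-like, >= 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call end must exceed start")
        if self.type not in ("DEL", "DUP"):
            raise ValueError(f"invalid call type {self.type!r}")
        if self.n_bins < 1:
            raise ValueError("call must be supported by at least one active bin")

    @property
    def size(self) -> int:
        return self.end - self.start


def segment_calls(
    path: np.ndarray,
    dosage: np.ndarray,
    log_ratio: np.ndarray,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    chrom: str,
    sample_id: str,
) -> list[CnvCall]:
    """Turn one chromosome's Viterbi path into calls.

    Arguments are aligned to the chromosome's *active* bins, in genomic
    order.  Maximal runs of DEL (or DUP) become one call each; the call
    spans from the start of its first bin to the end of its last bin, so
    inactive bins interior to a run are spanned but do not count toward
    ``n_bins``.  ``log_ratio`` holds ln p_state - ln p_norm per bin for the
    run's state, from which the phred-like quality is summed.
    """
    calls: list[CnvCall] = []
    n = len(path)
    i = 0
    while i < n:
        state = path[i]
        if state == NORM:
            i += 1
            continue
        j = i
        while j < n and path[j] == state:
            j += 1
        run = slice(i, j)
        quality = max(0.0, (10.0 / np.log(10.0)) * float(log_ratio[run].sum()))
        calls.append(
            CnvCall(
                sample_id=sample_id,
                chrom=chrom,
                start=int(bin_starts[i]),
                end=int(bin_ends[j - 1]),
                type=STATE_NAMES[state],
                n_bins=j - i,
                mean_dosage=float(dosage[run].mean()),
                quality=quality,
            )
        )
        i = j
    return calls


def score_call(call: CnvCall, log_p_state: np.ndarray, log_p_norm: np.ndarray) -> float:
    """Phred-like quality: summed log-likelihood ratio of the call's bins.

    quality = (10/ln 10) * sum(ln p_state - ln p_norm), floored at 0.
    Additive in bins, so longer runs of equal per-bin evidence score
    proportionally higher.
    """
    return max(0.0, (10.0 / np.log(10.0)) * float(np.sum(log_p_state - log_p_norm)))
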