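"""Precision/recall benchmarking of CNV calls against a truth set.

A truth event counts as *detected* if any call of the same sample (and, by
default, the same type) overlaps it by at least one base; a call counts as
*true* if it overlaps any truth event under the same rule.  Recall is the
fraction of truth events detected; precision the fraction of calls that are
true; f is their harmonic mean.  One call spanning two truth events detects
both while counting as a single true call, so TP (true calls) and the number
of detected truths are recorded separately.

The parameter/threshold sweep mirrors the standard caller-comparison
protocol: run the caller over a parameter grid, try every quality cutoff,
and keep the best precision achieved at each attainable recall (the PR
frontier).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .hmm import CnvCall
from .pipeline import call_cnvs, calls_to_frame

__all__ = [
    "MatchResult",
    "PRPoint",
    "match_calls",
    "precision_recall",
    "boundary_error",
    "pr_frontier",
    "sweep",
    "stratify_by_size",
    "max_recall_at_precision",
]


@dataclass
class MatchResult:
    """Outcome of overlap-matching calls against a truth set."""

    call_is_true: np.ndarray  # bool per call
    truth_detected: np.ndarray  # bool per truth event
    pairs: list[tuple[int, int, int, int]]  # (call_idx, truth_idx, |dstart|, |dend|)

    @property
    def n_calls(self) -> int:
        return len(self.call_is_true)

    @property
    def n_truths(self) -> int:
        return len(self.truth_detected)

    @property
    def tp(self) -> int:
        """Number of true-flagged calls (not the number of detected truths)."""
        return int(self.call_is_true.sum())

    @property
    def fp(self) -> int:
        return self.n_calls - self.tp

    @property
    def fn(self) -> int:
        return self.n_truths - int(self.truth_detected.sum())

    @property
    def n_detected(self) -> int:
        return int(self.truth_detected.sum())


@dataclass
class PRPoint:
    """One precision/recall operating point with its parameter provenance."""

    recall: float
    precision: float | None  # None when zero calls were made
    f: float
    params: dict = field(default_factory=dict)


def _as_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        df = calls.copy()
        if "sample_id" in df.columns and "sample" not in df.columns:
            df = df.rename(columns={"sample_id": "sample"})
        return df
    return calls_to_frame(list(calls))


def match_calls(calls, truth: pd.DataFrame, same_type_required: bool = True) -> MatchResult:
    """Any-overlap matching of calls to truth events, per sample.

    ``calls`` may be a list of `CnvCall` or a BED-like DataFrame; ``truth``
    is a DataFrame with columns sample/chrom/start/end/type.  Coordinates
    are half-open, so abutting intervals do not match.
    """
    cdf = _as_frame(calls).reset_index(drop=True)
    tdf = truth.reset_index(drop=True)
    trees: dict[tuple, IntervalTree] = {}
    for ti, row in tdf.iterrows():
        key = (row["sample"], row["chrom"], row["type"] if same_type_required else None)
        trees.setdefault(key, IntervalTree()).addi(int(row["start"]), int(row["end"]), ti)
    call_is_true = np.zeros(len(cdf), dtype=bool)
    truth_detected = np.zeros(len(tdf), dtype=bool)
    pairs: list[tuple[int, int, int, int]] = []
    for ci, row in cdf.iterrows():
        key = (row["sample"], row["chrom"], row["type"] if same_type_required else None)
        tree = trees.get(key)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(row["start"]), int(row["end"]))):
            ti = hit.data
            call_is_true[ci] = True
            truth_detected[ti] = True
            pairs.append(
                (
                    ci,
                    ti,
                    abs(int(row["start"]) - hit.begin),
                    abs(int(row["end"]) - hit.end),
                )
            )
    return MatchResult(call_is_true=call_is_true, truth_detected=truth_detected, pairs=pairs)


def precision_recall(match: MatchResult, params: dict | None = None) -> PRPoint:
    """Recall, precision and their harmonic mean f for one match result.

    Precision is undefined (None) when no calls were made — never reported
    as 1 — and f is then 0.
    """
    if match.n_truths == 0:
        raise ValueError("truth set is empty: benchmark misconfiguration")
    recall = match.n_detected / match.n_truths
    if match.n_calls == 0:
        return PRPoint(recall=recall, precision=None, f=0.0, params=dict(params or {}))
    precision = match.tp / match.n_calls
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return PRPoint(recall=recall, precision=precision, f=f, params=dict(params or {}))


def boundary_error(match: MatchResult) -> float | None:
    """Mean absolute boundary offset (bp) over both endpoints of all matched
    call/truth pairs; None when nothing matched."""
    if not match.pairs:
        return None
    offsets = [off for _, _, ds, de in match.pairs for off in (ds, de)]
    return float(np.mean(offsets))


def pr_frontier(points: list[PRPoint]) -> list[PRPoint]:
    """Best precision at each attainable recall, dominated points removed.

    Returned sorted by increasing recall; along the frontier precision is
    non-increasing.  Points with undefined precision never enter.
    """
    best: dict[float, PRPoint] = {}
    for p in points:
        if p.precision is None:
            continue
        cur = best.get(p.recall)
        if cur is None or p.precision > cur.precision:
            best[p.recall] = p
    frontier: list[PRPoint] = []
    for p in sorted(best.values(), key=lambda p: (-p.recall, -p.precision)):
        if frontier and p.precision <= frontier[-1].precision:
            continue  # dominated: lower recall and no better precision
        frontier.append(p)
    frontier.reverse()
    return frontier


def _quality_points(calls, truth, params, same_type_required, thresholds=None) -> list[PRPoint]:
    qualities = sorted({c.quality for c in calls})
    if thresholds is None:
        thresholds = [0.0] + qualities
    points = []
    for q in thresholds:
        kept = [c for c in calls if c.quality >= q]
        match = match_calls(kept, truth, same_type_required=same_type_required)
        points.append(precision_recall(match, params={**params, "min_quality": q}))
    return points


def sweep(
    counts,
    truth: pd.DataFrame,
    grid: dict[str, list] | None = None,
    *,
    quality_thresholds: list[float] | None = None,
    same_type_required: bool = True,
) -> tuple[list[PRPoint], list[PRPoint]]:
    """Parameter-grid and quality-cutoff sweep over the caller.

    ``grid`` maps `call_cnvs` keyword names (``n_discard``,
    ``transition_prob``, ``mosaic`` ...) to lists of values; the Cartesian
    product is evaluated.  At each grid point every quality cutoff is tried.
    Returns ``(frontier, all_points)``.
    """
    grid = grid or {}
    keys = list(grid)
    all_points: list[PRPoint] = []
    for combo in itertools.product(*(grid[k] for k in keys)) if keys else [()]:
        params = dict(zip(keys, combo))
        calls = call_cnvs(counts, **params)
        all_points.extend(
            _quality_points(calls, truth, params, same_type_required, quality_thresholds)
        )
    return pr_frontier(all_points), all_points


def stratify_by_size(
    truth: pd.DataFrame, bounds: tuple[int, int] = (1_000_000, 5_000_000)
) -> dict[str, pd.DataFrame]:
    """Partition truth events into size bands (default <1 Mb, 1-5 Mb, >5 Mb).

    Bands are half-open on the left: an event of exactly 1 Mb falls in the
    middle band.  The bands partition the truth set exactly.
    """
    lo, hi = bounds
    size = truth["end"] - truth["start"]
    return {
        f"<{lo // 1_000_000} Mb": truth[size < lo],
        f"{lo // 1_000_000}-{hi // 1_000_000} Mb": truth[(size >= lo) & (size < hi)],
        f">{hi // 1_000_000} Mb": truth[size >= hi],
    }


def max_recall_at_precision(points: list[PRPoint], min_precision: float = 0.5) -> PRPoint | None:
    """Best recall among points with precision >= ``min_precision`` (the
    headline summary used when comparing callers); None if no point
    qualifies."""
    eligible = [p for p in points if p.precision is not None and p.precision >= min_precision]
    if not eligible:
        return None
    return max(eligible, key=lambda p: (p.recall, p.precision))
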