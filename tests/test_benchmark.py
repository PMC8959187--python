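import numpy as np
import pandas as pd
import pytest

import depthcnv as dc
from depthcnv import (
    PRPoint,
    boundary_error,
    match_calls,
    max_recall_at_precision,
    pr_frontier,
    precision_recall,
    stratify_by_size,
    sweep,
)


def truth_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "type"])


def call_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "type"])
    df["n_bins"] = 1
    df["mean_dosage"] = 0.5
    df["quality"] = 10.0
    return df


class TestMatchCalls:
    def test_any_overlap_matches(self):
        calls = call_frame([("1", 100, 200, "S", "DEL")])
        truth = truth_frame([("S", "1", 150, 300, "DEL")])
        m = match_calls(calls, truth)
        assert m.truth_detected[0] and m.call_is_true[0]
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_abutting_intervals_do_not_match(self):
        calls = call_frame([("1", 100, 200, "S", "DEL")])
        truth = truth_frame([("S", "1", 200, 300, "DEL")])
        m = match_calls(calls, truth)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_one_call_spanning_two_truths(self):
        calls = call_frame([("1", 0, 1000, "S", "DEL")])
        truth = truth_frame(
            [("S", "1", 100, 200, "DEL"), ("S", "1", 700, 900, "DEL")]
        )
        m = match_calls(calls, truth)
        assert m.n_detected == 2 and m.tp == 1

    def test_type_and_sample_must_agree(self):
        calls = call_frame(
            [("1", 100, 200, "S", "DUP"), ("1", 100, 200, "other", "DEL")]
        )
        truth = truth_frame([("S", "1", 100, 200, "DEL")])
        assert match_calls(calls, truth).n_detected == 0
        assert match_calls(calls, truth, same_type_required=False).n_detected == 1


class TestPrecisionRecall:
    def test_half_precision_full_recall(self):
        calls = call_frame(
            [("1", 100, 200, "S", "DEL"), ("1", 5000, 6000, "S", "DEL")]
        )
        truth = truth_frame([("S", "1", 150, 300, "DEL")])
        p = precision_recall(match_calls(calls, truth))
        assert (p.precision, p.recall) == (0.5, 1.0)
        assert p.f == pytest.approx(2 / 3)

    def test_zero_calls_precision_undefined(self):
        truth = truth_frame([("S", "1", 150, 300, "DEL")])
        p = precision_recall(match_calls(call_frame([]), truth))
        assert p.precision is None and p.recall == 0.0 and p.f == 0.0

    def test_zero_truths_is_an_error(self):
        with pytest.raises(ValueError):
            precision_recall(match_calls(call_frame([]), truth_frame([])))

    def test_panel_operating_point_f(self):
        """The harmonic mean of precision 0.788 and recall 0.976 is ~0.872."""
        p, r = 0.788, 0.976
        assert 2 * p * r / (p + r) == pytest.approx(0.872, abs=5e-4)


class TestBoundaryError:
    def test_exact_match_zero(self):
        calls = call_frame([("1", 100, 300, "S", "DEL")])
        truth = truth_frame([("S", "1", 100, 300, "DEL")])
        assert boundary_error(match_calls(calls, truth)) == 0.0

    def test_one_bin_shift(self):
        calls = call_frame([("1", 200_000, 1_200_000, "S", "DEL")])
        truth = truth_frame([("S", "1", 0, 1_000_000, "DEL")])
        assert boundary_error(match_calls(calls, truth)) == 200_000.0

    def test_no_matches_is_missing(self):
        truth = truth_frame([("S", "1", 100, 300, "DEL")])
        assert boundary_error(match_calls(call_frame([]), truth)) is None


class TestFrontier:
    def test_single_point(self):
        pts = [PRPoint(recall=0.5, precision=0.8, f=0.61)]
        assert pr_frontier(pts) == pts

    def test_dominated_point_excluded(self):
        a = PRPoint(recall=0.9, precision=0.8, f=0.85)
        b = PRPoint(recall=0.5, precision=0.6, f=0.55)  # worse on both axes
        c = PRPoint(recall=0.5, precision=0.95, f=0.65)
        frontier = pr_frontier([a, b, c])
        assert frontier == [c, a]

    def test_frontier_precision_non_increasing_in_recall(self):
        rng = np.random.default_rng(3)
        pts = [
            PRPoint(recall=float(r), precision=float(p), f=0.0)
            for r, p in rng.uniform(0, 1, size=(200, 2)).round(2)
        ]
        frontier = pr_frontier(pts)
        recalls = [p.recall for p in frontier]
        precisions = [p.precision for p in frontier]
        assert recalls == sorted(recalls)
        assert precisions == sorted(precisions, reverse=True)

    def test_undefined_precision_never_enters(self):
        pts = [PRPoint(recall=0.0, precision=None, f=0.0)]
        assert pr_frontier(pts) == []


def test_stratification_partitions_truths():
    truth = pd.DataFrame(
        {
            "sample": ["S"] * 4,
            "chrom": ["1"] * 4,
            "start": [0, 0, 0, 0],
            "end": [500_000, 1_000_000, 4_999_999, 8_000_000],
            "type": ["DEL"] * 4,
        }
    )
    bands = stratify_by_size(truth)
    sizes = [len(df) for df in bands.values()]
    assert sizes == [1, 2, 1]
    assert sum(sizes) == len(truth)


@pytest.fixture(scope="module")
def bias_cohort():
    cfg = dc.SimulationConfig(
        n_samples=60, chromosomes=(("1", 200_000_000),),
        bias_rank=3, bias_sd=0.1, seed=11,
    )
    cfg = dc.plant_random_cnvs(cfg, n_del=6, n_dup=6, min_bins=6, max_bins=15)
    return dc.simulate_cohort(cfg)


class TestSweep:
    def test_single_grid_point_single_threshold(self, bias_cohort):
        cov, truth = bias_cohort
        frontier, pts = sweep(cov, truth, {"n_discard": [5]}, quality_thresholds=[0.0])
        assert len(pts) == 1
        assert frontier == [p for p in pts if p.precision is not None]

    def test_svd_improves_best_f_on_biased_cohort(self, bias_cohort):
        """Discarding singular vectors removes shared batch bias: the PR
        frontier with denoising strictly beats the frontier without it."""
        cov, truth = bias_cohort
        _, pts_on = sweep(cov, truth, {"n_discard": [5]})
        _, pts_off = sweep(cov, truth, {"n_discard": [0]})
        assert max(p.f for p in pts_on) > max(p.f for p in pts_off)

    def test_provenance_recorded(self, bias_cohort):
        cov, truth = bias_cohort
        frontier, _ = sweep(cov, truth, {"n_discard": [5]})
        assert all(p.params["n_discard"] == 5 and "min_quality" in p.params for p in frontier)


def test_multiplicative_error_model_beats_poisson_on_hypervariable_bins():
    """Hypervariable loci violate the Poisson noise assumption; modelling
    the per-bin error removes their false calls at unchanged recall."""
    cfg = dc.SimulationConfig(
        n_samples=60, chromosomes=(("1", 200_000_000),), bias_rank=0,
        hypervariable_fraction=0.02, hypervariable_noise_sd=0.5, seed=13,
    )
    cfg = dc.plant_random_cnvs(cfg, n_del=5, n_dup=5, min_bins=8, max_bins=15)
    cov, truth = dc.simulate_cohort(cfg)
    m_mult = dc.match_calls(dc.call_cnvs(cov, error_model="multiplicative"), truth)
    m_pois = dc.match_calls(dc.call_cnvs(cov, error_model="poisson"), truth)
    assert m_mult.n_detected >= m_pois.n_detected  # matched (or better) recall
    assert m_mult.fp < m_pois.fp


def test_detection_power_grows_with_cohort_size():
    """Max f over quality cutoffs is non-decreasing from 7 to 50 samples,
    within simulation noise: small batches cannot support the denoising and
    error estimation."""
    best_f = []
    for i, n in enumerate((7, 15, 30, 50)):
        cfg = dc.SimulationConfig(
            n_samples=n, chromosomes=(("1", 160_000_000),), seed=20 + i
        )
        cfg = dc.plant_random_cnvs(cfg, n_del=3, n_dup=3, min_bins=6, max_bins=12)
        cov, truth = dc.simulate_cohort(cfg)
        _, pts = sweep(cov, truth, {})
        best_f.append(max(p.f for p in pts))
    assert all(b >= a - 0.1 for a, b in zip(best_f, best_f[1:]))
    assert best_f[-1] >= best_f[0]
    assert best_f[-1] >= 0.8


def test_boundary_error_within_half_bin_on_aligned_truth():
    cfg = dc.SimulationConfig(
        n_samples=60, chromosomes=(("1", 200_000_000),), seed=23
    )
    cfg = dc.plant_random_cnvs(cfg, n_del=6, n_dup=6, min_bins=6, max_bins=15)
    cov, truth = dc.simulate_cohort(cfg)
    m = dc.match_calls(dc.call_cnvs(cov), truth)
    err = boundary_error(m)
    assert err is not None and err <= cfg.bin_size / 2


def test_max_recall_at_precision_summary():
    pts = [
        PRPoint(recall=0.9, precision=0.4, f=0.55),
        PRPoint(recall=0.7, precision=0.6, f=0.65),
        PRPoint(recall=0.5, precision=0.9, f=0.64),
    ]
    best = max_recall_at_precision(pts, 0.5)
    assert best.recall == 0.7
    assert max_recall_at_precision(pts, 0.99) is None
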