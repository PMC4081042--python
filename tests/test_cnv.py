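"""Read-depth CNVR caller: windows, ratio statistic, merging, summaries."""

import numpy as np
import pandas as pd
import pytest

from bovivar import CNVParams, GenomeLayout, call_cnvrs, make_windows, score_windows, \
    summarize_cnvrs, window_statistic
from bovivar.cnv import GAIN, LOSS, cnvrs_to_frame, min_window_length


@pytest.fixture
def ten_mb() -> GenomeLayout:
    return GenomeLayout(("1",), (10_000_000,))


def _scored(chrom, log2s, ps, wlen=10_000):
    starts = np.arange(len(log2s)) * (wlen // 2)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + wlen,
                         "log2": log2s, "p": ps})


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def test_make_windows_no_reads(ten_mb):
    w = make_windows({}, {}, ten_mb, 10_000)
    assert (w["test"] == 0).all() and (w["ref"] == 0).all()
    # half-overlap: stride is half the window length
    assert (np.diff(w["start"]) == 5_000).all()


def test_single_read_in_at_most_two_windows(ten_mb):
    w = make_windows({"1": np.array([123_456])}, {}, ten_mb, 10_000)
    hits = w[w["test"] > 0]
    assert 1 <= len(hits) <= 2
    assert (hits["test"] == 1).all()
    for _, row in hits.iterrows():
        assert row.start <= 123_455 < row.end  # 0-based containment


def test_window_counts_poisson_dispersion(ten_mb):
    rng = np.random.default_rng(8)
    n = 100_000
    pos = rng.integers(1, 10_000_001, n)
    w = make_windows({"1": pos}, {}, ten_mb, 10_000)
    inner = w.iloc[1:-2]  # full-length windows
    lam = n * 10_000 / 10_000_000
    assert inner["test"].mean() == pytest.approx(lam, rel=0.02)
    # index of dispersion ~ 1 for Poisson
    assert inner["test"].var() / inner["test"].mean() == pytest.approx(1.0, abs=0.1)


def test_window_length_validation(ten_mb):
    with pytest.raises(ValueError):
        make_windows({}, {}, ten_mb, 1)


def test_min_window_length_scales_with_totals():
    p = CNVParams()
    w1 = min_window_length(1_000_000, 1_000_000, 50_000_000, p)
    w2 = min_window_length(2_000_000, 2_000_000, 50_000_000, p)
    assert w2 < w1  # more reads allow smaller windows
    # lambda implied by the minimum window covers the detection boundary
    lam = 1_000_000 * w1 / 50_000_000
    assert 80 < lam < 130


# ---------------------------------------------------------------------------
# the ratio statistic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["exact-midp", "gh"])
def test_null_center(method):
    log2, p, corrected = window_statistic([100], [100], 100.0, 100.0, method)
    assert log2[0] == 0.0
    assert p[0] == pytest.approx(1.0)
    assert not corrected[0]


def test_unequal_totals_normalization():
    # test sample sequenced twice as deep: equal rates give counts 200 vs 100
    log2, p, _ = window_statistic([200], [100], 200.0, 100.0)
    assert log2[0] == 0.0
    assert p[0] > 0.95  # mid-p at an asymmetric theta is close to, not exactly, 1
    log2_gh, p_gh, _ = window_statistic([200], [100], 200.0, 100.0, method="gh")
    assert log2_gh[0] == 0.0 and p_gh[0] == pytest.approx(1.0)


def test_zero_count_continuity_correction():
    log2, p, corrected = window_statistic([0], [100], 100.0, 100.0)
    assert corrected[0]
    assert np.isfinite(log2[0]) and log2[0] < -5


def test_null_calibration_quick():
    rng = np.random.default_rng(2)
    x = rng.poisson(100, 200_000)
    y = rng.poisson(100, 200_000)
    _, p, _ = window_statistic(x, y, 100.0, 100.0)
    frac = (p < 0.01).mean()
    se = np.sqrt(0.01 * 0.99 / x.size)
    assert abs(frac - 0.01) < 4 * se


def test_doubled_rate_log2_centers_on_one():
    rng = np.random.default_rng(3)
    x = rng.poisson(400, 50_000)
    y = rng.poisson(200, 50_000)
    log2, _, _ = window_statistic(x, y, 200.0, 200.0)
    assert np.median(log2) == pytest.approx(1.0, abs=0.05)


def test_swap_symmetry():
    rng = np.random.default_rng(4)
    x = rng.poisson(150, 10_000)
    y = rng.poisson(100, 10_000)
    l1, p1, _ = window_statistic(x, y, 120.0, 120.0)
    l2, p2, _ = window_statistic(y, x, 120.0, 120.0)
    np.testing.assert_allclose(l1, -l2, atol=1e-12)
    np.testing.assert_allclose(p1, p2, atol=1e-12)


# ---------------------------------------------------------------------------
# CNVR merging
# ---------------------------------------------------------------------------

def test_nine_windows_no_cnvr_ten_windows_one():
    for n, expected in ((9, 0), (10, 1)):
        scored = _scored("1", [1.0] * n, [1e-6] * n)
        cnvrs = call_cnvrs(scored)
        assert len(cnvrs) == expected
    c = call_cnvrs(_scored("1", [1.0] * 10, [1e-6] * 10))[0]
    assert c.n_windows == 10
    assert c.direction == GAIN
    assert (c.start, c.end) == (0, 9 * 5_000 + 10_000)


def test_alternating_signs_break_runs():
    log2s = [1.0 if i % 2 == 0 else -1.0 for i in range(40)]
    assert call_cnvrs(_scored("1", log2s, [1e-6] * 40)) == []


def test_runs_do_not_cross_chromosomes():
    a = _scored("1", [1.0] * 6, [1e-6] * 6)
    b = _scored("2", [1.0] * 6, [1e-6] * 6)
    assert call_cnvrs(pd.concat([a, b], ignore_index=True)) == []


def test_subthreshold_window_breaks_a_run():
    log2s = [1.0] * 25
    ps = [1e-6] * 25
    ps[12] = 0.5  # non-significant window splits the run into 12 + 12
    cnvrs = call_cnvrs(_scored("1", log2s, ps))
    assert [c.n_windows for c in cnvrs] == [12, 12]


def test_loss_direction():
    c = call_cnvrs(_scored("1", [-1.0] * 10, [1e-6] * 10))[0]
    assert c.direction == LOSS


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summary_hand_arithmetic(ten_mb):
    from bovivar.cnv import CNVR
    cnvrs = [CNVR("1", 0, 10_000, GAIN, 10, 1.0, 1e-9),
             CNVR("1", 50_000, 80_000, LOSS, 12, -1.1, 1e-9),
             CNVR("1", 200_000, 220_000, GAIN, 11, 0.9, 1e-9)]
    s = summarize_cnvrs(cnvrs, ten_mb)
    row = s["per_chromosome"].loc["1"]
    assert row["count"] == 3
    assert row["total_bp"] == 60_000
    assert row["mean_length"] == pytest.approx(20_000)
    assert row["median_length"] == 20_000
    assert (row["min_length"], row["max_length"]) == (10_000, 30_000)
    assert s["direction"] == {GAIN: 2, LOSS: 1}
    assert s["genome_fraction"] == pytest.approx(0.006)


def test_summary_empty(ten_mb):
    s = summarize_cnvrs([], ten_mb)
    assert s["total_count"] == 0 and s["genome_fraction"] == 0.0


def test_summary_partitions_across_chromosomes():
    from bovivar import SimulationConfig, simulate_depth_tracks
    from bovivar.synthetic import CnvSegment
    cfg = SimulationConfig(seed=9, cnv_segments=(
        CnvSegment("1", 1_000_000, 2_505_000, 2.0),
        CnvSegment("3", 4_000_000, 5_505_000, 0.4),
    ))
    dep = simulate_depth_tracks(cfg)
    scored = score_windows(dep.windows, dep.total_reads, dep.total_reads, cfg.layout)
    cnvrs = call_cnvrs(scored)
    s = summarize_cnvrs(cnvrs, cfg.layout)
    assert s["per_chromosome"]["count"].sum() == s["total_count"] == len(cnvrs)
    assert {c.chrom for c in cnvrs} == {"1", "3"}
    directions = {c.chrom: c.direction for c in cnvrs}
    assert directions["1"] == GAIN and directions["3"] == LOSS


def test_determinism(ten_mb):
    rng = np.random.default_rng(5)
    pos = {"1": rng.integers(1, 10_000_001, 50_000)}
    w1 = make_windows(pos, pos, ten_mb, 10_000)
    s1 = score_windows(w1, 50_000, 50_000, ten_mb)
    s2 = score_windows(make_windows(pos, pos, ten_mb, 10_000), 50_000, 50_000, ten_mb)
    pd.testing.assert_frame_equal(s1, s2)
    assert cnvrs_to_frame(call_cnvrs(s1)).equals(cnvrs_to_frame(call_cnvrs(s2)))
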