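"""Event counting, pooled rates, bootstrap and recovery scoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gqkinetics.fret import FretTrace
from gqkinetics.kinetics import (
    BootstrapResult,
    EventDetectionParams,
    MoleculeEventRecord,
    bootstrap_mean_rate,
    count_events_batch,
    count_unfolding_events,
    relative_rate,
    score_event_recovery,
    summarize_condition,
)
from gqkinetics.simulate import TraceGroundTruth

from oracles import count_events_regex

SYMBOL_E = {"l": 0.30, "m": 0.50, "h": 0.70}


def trace_from_symbols(symbols: str, frame_interval: float = 0.05) -> FretTrace:
    e = np.array([SYMBOL_E[s] for s in symbols])
    return FretTrace("sym", e, frame_interval, observation_end_frame=len(e))


@pytest.mark.parametrize(
    "symbols, mode, expected",
    [
        ("h" * 20, "at_dip", 0),                      # never dips
        ("h" * 10 + "l" * 5 + "h" * 10 + "l" * 5 + "h" * 5, "at_dip", 2),
        ("h" * 10 + "l" * 5 + "h" * 10 + "l" * 5 + "h" * 5, "full_cycle", 2),
        ("h" * 10 + "l" + "h" * 10, "at_dip", 0),     # single-frame dip excluded
        ("l" * 5 + "m" * 5, "at_dip", 0),             # never arms
        ("h" * 5 + "l" * 5, "at_dip", 1),             # bleach ends trace mid-dip
        ("h" * 5 + "l" * 5, "full_cycle", 0),         # strict signature needs the rise
        ("hmmlmlml", "at_dip", 0),                    # band wander, runs broken
        ("hllmllh", "at_dip", 1),                     # one dip, no double count
    ],
)
def test_event_counter_hand_examples(symbols, mode, expected):
    params = EventDetectionParams(count_mode=mode)
    n, frames = count_unfolding_events(trace_from_symbols(symbols), params)
    assert n == expected
    assert len(frames) == expected


def test_event_frames_mark_dip_start_or_rise():
    symbols = "hhhh" + "llll" + "hhh"
    n, frames = count_unfolding_events(
        trace_from_symbols(symbols), EventDetectionParams(count_mode="at_dip")
    )
    assert n == 1 and frames.tolist() == [4]
    n, frames = count_unfolding_events(
        trace_from_symbols(symbols), EventDetectionParams(count_mode="full_cycle")
    )
    assert n == 1 and frames.tolist() == [8]


def test_undefined_frames_are_skipped_without_state_change():
    e = np.array([0.7, np.nan, 0.3, np.nan, 0.3, 0.7])
    ft = FretTrace("nan", e, 0.05, observation_end_frame=6)
    n, _ = count_unfolding_events(ft, EventDetectionParams(min_dwell_frames=2))
    assert n == 1  # the dwell run continues across the NaN frame


def test_observation_window_truncates_detection():
    ft = trace_from_symbols("hhhhllllhhhh")
    ft.observation_end_frame = 5  # window ends one frame into the dip
    n, _ = count_unfolding_events(ft, EventDetectionParams(min_dwell_frames=2))
    assert n == 0


@given(
    symbols=st.text(alphabet="lmh", min_size=1, max_size=40),
    min_dwell=st.integers(1, 3),
    mode=st.sampled_from(["at_dip", "full_cycle"]),
)
def test_event_counter_matches_regex_oracle(symbols, min_dwell, mode):
    params = EventDetectionParams(min_dwell_frames=min_dwell, count_mode=mode)
    n, _ = count_unfolding_events(trace_from_symbols(symbols), params)
    assert n == count_events_regex(symbols, min_dwell, mode)


@given(symbols=st.text(alphabet="lmh", min_size=1, max_size=40))
def test_raising_low_threshold_never_decreases_count(symbols):
    e = np.array([SYMBOL_E[s] for s in symbols])
    counts = []
    for low in (0.25, 0.35, 0.45):  # 0.25 < e_low, so fewer frames qualify as dips
        ft = FretTrace("sym", e, 0.05, observation_end_frame=len(e))
        n, _ = count_unfolding_events(ft, EventDetectionParams(low_threshold=low))
        counts.append(n)
    assert counts == sorted(counts)


def test_batch_counter_agrees_with_single_trace(rng):
    e = rng.choice([0.30, 0.50, 0.70], size=(50, 30))
    counts, events = count_events_batch(e)
    for i in range(50):
        ft = FretTrace(f"m{i}", e[i], 0.05, observation_end_frame=30)
        n, frames = count_unfolding_events(ft)
        assert n == counts[i]
        assert np.array_equal(frames, np.nonzero(events[i])[0])


def test_detection_params_validation():
    with pytest.raises(ValueError):
        EventDetectionParams(low_threshold=0.6, high_threshold=0.5)
    with pytest.raises(ValueError):
        EventDetectionParams(min_dwell_frames=0)
    with pytest.raises(ValueError):
        EventDetectionParams(count_mode="bogus")


# ---------------------------------------------------------------- rates


def test_record_rate_is_events_over_time():
    r = MoleculeEventRecord("m", 3, 54.3)
    assert r.rate == 3 / 54.3
    with pytest.raises(ValueError):
        MoleculeEventRecord("m", 1, 0.0)


def test_pooled_rate_pools_events_over_total_time():
    records = [
        MoleculeEventRecord("a", 3, 54.3),
        MoleculeEventRecord("b", 0, 100.0),  # zero-event traces contribute time only
        MoleculeEventRecord("c", 5, 45.7),
    ]
    est = summarize_condition(records, "demo")
    assert est.n_events == 8
    assert est.total_time == pytest.approx(200.0)
    assert est.pooled_rate == pytest.approx(8 / 200.0)
    assert est.mean_of_rates == pytest.approx(np.mean([r.rate for r in records]))


def test_pooled_rate_is_time_weighted_mean_of_rates(rng):
    records = [
        MoleculeEventRecord(f"m{i}", int(n), float(t))
        for i, (n, t) in enumerate(zip(rng.poisson(3, 40), rng.uniform(10, 200, 40)))
    ]
    est = summarize_condition(records, "x")
    t = np.array([r.observation_time for r in records])
    r = np.array([r.rate for r in records])
    assert est.pooled_rate == pytest.approx(np.sum(t * r) / np.sum(t))


def test_summarize_condition_rejects_empty():
    with pytest.raises(ValueError):
        summarize_condition([], "empty")


def test_all_zero_event_records_give_zero_rate():
    records = [MoleculeEventRecord(f"m{i}", 0, 30.0) for i in range(5)]
    assert summarize_condition(records, "quiet").pooled_rate == 0.0


# ---------------------------------------------------------------- bootstrap


def test_bootstrap_degenerate_distribution():
    records = [MoleculeEventRecord(f"m{i}", 2, 20.0) for i in range(10)]
    res = bootstrap_mean_rate(records, n_boot=500, seed=1)
    assert res.gaussian_sd == 0.0
    assert res.empirical_sd == 0.0
    assert res.ci_low == res.ci_high == pytest.approx(0.1)
    assert np.all(res.resampled_means == 0.1)


def test_bootstrap_two_molecule_enumeration():
    # Exact enumeration: resamples of {0, 0.1} give means {0, .05, .1} with
    # probabilities {1/4, 1/2, 1/4}; sd = sqrt(0.00125) = 0.035355.
    res = bootstrap_mean_rate(np.array([0.0, 0.1]), n_boot=20000, seed=9)
    values, counts = np.unique(np.round(res.resampled_means, 10), return_counts=True)
    assert values.tolist() == [0.0, 0.05, 0.1]
    for p, c in zip([0.25, 0.5, 0.25], counts):
        se = np.sqrt(20000 * p * (1 - p))
        assert abs(c - 20000 * p) < 3 * se
    assert res.empirical_sd == pytest.approx(np.sqrt(0.00125), rel=0.02)


def test_bootstrap_sd_follows_clt(rng):
    rates = rng.exponential(0.05, size=500)
    res = bootstrap_mean_rate(rates, n_boot=20000, seed=11)
    expected = rates.std(ddof=1) / np.sqrt(500)
    assert res.gaussian_sd == pytest.approx(expected, rel=0.05)
    assert res.gaussian_mean == pytest.approx(rates.mean(), rel=0.01)
    assert res.ci_low <= res.gaussian_mean <= res.ci_high


def test_bootstrap_reproducible_and_validated():
    rates = np.array([0.0, 0.05, 0.1, 0.2])
    a = bootstrap_mean_rate(rates, n_boot=200, seed=5)
    b = bootstrap_mean_rate(rates, n_boot=200, seed=5)
    assert np.array_equal(a.resampled_means, b.resampled_means)
    with pytest.raises(ValueError):
        bootstrap_mean_rate(np.array([0.1]), n_boot=10, seed=0)


# ---------------------------------------------------------------- relative rate


def test_relative_rate_identity_and_scaling():
    est = summarize_condition([MoleculeEventRecord("a", 5, 100.0)], "ref")
    rel = relative_rate(est, est)
    assert rel.relative_rate == pytest.approx(1.0)

    lig = summarize_condition([MoleculeEventRecord("b", 2, 100.0)], "lig")
    boot_l = bootstrap_mean_rate(np.array([0.01, 0.03]), n_boot=100, seed=1)
    boot_r = bootstrap_mean_rate(np.array([0.04, 0.06]), n_boot=100, seed=2)
    rel = relative_rate(lig, est, boot_l, boot_r)
    assert rel.relative_rate == pytest.approx(0.4)
    assert np.allclose(
        rel.relative_distribution, boot_l.resampled_means / boot_r.gaussian_mean
    )


def test_relative_rate_requires_positive_reference():
    zero = summarize_condition([MoleculeEventRecord("a", 0, 10.0)], "ref")
    lig = summarize_condition([MoleculeEventRecord("b", 1, 10.0)], "lig")
    with pytest.raises(ValueError):
        relative_rate(lig, zero)


# ---------------------------------------------------------------- recovery scoring


def _truth(events_and_dwells, frame_interval=0.05, duration=10.0):
    path = []
    t = 0.0
    events = []
    for start, dwell in events_and_dwells:
        path.append(("folded", t, start))
        path.append(("unfolded", start, start + dwell))
        events.append(start)
        t = start + dwell
    path.append(("folded", t, duration))
    return TraceGroundTruth("m", "parallel", path, events, None, None)


def test_recovery_perfect_and_empty_conventions():
    truth = _truth([(1.0, 0.5), (3.0, 0.5)])
    det = [int(1.0 / 0.05), int(3.0 / 0.05)]
    assert score_event_recovery(det, truth, 0.05, tolerance=2) == (1.0, 1.0)
    # no detections, true events exist -> precision 1.0 by convention, recall 0
    assert score_event_recovery([], truth, 0.05, tolerance=2) == (1.0, 0.0)
    # spurious detection, no true events -> precision 0, recall 1.0
    empty = _truth([])
    assert score_event_recovery([10], empty, 0.05, tolerance=2) == (0.0, 1.0)


def test_recovery_greedy_matching_is_one_to_one():
    truth = _truth([(1.0, 0.5)])
    # two detections near one true event: only one can match
    p, r = score_event_recovery([19, 21], truth, 0.05, tolerance=3)
    assert r == 1.0 and p == pytest.approx(0.5)


def test_recovery_dwell_filter_drops_short_events():
    truth = _truth([(1.0, 0.05), (3.0, 1.0)])  # first dwell is one frame
    det = [int(3.0 / 0.05)]
    p, r = score_event_recovery(det, truth, 0.05, tolerance=2, min_dwell_frames=3)
    assert (p, r) == (1.0, 1.0)
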