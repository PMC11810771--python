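"""Agent logic: split statistics, the five delay-management closed forms,
delay-recurrence probability, fuzzy matching and the selection policy."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import liquidengine as lqe
from liquidengine.errors import (
    DegenerateStatisticsError,
    InsufficientDataError,
    InvalidTimeError,
    NoBenchmarkError,
    NoImplementationError,
)

import oracles
from conftest import seed_history


# ---------------------------------------------------------------------------
# split statistics
# ---------------------------------------------------------------------------

def test_split_stats_even_example():
    s = lqe.split_stats([1, 2, 3, 4])
    assert (s.fast_average, s.slow_average) == (1.5, 3.5)
    assert s.n == 4


def test_split_stats_constant_times():
    s = lqe.split_stats([5.0] * 4)
    assert s.fast_average == s.slow_average == 5.0
    assert s.fast_stddev == s.slow_stddev == 0.0


def test_split_stats_odd_length_median_goes_fast():
    s = lqe.split_stats([1.0, 2.0, 3.0])
    assert s.fast_average == 1.5  # fast half = [1, 2]
    assert s.slow_average == 3.0


def test_split_stats_matches_sort_and_halve_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        times = rng.uniform(0.001, 10.0, int(rng.integers(2, 51))).tolist()
        s = lqe.split_stats(times)
        fa, fs, sa, ss = oracles.split_stats_lines(times)
        assert (s.fast_average, s.fast_stddev, s.slow_average, s.slow_stddev) == \
            (fa, fs, sa, ss)
        assert s.fast_average <= s.slow_average


def test_split_stats_needs_two():
    with pytest.raises(InsufficientDataError):
        lqe.split_stats([1.0])


# ---------------------------------------------------------------------------
# delay closed forms
# ---------------------------------------------------------------------------

def _stats(fa, fs, sa=10.0, ss=0.0, n=10):
    return lqe.ImplementationStats(fa, fs, sa, ss, n)


def test_detect_delay_strict_threshold():
    assert lqe.detect_delay(1.5, _stats(1.0, 0.1)) is True
    assert lqe.detect_delay(1.4, _stats(1.0, 0.1)) is False  # boundary: strict >
    assert lqe.detect_delay(1.0, _stats(1.0, 0.0)) is False


def test_delay_factor_ratio_and_guard():
    assert lqe.delay_factor(5.0, _stats(2.0, 0.0)) == 2.5
    assert lqe.delay_factor(2.0, _stats(2.0, 0.0)) == 1.0
    with pytest.raises(DegenerateStatisticsError):
        lqe.delay_factor(1.0, _stats(0.0, 0.0))


def test_adjusted_run_time_mixture():
    assert lqe.adjusted_run_time(_stats(2.0, 0.0), 3.0, 0.5) == 4.0
    assert lqe.adjusted_run_time(_stats(2.0, 0.0), 3.0, 0.0) == 2.0
    assert lqe.adjusted_run_time(_stats(2.0, 0.0), 3.0, 1.0) == 6.0


def test_delay_over_two_clauses():
    stats = lqe.ImplementationStats(1.0, 0.1, 3.0, 0.2, 10)
    assert lqe.delay_over(1.05, stats) is True   # below fast avg + fast std
    assert lqe.delay_over(2.5, stats) is True    # below slow avg - slow std
    assert lqe.delay_over(3.5, stats) is False


def test_selection_probabilities_inverse_square():
    d = lqe.selection_probabilities({"A": 1.0, "B": 2.0}).probabilities
    assert d == pytest.approx({"A": 0.8, "B": 0.2})
    assert lqe.selection_probabilities({"only": 3.0}).probabilities == {"only": 1.0}
    uniform = lqe.selection_probabilities({k: 2.0 for k in "abcd"}).probabilities
    assert all(v == pytest.approx(0.25) for v in uniform.values())
    with pytest.raises(InvalidTimeError):
        lqe.selection_probabilities({"A": 0.0})


def test_closed_forms_match_straight_line_oracles_on_random_histories():
    rng = np.random.default_rng(11)
    for _ in range(200):
        times = rng.uniform(1e-4, 5.0, int(rng.integers(2, 51))).tolist()
        s = lqe.split_stats(times)
        measured = float(rng.uniform(0, 10))
        assert lqe.detect_delay(measured, s) == oracles.detect_delay_line(
            measured, s.fast_average, s.fast_stddev
        )
        assert lqe.delay_factor(measured, s) == oracles.delay_factor_line(
            measured, s.fast_average
        )
        p = float(rng.uniform(0, 1))
        f = float(rng.uniform(1, 20))
        assert lqe.adjusted_run_time(s, f, p) == oracles.adjusted_run_time_line(
            s.fast_average, f, p
        )
        assert lqe.delay_over(measured, s) == oracles.delay_over_line(
            measured, s.fast_average, s.fast_stddev, s.slow_average, s.slow_stddev
        )
        adj = {f"i{k}": float(t) for k, t in enumerate(rng.uniform(0.1, 9, 4))}
        assert lqe.selection_probabilities(adj).probabilities == \
            oracles.selection_probabilities_lines(adj)


# ---------------------------------------------------------------------------
# delay recurrence probability
# ---------------------------------------------------------------------------

def test_p_delay_degenerate_histories_use_laplace_rule():
    all_delayed = lqe.DelayState(history=[(i, True) for i in range(10)])
    assert lqe.estimate_p_delay(all_delayed) == pytest.approx(11 / 12)
    none_delayed = lqe.DelayState(history=[(i, False) for i in range(10)])
    assert lqe.estimate_p_delay(none_delayed) == pytest.approx(1 / 12)


def test_p_delay_mixed_history_tracks_trend():
    # delays early, none recently: predicted probability for the next run
    # sits strictly below the overall delay frequency
    early = lqe.DelayState(history=[(i, i < 5) for i in range(20)])
    assert lqe.estimate_p_delay(early) < 5 / 20
    # and the mirrored history sits strictly above it
    late = lqe.DelayState(history=[(i, i >= 15) for i in range(20)])
    assert lqe.estimate_p_delay(late) > 5 / 20


def test_p_delay_requires_history_and_stays_in_unit_interval():
    with pytest.raises(InsufficientDataError):
        lqe.estimate_p_delay(lqe.DelayState())
    rng = np.random.default_rng(13)
    for _ in range(10):
        hist = [(i, bool(rng.integers(0, 2))) for i in range(30)]
        p = lqe.estimate_p_delay(lqe.DelayState(history=hist))
        assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# fuzzy matching
# ---------------------------------------------------------------------------

def test_fuzzy_exact_match_scores_one():
    t = lqe.BenchmarkTable("m")
    t.add("A", (500.0, 500.0, 9.0), 0.1)
    t.add("A", (100.0, 100.0, 9.0), 0.05)
    sig, times, score = lqe.fuzzy_match((500.0, 500.0, 9.0), t)
    assert sig == (500.0, 500.0, 9.0) and score == 1.0
    assert times == {"A": [0.1]}


def test_fuzzy_monotone_dominance():
    t = lqe.BenchmarkTable("m")
    t.add("A", (500.0, 500.0), 0.1)
    t.add("A", (4000.0, 4000.0), 0.9)
    sig, _, _ = lqe.fuzzy_match((512.0, 512.0), t)
    assert sig == (500.0, 500.0)


def test_fuzzy_match_equals_exhaustive_oracle_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(30):
        t = lqe.BenchmarkTable("m")
        cands = [tuple(rng.uniform(1, 1000, 4)) for _ in range(8)]
        for c in cands:
            t.add("A", c, 0.1)
        query = tuple(rng.uniform(1, 1000, 4))
        got, _, got_score = lqe.fuzzy_match(query, t)
        scores = [oracles.fuzzy_score_lines(query, c) for c in t.signatures()]
        best = t.signatures()[int(np.argmax(scores))]
        assert got == best
        assert got_score == pytest.approx(max(scores))


def test_fuzzy_empty_table_is_error():
    with pytest.raises(NoBenchmarkError):
        lqe.fuzzy_match((1.0,), lqe.BenchmarkTable("m"))


def test_fuzzy_zero_feature_membership():
    # zero candidate feature: membership 1 only at exact zero
    t = lqe.BenchmarkTable("m")
    t.add("A", (0.0, 10.0), 0.1)
    t.add("A", (5.0, 10.0), 0.1)
    sig, _, _ = lqe.fuzzy_match((0.0, 10.0), t)
    assert sig == (0.0, 10.0)


# ---------------------------------------------------------------------------
# selection policy
# ---------------------------------------------------------------------------

SIG = (100.0, 100.0)


def test_no_delay_regime_is_deterministic_argmin(two_impl_registry, store, fingerprint):
    seed_history(store, "m", SIG,
                 {"A": [1.0, 1.1, 1.2, 1.0], "B": [5.0, 5.1, 5.2, 5.0]},
                 fingerprint.digest)
    agent = lqe.Agent(two_impl_registry, store, fingerprint=fingerprint)
    for seed in range(25):
        impl, trace = agent.decide("m", SIG, seed=seed)
        assert impl == "A"
        assert trace["mode"] == "deterministic"


def test_delayed_implementation_keeps_positive_probability(
        two_impl_registry, store, fingerprint):
    seed_history(store, "m", SIG, {"A": [2.0] * 6, "B": [2.0] * 6},
                 fingerprint.digest)
    agent = lqe.Agent(two_impl_registry, store, fingerprint=fingerprint)
    agent.delay_states[("m", "A")] = lqe.DelayState(
        delayed=True, delay_factor=50.0, p_delay=1.0)
    _, trace = agent.decide("m", SIG, seed=0)
    assert trace["mode"] == "stochastic"
    assert trace["probabilities"]["A"] > 0.0
    assert sum(trace["probabilities"].values()) == pytest.approx(1.0, abs=1e-12)


def test_stochastic_selection_frequency_matches_distribution(
        two_impl_registry, store, fingerprint):
    # A delayed with adjusted time 4.0, B at 2.0 -> P(A) = 0.2
    seed_history(store, "m", SIG, {"A": [2.0] * 6, "B": [2.0] * 6},
                 fingerprint.digest)
    agent = lqe.Agent(two_impl_registry, store, fingerprint=fingerprint)
    agent.delay_states[("m", "A")] = lqe.DelayState(
        delayed=True, delay_factor=3.0, p_delay=0.5)
    n = 4000
    hits = sum(agent.decide("m", SIG, seed=s)[0] == "A" for s in range(n))
    sd = (0.2 * 0.8 / n) ** 0.5
    assert abs(hits / n - 0.2) < 3 * sd


def test_unavailable_implementations_are_ignored(store, fingerprint):
    reg = lqe.Registry()
    reg.register(lqe.ImplementationEntry("m", "A", lambda: None, available=False))
    reg.register(lqe.ImplementationEntry("m", "B", lambda: None))
    seed_history(store, "m", SIG, {"A": [0.1] * 5, "B": [1.0] * 5},
                 fingerprint.digest)
    agent = lqe.Agent(reg, store, fingerprint=fingerprint)
    impl, _ = agent.decide("m", SIG, seed=0)
    assert impl == "B"  # A is faster but unavailable
    reg2 = lqe.Registry()
    reg2.register(lqe.ImplementationEntry("m", "A", lambda: None, available=False))
    with pytest.raises(NoImplementationError):
        lqe.Agent(reg2, store, fingerprint=fingerprint).decide("m", SIG)


def test_single_available_implementation_always_chosen(store, fingerprint):
    reg = lqe.Registry()
    reg.register(lqe.ImplementationEntry("m", "only", lambda: None))
    seed_history(store, "m", SIG, {"only": [1.0] * 5}, fingerprint.digest)
    agent = lqe.Agent(reg, store, fingerprint=fingerprint)
    assert agent.decide("m", SIG, seed=3)[0] == "only"


def test_selection_monotonic_in_adjusted_time():
    base = {"A": 2.0, "B": 3.0, "C": 5.0}
    p_before = lqe.selection_probabilities(base).probabilities["A"]
    for worse in (2.5, 4.0, 10.0, 100.0):
        probs = lqe.selection_probabilities({**base, "A": worse}).probabilities
        assert probs["A"] < p_before
        p_before = probs["A"]


def test_insufficient_history_falls_back_to_defaults(registry, store, fingerprint):
    # only 2 local records: decision trace shows factory defaults as source
    sig = (100.0, 100.0, 9.0)
    seed_history(store, lqe.CONV2D, sig,
                 {"vectorized": [0.01, 0.011]}, fingerprint.digest)
    agent = lqe.Agent(registry, store, fingerprint=fingerprint)
    _, trace = agent.decide(lqe.CONV2D, sig, seed=0)
    sources = {i: v["source"] for i, v in trace["implementations"].items()}
    assert set(sources.values()) == {"defaults"}
    assert trace["matched_signature"] is not None


def test_foreign_device_history_triggers_defaults(registry, store, fingerprint):
    sig = (100.0, 100.0, 9.0)
    seed_history(store, lqe.CONV2D, sig,
                 {"vectorized": [9.0] * 10, "unthreaded": [1.0] * 10,
                  "threaded": [2.0] * 10}, "foreign-device")
    agent = lqe.Agent(registry, store, fingerprint=fingerprint)
    _, trace = agent.decide(lqe.CONV2D, sig, seed=0)
    assert trace["hardware_changed"] is True
    assert all(v["source"] == "defaults"
               for v in trace["implementations"].values())


def test_decision_overhead_under_50ms(two_impl_registry, store, fingerprint):
    seed_history(store, "m", SIG,
                 {"A": [1.0] * 50, "B": [2.0] * 50}, fingerprint.digest)
    agent = lqe.Agent(two_impl_registry, store, fingerprint=fingerprint)
    agent.decide("m", SIG, seed=0)  # warm caches
    durations = []
    for s in range(20):
        t0 = time.perf_counter()
        agent.decide("m", SIG, seed=s)
        durations.append(time.perf_counter() - t0)
    assert np.median(durations) < 0.05


def test_select_implementation_function(two_impl_registry, store, fingerprint):
    seed_history(store, "m", SIG, {"A": [1.0] * 4, "B": [2.0] * 4},
                 fingerprint.digest)
    impl, trace = lqe.select_implementation("m", SIG, two_impl_registry, store,
                                            rng_seed=0)
    assert impl == "A" and trace["chosen"] == "A"


# ---------------------------------------------------------------------------
# engine round trip: decide -> run -> record -> delay bookkeeping
# ---------------------------------------------------------------------------

def test_engine_records_runs_and_traces(registry, store):
    engine = lqe.Engine(registry, store, base_seed=1)
    img = np.random.default_rng(0).random((32, 32))
    ker = np.ones((3, 3))
    out, trace = engine.run(lqe.CONV2D, img, ker, impl_id="vectorized")
    assert out.shape == img.shape
    assert trace["measured_run_time"] > 0
    sig = lqe.signature_of(lqe.CONV2D, img, ker)
    table = store.build_table(lqe.CONV2D)
    assert table.times_for(sig)["vectorized"]


def test_engine_delay_state_lifecycle(two_impl_registry, store, fingerprint):
    # feed measured times through observe(): delay turns on past the 4-sigma
    # gate and off once a normal time is seen again
    seed_history(store, "m", SIG, {"A": [1.0, 1.0, 1.1, 1.1]}, fingerprint.digest)
    agent = lqe.Agent(two_impl_registry, store, fingerprint=fingerprint)
    _, trace = agent.decide("m", SIG, seed=0)
    agent.observe("m", "A", SIG, measured=8.0, trace=trace)
    state = agent.delay_states[("m", "A")]
    assert state.delayed is True
    assert state.delay_factor == pytest.approx(8.0)
    _, trace = agent.decide("m", SIG, seed=0)
    assert trace["mode"] == "stochastic"
    agent.observe("m", "A", SIG, measured=1.0, trace=trace)
    assert state.delayed is False


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=6, unique=True))
def test_selection_distribution_sums_to_one(times):
    d = lqe.selection_probabilities(
        {f"i{k}": t for k, t in enumerate(times)}
    ).probabilities
    assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(v >= 0 for v in d.values())
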