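"""The supervisor agent: run-time statistics, delay management and selection.

For each implementation the agent splits its recent recorded run times into
a fastest and a slowest half and summarizes each by mean and population
standard deviation (FastAverage/FastStdDev, SlowAverage/SlowStdDev). These
four numbers drive delay management:

* a run is *delayed* when its measured time exceeds
  ``FastAverage + 4 * FastStdDev``;
* a delayed implementation carries a *delay factor*
  ``measured / FastAverage``;
* the probability that the delay recurs on the next run (``p_delay``) comes
  from a logistic fit of the delayed flag against run index (Laplace-smoothed
  empirical frequency when the history is one-sided);
* its expected cost is the *adjusted run time*
  ``FastAverage * (1 - p_delay) + FastAverage * DelayFactor * p_delay``;
* the delay is *over* once a measured time falls below
  ``SlowAverage - SlowStdDev`` or below ``FastAverage + FastStdDev``.

With no delay flags set the agent deterministically picks the smallest
FastAverage. While any implementation is delayed it samples from the
inverse-square distribution ``P(k) = (1/t_k^2) / sum_j (1/t_j^2)`` over
adjusted times, so a delayed implementation keeps a strictly positive
probability of being retried.

When a signature has insufficient local history, the agent fuzzy-matches the
current input against the benchmarked signatures (triangular membership per
feature, mean-aggregated) and falls back to the packaged factory-default
tables.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateStatisticsError,
    InsufficientDataError,
    InvalidTimeError,
    NoBenchmarkError,
    NoImplementationError,
)
from .kernels import Registry, signature_of
from .store import (
    INSUFFICIENT_HISTORY,
    BenchmarkTable,
    DeviceFingerprint,
    RunRecord,
    Store,
    load_defaults,
)

logger = logging.getLogger("liquidengine.agent")

#: multiplier on FastStdDev in the delay-entry test
DELAY_SIGMAS = 4.0
#: observations of the delayed flag kept per implementation
DELAY_HISTORY_WINDOW = 50


# ---------------------------------------------------------------------------
# split statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImplementationStats:
    """Fast/slow split summary of one implementation's recent run times."""

    fast_average: float
    fast_stddev: float
    slow_average: float
    slow_stddev: float
    n: int


def _mean_std(values) -> tuple[float, float]:
    # plain left-to-right arithmetic; population (divide-by-n) deviation
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)


def split_stats(run_times) -> ImplementationStats:
    """Sort ascending, split into fastest/slowest halves, summarize each.

    With an odd count the median value goes to the fast half, biasing toward
    the optimistic baseline the delay test compares against.
    """
    times = [float(t) for t in run_times]
    if len(times) < 2:
        raise InsufficientDataError(f"need >= 2 run times, got {len(times)}")
    times.sort()
    half = (len(times) + 1) // 2
    fast_mean, fast_std = _mean_std(times[:half])
    slow_mean, slow_std = _mean_std(times[half:])
    return ImplementationStats(fast_mean, fast_std, slow_mean, slow_std, len(times))


def detect_delay(measured: float, stats: ImplementationStats) -> bool:
    """Delay entry test: measured strictly above FastAverage + 4·FastStdDev."""
    return measured > stats.fast_average + DELAY_SIGMAS * stats.fast_stddev


def delay_factor(measured: float, stats: ImplementationStats) -> float:
    """Ratio of the measured run time to the fast average."""
    if stats.fast_average == 0:
        raise DegenerateStatisticsError("fast_average is zero")
    return measured / stats.fast_average


def adjusted_run_time(stats: ImplementationStats, factor: float, p_delay: float) -> float:
    """Expected cost of a delayed implementation on the next run."""
    return (
        stats.fast_average * (1.0 - p_delay)
        + stats.fast_average * factor * p_delay
    )


def delay_over(measured: float, stats: ImplementationStats) -> bool:
    """Delay exit test: below SlowAverage − SlowStdDev or FastAverage + FastStdDev."""
    return (
        measured < stats.slow_average - stats.slow_stddev
        or measured < stats.fast_average + stats.fast_stddev
    )


# ---------------------------------------------------------------------------
# delay state and recurrence probability
# ---------------------------------------------------------------------------

@dataclass
class DelayState:
    """Per-(method, implementation) delay bookkeeping."""

    delayed: bool = False
    delay_factor: float = 0.0
    p_delay: float = 0.0
    history: list = field(default_factory=list)  # [(run index, delayed flag)]

    def observe(self, run_index: int, delayed_flag: bool) -> None:
        self.history.append((int(run_index), bool(delayed_flag)))
        if len(self.history) > DELAY_HISTORY_WINDOW:
            del self.history[: len(self.history) - DELAY_HISTORY_WINDOW]


def estimate_p_delay(state: DelayState) -> float:
    """Probability the delay is present on the next run.

    A logistic model of the delayed flag against run index over the recent
    history, evaluated at the next index; one-sided histories use the
    Laplace-smoothed frequency (k+1)/(n+2).
    """
    history = state.history[-DELAY_HISTORY_WINDOW:]
    if not history:
        raise InsufficientDataError("empty delay history")
    flags = [1 if d else 0 for _, d in history]
    n = len(flags)
    k = sum(flags)
    if k == 0 or k == n:
        return (k + 1.0) / (n + 2.0)
    from sklearn.linear_model import LogisticRegression

    x = np.array([[i] for i, _ in history], dtype=float)
    y = np.array(flags)
    model = LogisticRegression(max_iter=500)
    model.fit(x, y)
    next_index = float(history[-1][0] + 1)
    p = float(model.predict_proba([[next_index]])[0, 1])
    return min(1.0, max(0.0, p))


# ---------------------------------------------------------------------------
# selection distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionDistribution:
    """Probabilities over implementation ids; sums to 1."""

    probabilities: dict

    def sample(self, rng: np.random.Generator) -> str:
        ids = list(self.probabilities)
        p = np.array([self.probabilities[i] for i in ids])
        return ids[int(rng.choice(len(ids), p=p))]


def selection_probabilities(adjusted_times: dict) -> SelectionDistribution:
    """Inverse-square normalization: P(k) = (1/t_k²) / Σ_j (1/t_j²)."""
    if not adjusted_times:
        raise NoImplementationError("no implementations to select among")
    for impl, t in adjusted_times.items():
        if not t > 0:
            raise InvalidTimeError(f"non-positive adjusted time for {impl}: {t}")
    inv = {impl: 1.0 / (t * t) for impl, t in adjusted_times.items()}
    total = sum(inv.values())
    return SelectionDistribution({impl: v / total for impl, v in inv.items()})


# ---------------------------------------------------------------------------
# fuzzy matching of input signatures
# ---------------------------------------------------------------------------

def _membership(query: float, candidate: float) -> float:
    # triangular membership centered on the candidate, half-width = candidate
    if candidate == 0.0:
        return 1.0 if query == 0.0 else 0.0
    return max(0.0, 1.0 - abs(query - candidate) / abs(candidate))


def fuzzy_score(signature, candidate) -> float:
    """Mean triangular membership of ``signature`` against one candidate."""
    sig = tuple(float(x) for x in signature)
    cand = tuple(float(x) for x in candidate)
    if len(sig) != len(cand):
        raise ValueError("signature length mismatch")
    return sum(_membership(q, c) for q, c in zip(sig, cand)) / len(sig)


def fuzzy_match(signature, table: BenchmarkTable, method_id: str | None = None):
    """Most similar benchmarked signature and its per-implementation times.

    Ties resolve to the earliest candidate in table order.
    """
    if table.is_empty():
        raise NoBenchmarkError(
            f"no benchmark entries for {method_id or table.method_id!r}"
        )
    best_sig, best_score = None, -1.0
    for cand in table.signatures():
        score = fuzzy_score(signature, cand)
        if score > best_score:
            best_sig, best_score = cand, score
    return best_sig, table.times_for(best_sig), best_score


# ---------------------------------------------------------------------------
# the agent and engine
# ---------------------------------------------------------------------------

class Agent:
    """Implementation selector with per-(method, implementation) delay state."""

    def __init__(self, registry: Registry, store: Store,
                 fingerprint: DeviceFingerprint | None = None):
        self.registry = registry
        self.store = store
        self.fingerprint = fingerprint or DeviceFingerprint.current()
        self.delay_states: dict[tuple[str, str], DelayState] = {}
        self._counters: dict[str, int] = {}
        self._defaults_cache: dict[str, BenchmarkTable] = {}

    # -- internals ----------------------------------------------------------

    def _state(self, method_id: str, impl_id: str) -> DelayState:
        return self.delay_states.setdefault((method_id, impl_id), DelayState())

    def _defaults(self, method_id: str) -> BenchmarkTable | None:
        if method_id not in self._defaults_cache:
            try:
                self._defaults_cache[method_id] = load_defaults(
                    method_id, self.store.root
                )
            except Exception:
                self._defaults_cache[method_id] = None
        return self._defaults_cache[method_id]

    def _baseline_times(self, method_id: str, signature, impl_ids):
        """Per-implementation run times: local history, else factory defaults."""
        device = self.fingerprint.digest
        local = self.store.build_table(method_id, device_id=device)
        matched_local = None
        if not local.is_empty():
            matched_local = fuzzy_match(signature, local, method_id)
        default_match = None
        times, sources = {}, {}
        for impl in impl_ids:
            recent = INSUFFICIENT_HISTORY
            if matched_local is not None:
                recent = self.store.load_recent(
                    method_id, impl, matched_local[0], device_id=device
                )
            if recent is not INSUFFICIENT_HISTORY:
                times[impl] = list(recent)
                sources[impl] = "history"
                continue
            if default_match is None:
                defaults = self._defaults(method_id)
                if defaults is not None and not defaults.is_empty():
                    default_match = fuzzy_match(signature, defaults, method_id)
            if default_match is not None and impl in default_match[1]:
                times[impl] = list(default_match[1][impl])
                sources[impl] = "defaults"
            else:
                times[impl] = None
                sources[impl] = "prior"
        # implementations with no data anywhere get a neutral prior equal to
        # the mean fast baseline of the known ones (stays selectable)
        known = [v for v in times.values() if v]
        prior = (
            float(np.mean([np.mean(v) for v in known])) if known else 1.0
        )
        for impl in impl_ids:
            if times[impl] is None:
                times[impl] = [prior, prior]
            elif len(times[impl]) == 1:
                times[impl] = times[impl] * 2
        matched = matched_local[0] if matched_local is not None else (
            default_match[0] if default_match is not None else None
        )
        return times, sources, matched

    # -- public API ---------------------------------------------------------

    def decide(self, method_id: str, signature, seed: int | None = None):
        """Pick an implementation for this call; returns (impl_id, trace)."""
        t0 = time.perf_counter()
        entries = self.registry.list(method_id, only_available=True)
        if not entries:
            raise NoImplementationError(f"no available implementation of {method_id!r}")
        impl_ids = [e.impl_id for e in entries]
        hardware_changed = self.store.detect_hardware_change(self.fingerprint)
        times, sources, matched = self._baseline_times(method_id, signature, impl_ids)
        stats = {impl: split_stats(times[impl]) for impl in impl_ids}
        delayed = {
            impl: self._state(method_id, impl).delayed for impl in impl_ids
        }
        trace = {
            "method": method_id,
            "signature": list(float(x) for x in signature),
            "matched_signature": list(matched) if matched is not None else None,
            "device": self.fingerprint.digest,
            "hardware_changed": hardware_changed,
            "implementations": {
                impl: {
                    "fast_average": stats[impl].fast_average,
                    "fast_stddev": stats[impl].fast_stddev,
                    "slow_average": stats[impl].slow_average,
                    "slow_stddev": stats[impl].slow_stddev,
                    "n": stats[impl].n,
                    "source": sources[impl],
                    "delayed": delayed[impl],
                }
                for impl in impl_ids
            },
        }
        if not any(delayed.values()):
            chosen = min(impl_ids, key=lambda i: stats[i].fast_average)
            trace.update(mode="deterministic", chosen=chosen,
                         probabilities={chosen: 1.0})
        else:
            adjusted = {}
            for impl in impl_ids:
                state = self._state(method_id, impl)
                if state.delayed:
                    p = estimate_p_delay(state) if state.history else state.p_delay
                    state.p_delay = p
                    adjusted[impl] = adjusted_run_time(stats[impl], state.delay_factor, p)
                    trace["implementations"][impl]["p_delay"] = p
                    trace["implementations"][impl]["delay_factor"] = state.delay_factor
                else:
                    adjusted[impl] = stats[impl].fast_average
            dist = selection_probabilities(adjusted)
            if seed is None:
                seed = self._counters.get(method_id, 0)
            rng = np.random.default_rng(seed)
            chosen = dist.sample(rng)
            trace.update(mode="stochastic", chosen=chosen, seed=int(seed),
                         adjusted_times=adjusted,
                         probabilities=dict(dist.probabilities))
        trace["stats"] = stats  # pre-run stats, consumed by observe()
        trace["decision_ms"] = (time.perf_counter() - t0) * 1e3
        logger.info("%s", json.dumps({k: v for k, v in trace.items() if k != "stats"}))
        return chosen, trace

    def observe(self, method_id: str, impl_id: str, signature, measured: float,
                trace: dict | None = None) -> None:
        """Record a timed run and update the implementation's delay state."""
        run_index = self._counters.get(method_id, 0)
        self._counters[method_id] = run_index + 1
        self.store.record_run(
            RunRecord(
                method_id=method_id,
                impl_id=impl_id,
                signature=tuple(signature),
                run_time=measured,
                device_id=self.fingerprint.digest,
            )
        )
        if trace is not None and impl_id in trace.get("stats", {}):
            stats = trace["stats"][impl_id]
            source = trace["implementations"][impl_id]["source"]
        else:
            entries = self.registry.list(method_id, only_available=True)
            times, sources, _ = self._baseline_times(
                method_id, signature, [e.impl_id for e in entries]
            )
            stats = split_stats(times[impl_id])
            source = sources[impl_id]
        if source != "history":
            # factory defaults and neutral priors are cross-device baselines
            # for relative comparison; they are not calibrated delay gates
            # for this host, so delay bookkeeping waits for local history
            return
        state = self._state(method_id, impl_id)
        delayed_now = detect_delay(measured, stats)
        if state.delayed:
            if delay_over(measured, stats):
                state.delayed = False
                state.p_delay = 0.0
            else:
                state.delay_factor = delay_factor(measured, stats)
        elif delayed_now:
            state.delayed = True
            state.delay_factor = delay_factor(measured, stats)
        state.observe(run_index, delayed_now)


def select_implementation(method_id: str, signature, registry: Registry,
                          store: Store, rng_seed: int | None = None,
                          agent: Agent | None = None):
    """One-shot selection; returns (impl_id, decision trace)."""
    agent = agent or Agent(registry, store)
    return agent.decide(method_id, signature, seed=rng_seed)


class Engine:
    """Runs methods through the agent: select, time, record, update."""

    def __init__(self, registry: Registry, store: Store | None = None,
                 base_seed: int = 0):
        self.registry = registry
        self.store = store or Store()
        self.agent = Agent(registry, self.store)
        self.base_seed = int(base_seed)
        self._calls = 0

    def _next_seed(self) -> int:
        seed = int(
            np.random.SeedSequence([self.base_seed, self._calls]).generate_state(1)[0]
            % (2**31)
        )
        self._calls += 1
        return seed

    def run(self, method_id: str, *args, impl_id: str | None = None):
        """Execute one call; returns (output, trace).

        With ``impl_id=None`` the agent chooses; otherwise the named
        implementation runs directly (still timed and recorded).
        """
        signature = signature_of(method_id, *args)
        if impl_id is None:
            impl_id, trace = self.agent.decide(
                method_id, signature, seed=self._next_seed()
            )
        else:
            trace = {"method": method_id, "chosen": impl_id, "mode": "pinned",
                     "signature": list(signature)}
        entry = self.registry.get(method_id, impl_id)
        t0 = time.perf_counter()
        out = entry.runner(*_prepare_args(method_id, args))
        measured = time.perf_counter() - t0
        trace["measured_run_time"] = measured
        self.agent.observe(method_id, impl_id, signature, measured, trace)
        return out, trace


def _prepare_args(method_id: str, args):
    from . import kernels

    if method_id == kernels.CONV2D:
        img, ker = args
        return kernels._as_image2d(img), kernels._as_kernel(ker)
    if method_id == kernels.CATMULL_ROM_ZOOM:
        stack, m = args
        vol, _ = kernels._as_stack(stack)
        return vol, int(m)
    if method_id == kernels.NLM_DENOISE:
        img, params = args
        if not isinstance(params, kernels.NLMParams):
            params = kernels.NLMParams(**params)
        return kernels._as_image2d(img), params
    raise NoImplementationError(f"unknown method {method_id!r}")
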