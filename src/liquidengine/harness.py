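"""Synthetic image generator and the delay-injection experiment harness.

The harness reproduces, at desk scale, the sequential-run delay experiment:
run one method many times in a row, artificially inflate the wall-clock of
one implementation during a window of runs, and compare the adaptive policy
(agent chooses per call) against a pinned policy (always the initially
fastest implementation). Delay emulation is in-process time inflation — a
busy sleep appended after the true computation — so outputs are unchanged
and no contended hardware is needed.
"""

from __future__ import annotations

import tempfile
import time
from dataclasses import dataclass, field

import numpy as np

from .agent import Engine
from .errors import InvalidParameterError
from .kernels import (
    CATMULL_ROM_ZOOM,
    CONV2D,
    NLM_DENOISE,
    NLMParams,
    Registry,
    build_default_registry,
)
from .store import Store


# ---------------------------------------------------------------------------
# synthetic images
# ---------------------------------------------------------------------------

#: coefficients of the deterministic linear ramp a·x + b·y + c
RAMP_COEFFS = (0.5, 0.25, 1.0)


def generate_image(height: int, width: int, frames: int | None = None,
                   kind: str = "uniform-noise", seed: int = 0) -> np.ndarray:
    """Deterministic synthetic image (2D) or stack (frames × H × W).

    kinds: ``uniform-noise`` — i.i.d. uniform in [0, 1); ``spots`` —
    Gaussian peaks on a flat background (visually meaningful denoising
    input); ``ramp`` — the exact linear field a·x + b·y + c (degree-1
    reproduction tests).
    """
    if height < 1 or width < 1 or (frames is not None and frames < 1):
        raise InvalidParameterError("image dimensions must be >= 1")
    t = 1 if frames is None else int(frames)
    rng = np.random.default_rng(seed)
    if kind == "uniform-noise":
        out = rng.random((t, height, width))
    elif kind == "ramp":
        a, b, c = RAMP_COEFFS
        yy, xx = np.mgrid[0:height, 0:width].astype(float)
        out = np.broadcast_to(a * xx + b * yy + c, (t, height, width)).copy()
    elif kind == "spots":
        out = np.full((t, height, width), 0.1)
        n_spots = max(1, (height * width) // 400)
        yy, xx = np.mgrid[0:height, 0:width].astype(float)
        for f in range(t):
            cy = rng.uniform(0, height, n_spots)
            cx = rng.uniform(0, width, n_spots)
            amp = rng.uniform(0.5, 1.0, n_spots)
            s = rng.uniform(1.0, max(2.0, min(height, width) / 20), n_spots)
            for k in range(n_spots):
                out[f] += amp[k] * np.exp(
                    -((yy - cy[k]) ** 2 + (xx - cx[k]) ** 2) / (2 * s[k] ** 2)
                )
    else:
        raise InvalidParameterError(f"unknown image kind {kind!r}")
    return out[0] if frames is None else out


# ---------------------------------------------------------------------------
# delay injection
# ---------------------------------------------------------------------------

def inject_delay(registry: Registry, method_id: str, target_impl: str,
                 slowdown: float, active_predicate) -> Registry:
    """Inflate the wall-clock of one implementation while a predicate holds.

    The target's runner is wrapped in place: the true computation runs
    unchanged, then a busy sleep of (slowdown − 1)× the elapsed time is
    appended whenever ``active_predicate()`` is true. Outputs are identical
    with and without injection.
    """
    if slowdown <= 1:
        raise InvalidParameterError("slowdown must be > 1")
    entry = registry.get(method_id, target_impl)  # raises if unknown
    inner = entry.runner

    def delayed_runner(*args, **kwargs):
        t0 = time.perf_counter()
        out = inner(*args, **kwargs)
        if active_predicate():
            elapsed = time.perf_counter() - t0
            deadline = t0 + elapsed * slowdown
            while time.perf_counter() < deadline:
                pass
        return out

    entry.runner = delayed_runner
    return registry


# ---------------------------------------------------------------------------
# the delay-management experiment
# ---------------------------------------------------------------------------

@dataclass
class DelayExperimentConfig:
    """Sequential-run delay experiment at desk scale.

    Defaults: 60 conv2d runs of a 9×9 all-ones kernel on a 256×256 uniform
    noise image, with an 8× slowdown injected on the preferred
    implementation during runs 15–29 (half-open window [15, 30)).
    """

    method_id: str = CONV2D
    n_runs: int = 60
    delay_window: tuple = (15, 30)
    slowdown: float = 8.0
    target_impl: str | None = None  # None: the initially fastest one
    seed: int = 0
    image_side: int = 256
    kernel_size: int = 9
    seeding_repeats: int = 4

    def __post_init__(self):
        lo, hi = self.delay_window
        if not (0 <= lo < hi <= self.n_runs):
            raise InvalidParameterError("delay_window must lie within [0, n_runs)")
        if self.slowdown <= 1:
            raise InvalidParameterError("slowdown must be > 1")

    def to_dict(self) -> dict:
        return {
            "method_id": self.method_id, "n_runs": self.n_runs,
            "delay_window": list(self.delay_window), "slowdown": self.slowdown,
            "target_impl": self.target_impl, "seed": self.seed,
            "image_side": self.image_side, "kernel_size": self.kernel_size,
            "seeding_repeats": self.seeding_repeats,
        }


def _desk_scale_args(config: DelayExperimentConfig):
    side = config.image_side
    if config.method_id == CONV2D:
        img = generate_image(side, side, kind="uniform-noise", seed=config.seed)
        return img, np.ones((config.kernel_size, config.kernel_size))
    if config.method_id == CATMULL_ROM_ZOOM:
        stack = generate_image(min(side, 64), min(side, 64), frames=2,
                               kind="uniform-noise", seed=config.seed)
        return stack, 5
    if config.method_id == NLM_DENOISE:
        img = generate_image(min(side, 96), min(side, 96),
                             kind="uniform-noise", seed=config.seed)
        return img, NLMParams(patch_size=3, patch_distance=5, sigma=0.1, h=0.1)
    raise InvalidParameterError(f"unknown method {config.method_id!r}")


def run_delay_experiment(config: DelayExperimentConfig, adaptive: bool = True,
                         store_root=None) -> dict:
    """Execute the sequential-run experiment; returns trace + summary.

    A fresh registry and store are used per experiment. Before the measured
    sequence, every implementation is run ``seeding_repeats`` times so local
    history exists; the initially fastest implementation (by FastAverage)
    becomes both the pinned choice and — unless overridden — the delay
    target.
    """
    registry = build_default_registry()
    root = store_root or tempfile.mkdtemp(prefix="lqe_experiment_")
    store = Store(root)
    engine = Engine(registry, store, base_seed=config.seed)
    args = _desk_scale_args(config)

    # seed local history: pinned warm-up runs of every available implementation
    for entry in registry.list(config.method_id, only_available=True):
        for _ in range(config.seeding_repeats):
            engine.run(config.method_id, *args, impl_id=entry.impl_id)

    from .kernels import signature_of

    signature = signature_of(config.method_id, *args)
    preferred, _ = engine.agent.decide(config.method_id, signature, seed=0)
    target = config.target_impl or preferred

    state = {"run": -1}
    lo, hi = config.delay_window
    inject_delay(
        registry, config.method_id, target, config.slowdown,
        lambda: lo <= state["run"] < hi,
    )

    runs = []
    for i in range(config.n_runs):
        state["run"] = i
        _, trace = engine.run(
            config.method_id, *args,
            impl_id=None if adaptive else preferred,
        )
        runs.append(
            {
                "index": i,
                "impl": trace["chosen"],
                "run_time": trace["measured_run_time"],
                "in_window": lo <= i < hi,
                "mode": trace.get("mode", "pinned"),
            }
        )

    t_all = [r["run_time"] for r in runs]
    t_in = [r["run_time"] for r in runs if r["in_window"]]
    t_out = [r["run_time"] for r in runs if not r["in_window"]]

    def share(rows):
        return sum(1 for r in rows if r["impl"] == target) / len(rows) if rows else 0.0

    summary = {
        "adaptive": adaptive,
        "preferred_impl": preferred,
        "target_impl": target,
        "mean_time": float(np.mean(t_all)),
        "mean_time_window": float(np.mean(t_in)),
        "mean_time_outside": float(np.mean(t_out)),
        "target_share_window": share([r for r in runs if r["in_window"]]),
        "target_share_outside": share([r for r in runs if not r["in_window"]]),
        "post_window_modal_impl": _modal_impl(runs, hi, config.n_runs),
    }
    return {"config": config.to_dict(), "runs": runs, "summary": summary}


def _modal_impl(runs, start, stop):
    counts: dict[str, int] = {}
    for r in runs:
        if start <= r["index"] < stop:
            counts[r["impl"]] = counts.get(r["impl"], 0) + 1
    return max(counts, key=counts.get) if counts else None
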