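"""Manual benchmarking of implementations over signature grids.

A :class:`BenchmarkGrid` crosses input signatures with every available
implementation of a method; each cell is timed ``repeats`` times (wall-clock
around the kernel call only, the first repeat flagged as warm-up and
excluded from the reported median), every timed run is appended to the
run-time store, and the populated :class:`~liquidengine.store.BenchmarkTable`
is returned. The default grids are desk-scale reductions of sweeps over
kernel size / image side (conv2d), stack shape at 5× magnification
(Catmull-Rom) and image side × patch distance × patch size (NLM).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import kernels
from .errors import UnknownMethodError
from .harness import generate_image
from .kernels import CATMULL_ROM_ZOOM, CONV2D, NLM_DENOISE, NLMParams, Registry
from .store import BenchmarkTable, DeviceFingerprint, RunRecord, Store

logger = logging.getLogger("liquidengine.benchmark")

DEFAULT_REPEATS = 3


@dataclass
class BenchmarkGrid:
    """Signatures to benchmark for one method, with per-cell repeats."""

    method_id: str
    signatures: list = field(default_factory=list)
    repeats: int = DEFAULT_REPEATS

    def __post_init__(self):
        if not self.signatures:
            raise ValueError("grid needs at least one signature")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        self.signatures = [tuple(float(x) for x in s) for s in self.signatures]

    def to_json(self) -> str:
        return json.dumps(
            {
                "method_id": self.method_id,
                "repeats": self.repeats,
                "signatures": [list(s) for s in self.signatures],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BenchmarkGrid":
        d = json.loads(text)
        return cls(d["method_id"], d["signatures"], d.get("repeats", DEFAULT_REPEATS))


def default_grid(method_id: str, repeats: int = DEFAULT_REPEATS) -> BenchmarkGrid:
    """Desk-scale default grid for a shipped method."""
    if method_id == CONV2D:
        sigs = [
            (side, side, k)
            for side in (100, 500, 1000)
            for k in (1, 5, 9, 13, 17, 21)
        ]
    elif method_id == CATMULL_ROM_ZOOM:
        sigs = [
            (t, s, s, 5)
            for t, s in ((1, 10), (10, 10), (10, 100), (10, 300))
        ]
    elif method_id == NLM_DENOISE:
        sigs = [
            (side, side, ps, pd, 1.0, 0.1)
            for side in (200, 500)
            for pd in (10, 100)
            for ps in (5, 10, 20)
        ]
    else:
        raise UnknownMethodError(f"no default grid for {method_id!r}")
    return BenchmarkGrid(method_id, sigs, repeats)


def synthesize_args(method_id: str, signature, seed: int = 0):
    """Build the synthetic call arguments matching a signature.

    Images are uniform noise; convolution kernels are all-ones.
    """
    sig = tuple(float(x) for x in signature)
    mix = int(hashlib.sha256(repr((method_id, sig, seed)).encode()).hexdigest(), 16)
    local_seed = mix % (2**31)
    if method_id == CONV2D:
        h, w, k = (int(x) for x in sig)
        img = generate_image(h, w, kind="uniform-noise", seed=local_seed)
        return img, np.ones((k, k))
    if method_id == CATMULL_ROM_ZOOM:
        t, h, w, m = (int(x) for x in sig)
        stack = generate_image(h, w, frames=t, kind="uniform-noise", seed=local_seed)
        return stack, m
    if method_id == NLM_DENOISE:
        h, w = int(sig[0]), int(sig[1])
        img = generate_image(h, w, kind="uniform-noise", seed=local_seed)
        params = NLMParams(
            patch_size=int(sig[2]), patch_distance=int(sig[3]),
            sigma=sig[4], h=sig[5],
        )
        return img, params
    raise UnknownMethodError(f"unknown method {method_id!r}")


def run_benchmark(grid: BenchmarkGrid, registry: Registry, store: Store,
                  seed: int = 0):
    """Time every (signature, implementation) cell of a grid.

    Returns ``(table, report)``: the table holds every recorded time
    (warm-up repeats included); the report lists, per cell, the median time
    excluding the warm-up repeat and flags the fastest implementation per
    signature. Unavailable implementations are skipped with a logged notice.
    """
    entries = registry.list(grid.method_id)
    fingerprint = DeviceFingerprint.current()
    table = BenchmarkTable(method_id=grid.method_id)
    medians: dict[tuple, dict[str, float]] = {}
    for sig in grid.signatures:
        args = synthesize_args(grid.method_id, sig, seed)
        medians[sig] = {}
        for entry in entries:
            if not entry.available:
                logger.info("skipping unavailable %s/%s", grid.method_id, entry.impl_id)
                continue
            cell_times = []
            for _ in range(grid.repeats):
                t0 = time.perf_counter()
                entry.runner(*args)
                elapsed = time.perf_counter() - t0
                cell_times.append(elapsed)
                store.record_run(
                    RunRecord(
                        method_id=grid.method_id,
                        impl_id=entry.impl_id,
                        signature=sig,
                        run_time=elapsed,
                        device_id=fingerprint.digest,
                    )
                )
                table.add(entry.impl_id, sig, elapsed)
            timed = cell_times[1:] if len(cell_times) > 1 else cell_times
            medians[sig][entry.impl_id] = float(np.median(timed))
    report = []
    for sig, per_impl in medians.items():
        if not per_impl:
            continue
        fastest = min(per_impl, key=per_impl.get)
        for impl, med in per_impl.items():
            report.append(
                {
                    "signature": list(sig),
                    "implementation": impl,
                    "median_time": med,
                    "fastest": impl == fastest,
                }
            )
    return table, report


def format_report(report) -> str:
    """Tab-separated benchmark report (signature, impl, median, fastest)."""
    lines = ["signature\timplementation\tmedian_time_s\tfastest"]
    for row in report:
        sig = "x".join(f"{v:g}" for v in row["signature"])
        lines.append(
            f"{sig}\t{row['implementation']}\t{row['median_time']:.6g}\t"
            f"{int(row['fastest'])}"
        )
    return "\n".join(lines) + "\n"


def build_factory_defaults(registry: Registry, out_dir=None,
                           repeats: int = DEFAULT_REPEATS, seed: int = 0,
                           store: Store | None = None) -> list[Path]:
    """Run the default grids for all shipped methods and write the packaged
    default tables (one JSON file per method). Maintainer-side operation."""
    if out_dir is None:
        out_dir = Path(__file__).parent / "data" / "defaults"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if store is None:
        import tempfile

        store = Store(tempfile.mkdtemp(prefix="lqe_defaults_"))
    paths = []
    for method_id in (CONV2D, CATMULL_ROM_ZOOM, NLM_DENOISE):
        grid = default_grid(method_id, repeats=repeats)
        table, report = run_benchmark(grid, registry, store, seed=seed)
        path = out_dir / f"{method_id}.json"
        with open(path, "w") as fh:
            json.dump(table.to_dict(), fh, indent=1)
        logger.info("wrote %s (%d entries)", path, len(table.entries))
        paths.append(path)
    return paths
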