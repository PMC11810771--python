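"""Persistent historical record of per-implementation run times.

Records live under ``<store root>/<method>/<impl>.jsonl`` — one JSON object
per line, append-only — keyed by input signature and device fingerprint.
The default store root is ``~/.liquid_engine`` and can be overridden per
call, or globally through the ``LIQUID_ENGINE_STORE_ROOT`` environment
variable.

Retrieval is windowed: the agent reads at most the 50 most recent run times
for a (method, implementation, signature, device) key; three or more
recorded runs are enough to proceed, fewer than three yields the
:data:`INSUFFICIENT_HISTORY` marker so callers fall back to the packaged
factory-default benchmark tables.
"""

from __future__ import annotations

import hashlib
import json
import os
import platform
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import MissingDefaultsError, StorageError

#: history window: number of most recent run times the agent considers
HISTORY_WINDOW = 50
#: minimum recorded runs before local history replaces factory defaults
MIN_HISTORY = 3

ENV_STORE_ROOT = "LIQUID_ENGINE_STORE_ROOT"


class _InsufficientHistory:
    """Marker: fewer than MIN_HISTORY runs recorded — fall back to defaults."""

    def __repr__(self):
        return "INSUFFICIENT_HISTORY"

    def __bool__(self):
        return False


INSUFFICIENT_HISTORY = _InsufficientHistory()


def default_store_root() -> Path:
    env = os.environ.get(ENV_STORE_ROOT)
    if env:
        return Path(env)
    return Path.home() / ".liquid_engine"


# ---------------------------------------------------------------------------
# device fingerprint
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviceFingerprint:
    """Stable digest of host descriptors; identical hosts hash identically."""

    digest: str

    @classmethod
    def current(cls) -> "DeviceFingerprint":
        total_mem = 0
        try:
            total_mem = os.sysconf("SC_PAGE_SIZE") * os.sysconf("SC_PHYS_PAGES")
        except (ValueError, OSError, AttributeError):
            pass
        descriptor = "|".join(
            [
                platform.machine(),
                platform.processor() or platform.machine(),
                str(os.cpu_count() or 0),
                str(total_mem),
                platform.system(),
            ]
        )
        return cls(hashlib.sha256(descriptor.encode()).hexdigest()[:16])


@dataclass(frozen=True)
class RunRecord:
    """One timed execution of an implementation."""

    method_id: str
    impl_id: str
    signature: tuple[float, ...]
    run_time: float
    timestamp: float = field(default_factory=time.time)
    device_id: str = ""

    def __post_init__(self):
        if not self.run_time > 0:
            raise ValueError(f"run_time must be > 0, got {self.run_time}")
        object.__setattr__(self, "signature", tuple(float(x) for x in self.signature))

    def to_json(self) -> str:
        return json.dumps(
            {
                "signature": list(self.signature),
                "run_time": self.run_time,
                "timestamp": self.timestamp,
                "device_id": self.device_id,
            }
        )

    @classmethod
    def from_json(cls, method_id: str, impl_id: str, line: str) -> "RunRecord":
        d = json.loads(line)
        return cls(
            method_id=method_id,
            impl_id=impl_id,
            signature=tuple(d["signature"]),
            run_time=d["run_time"],
            timestamp=d["timestamp"],
            device_id=d.get("device_id", ""),
        )


# ---------------------------------------------------------------------------
# benchmark tables
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkTable:
    """Mapping (impl_id, signature) -> recorded run times, seconds."""

    method_id: str
    entries: dict = field(default_factory=dict)  # (impl_id, sig tuple) -> [times]

    def add(self, impl_id: str, signature, run_time: float) -> None:
        key = (impl_id, tuple(float(x) for x in signature))
        self.entries.setdefault(key, []).append(float(run_time))

    def signatures(self) -> list[tuple[float, ...]]:
        """Unique signatures in first-seen order."""
        seen: dict[tuple, None] = {}
        for _, sig in self.entries:
            seen.setdefault(sig)
        return list(seen)

    def implementations(self) -> list[str]:
        seen: dict[str, None] = {}
        for impl, _ in self.entries:
            seen.setdefault(impl)
        return list(seen)

    def times_for(self, signature) -> dict[str, list[float]]:
        sig = tuple(float(x) for x in signature)
        return {
            impl: list(times)
            for (impl, s), times in self.entries.items()
            if s == sig
        }

    def is_empty(self) -> bool:
        return not self.entries

    def to_dict(self) -> dict:
        rows = []
        for sig in self.signatures():
            rows.append({"signature": list(sig), "times": self.times_for(sig)})
        return {"method_id": self.method_id, "entries": rows}

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkTable":
        table = cls(method_id=d["method_id"])
        for row in d["entries"]:
            for impl, times in row["times"].items():
                for t in times:
                    table.add(impl, row["signature"], t)
        return table


# ---------------------------------------------------------------------------
# the store
# ---------------------------------------------------------------------------

class Store:
    """Append-only JSON-lines run-time store with an in-memory read cache."""

    def __init__(self, root: Path | str | None = None):
        self.root = Path(root) if root is not None else default_store_root()
        self._cache: dict[tuple[str, str], list[RunRecord]] = {}

    def _path(self, method_id: str, impl_id: str) -> Path:
        return self.root / method_id / f"{impl_id}.jsonl"

    def _load(self, method_id: str, impl_id: str) -> list[RunRecord]:
        key = (method_id, impl_id)
        if key not in self._cache:
            path = self._path(method_id, impl_id)
            records: list[RunRecord] = []
            if path.exists():
                with open(path) as fh:
                    for line in fh:
                        line = line.strip()
                        if line:
                            records.append(RunRecord.from_json(method_id, impl_id, line))
            self._cache[key] = records
        return self._cache[key]

    def record_run(self, record: RunRecord) -> int:
        """Durably append a record; returns the total stored for its key."""
        # populate the cache from disk BEFORE appending, so the new record
        # is counted exactly once
        records = self._load(record.method_id, record.impl_id)
        path = self._path(record.method_id, record.impl_id)
        try:
            path.parent.mkdir(parents=True, exist_ok=True)
            with open(path, "a") as fh:
                fh.write(record.to_json() + "\n")
        except OSError as exc:
            raise StorageError(f"cannot write run-time store at {path}: {exc}") from exc
        records.append(record)
        return sum(1 for r in records if r.signature == record.signature)

    def load_recent(self, method_id: str, impl_id: str, signature,
                    window: int = HISTORY_WINDOW, device_id: str | None = None):
        """Run times for an exact signature, most recent first.

        Recency is file (insertion) order. Returns at most ``window`` times;
        fewer than MIN_HISTORY recorded runs returns INSUFFICIENT_HISTORY.
        """
        sig = tuple(float(x) for x in signature)
        records = self._load(method_id, impl_id)
        times = [
            r.run_time
            for r in records
            if r.signature == sig and (device_id is None or r.device_id == device_id)
        ]
        if len(times) < MIN_HISTORY:
            return INSUFFICIENT_HISTORY
        return times[::-1][:window]

    def detect_hardware_change(self, current: DeviceFingerprint) -> bool:
        """True iff the store holds records from a different device."""
        if not self.root.exists():
            return False
        for method_dir in sorted(self.root.iterdir()):
            if not method_dir.is_dir() or method_dir.name == "defaults":
                continue
            for path in sorted(method_dir.glob("*.jsonl")):
                for r in self._load(method_dir.name, path.stem):
                    if r.device_id and r.device_id != current.digest:
                        return True
        return False

    def build_table(self, method_id: str, device_id: str | None = None) -> BenchmarkTable:
        """Local benchmark table for a method (optionally one device only)."""
        table = BenchmarkTable(method_id=method_id)
        method_dir = self.root / method_id
        if method_dir.is_dir():
            for path in sorted(method_dir.glob("*.jsonl")):
                for r in self._load(method_id, path.stem):
                    if device_id is None or r.device_id == device_id:
                        table.add(r.impl_id, r.signature, r.run_time)
        return table

    def reset(self) -> None:
        """Delete all stored records (keeps user default tables)."""
        self._cache.clear()
        if not self.root.exists():
            return
        for method_dir in self.root.iterdir():
            if method_dir.is_dir() and method_dir.name != "defaults":
                for path in method_dir.glob("*.jsonl"):
                    path.unlink()


# module-level conveniences mirroring the operation contracts -----------------

def record_run(record: RunRecord, store_root=None) -> int:
    return Store(store_root).record_run(record)


def load_recent(method_id: str, impl_id: str, signature,
                window: int = HISTORY_WINDOW, store_root=None,
                device_id: str | None = None):
    return Store(store_root).load_recent(method_id, impl_id, signature, window, device_id)


def detect_hardware_change(current: DeviceFingerprint, store_root=None) -> bool:
    return Store(store_root).detect_hardware_change(current)


def load_defaults(method_id: str, store_root=None) -> BenchmarkTable:
    """Factory-default benchmark table for a method.

    A user-supplied table at ``<store root>/defaults/<method>.json`` overrides
    the packaged one.
    """
    root = Path(store_root) if store_root is not None else default_store_root()
    override = root / "defaults" / f"{method_id}.json"
    if override.exists():
        with open(override) as fh:
            return BenchmarkTable.from_dict(json.load(fh))
    packaged = resources.files("liquidengine").joinpath(f"data/defaults/{method_id}.json")
    try:
        text = packaged.read_text()
    except (FileNotFoundError, OSError):
        raise MissingDefaultsError(f"no factory-default benchmarks for {method_id!r}")
    return BenchmarkTable.from_dict(json.loads(text))
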