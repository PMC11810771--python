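import numpy as np
import pytest

import liquidengine as lqe

IMPLS = ("unthreaded", "threaded", "vectorized")
METHODS = (lqe.CONV2D, lqe.CATMULL_ROM_ZOOM, lqe.NLM_DENOISE)


@pytest.fixture()
def store(tmp_path):
    return lqe.Store(tmp_path / "store")


@pytest.fixture()
def fingerprint():
    return lqe.DeviceFingerprint.current()


@pytest.fixture()
def registry():
    """Fresh copy of the shipped registry (safe to mutate)."""
    return lqe.build_default_registry()


def seed_history(store, method, sig, per_impl_times, device_id):
    """Populate a store with fixed run times per implementation."""
    for impl, times in per_impl_times.items():
        for t in times:
            store.record_run(
                lqe.RunRecord(method, impl, sig, t, device_id=device_id)
            )


@pytest.fixture()
def two_impl_registry():
    reg = lqe.Registry()
    reg.register(lqe.ImplementationEntry("m", "A", lambda *a: None))
    reg.register(lqe.ImplementationEntry("m", "B", lambda *a: None))
    return reg


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the scalar kernels once so per-test timings are stable."""
    img = np.ones((4, 4))
    lqe.conv2d(img, np.ones((3, 3)), "unthreaded")
    lqe.catmull_rom_zoom(img, 2, "unthreaded")
    lqe.nlm_denoise(img, lqe.NLMParams(3, 1, 0.0, 0.5), "unthreaded")
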