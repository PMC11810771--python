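"""Multi-implementation bioimage kernels and the implementation registry.

Three methods ship with the package — 2D convolution, Catmull-Rom integer
upsampling and nonlocal-means (NLM) denoising — each as a family of
interchangeable implementations that produce numerically identical outputs
(within floating-point accumulation order) by different computational
strategies:

``unthreaded``
    sequential scalar loops (numba-compiled reference),
``threaded``
    chunked execution across a CPU thread pool,
``vectorized``
    whole-array expressions (numpy / scipy.ndimage).

All three methods clamp out-of-bounds reads to the nearest edge pixel, in
every implementation, so outputs agree at the borders too.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit
from scipy import ndimage, signal

from .errors import (
    DuplicateImplementationError,
    InvalidParameterError,
    UnknownImplementationError,
    UnknownMethodError,
)

CONV2D = "conv2d"
CATMULL_ROM_ZOOM = "catmull_rom_zoom"
NLM_DENOISE = "nlm_denoise"

#: documented feature order of each method's input signature
SIGNATURE_FIELDS = {
    CONV2D: ("height", "width", "kernel_size"),
    CATMULL_ROM_ZOOM: ("frames", "height", "width", "magnification"),
    NLM_DENOISE: ("height", "width", "patch_size", "patch_distance", "sigma", "h"),
}

_N_WORKERS = max(2, min(8, os.cpu_count() or 2))


# ---------------------------------------------------------------------------
# input validation helpers
# ---------------------------------------------------------------------------

def _as_image2d(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidParameterError(f"expected a 2D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("image contains non-finite values")
    return arr


def _as_stack(stack) -> tuple[np.ndarray, bool]:
    """Return (T,H,W) float64 volume and whether the input was 2D."""
    arr = np.asarray(stack, dtype=np.float64)
    was_2d = arr.ndim == 2
    if was_2d:
        arr = arr[None]
    if arr.ndim != 3 or min(arr.shape) < 1:
        raise InvalidParameterError(f"expected a T×H×W stack, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("stack contains non-finite values")
    return arr, was_2d


def _as_kernel(kernel) -> np.ndarray:
    k = np.asarray(kernel, dtype=np.float64)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise InvalidParameterError(f"kernel must be square, got shape {k.shape}")
    if k.shape[0] % 2 == 0:
        raise InvalidParameterError(f"kernel side must be odd, got {k.shape[0]}")
    if not np.all(np.isfinite(k)):
        raise InvalidParameterError("kernel contains non-finite values")
    return k


@dataclass(frozen=True)
class NLMParams:
    """Nonlocal-means parameters.

    patch_size : full side length of the comparison patch, pixels (even
        values are rounded up to the next odd integer so the patch has a
        center); patch_distance : search-window radius, pixels; sigma :
        assumed noise standard deviation, intensity units; h : weight
        cut-off distance, intensity units.
    """

    patch_size: int
    patch_distance: int
    sigma: float = 0.0
    h: float = 0.1

    def __post_init__(self):
        if self.patch_size < 1:
            raise InvalidParameterError("patch_size must be >= 1")
        if self.patch_distance < 1:
            raise InvalidParameterError("patch_distance must be >= 1")
        if not self.h > 0:
            raise InvalidParameterError("h must be > 0")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")

    @property
    def effective_patch_size(self) -> int:
        """Odd patch side actually used (even sizes rounded up)."""
        return self.patch_size if self.patch_size % 2 == 1 else self.patch_size + 1


# ---------------------------------------------------------------------------
# 2D convolution (correlation with edge clamping)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _conv2d_scalar(img, ker):
    H, W = img.shape
    K = ker.shape[0]
    c = K // 2
    out = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for u in range(K):
                ii = i + u - c
                if ii < 0:
                    ii = 0
                elif ii >= H:
                    ii = H - 1
                for v in range(K):
                    jj = j + v - c
                    if jj < 0:
                        jj = 0
                    elif jj >= W:
                        jj = W - 1
                    acc += ker[u, v] * img[ii, jj]
            out[i, j] = acc
    return out


def _conv2d_vectorized(img, ker):
    H, W = img.shape
    K = ker.shape[0]
    c = K // 2
    padded = np.pad(img, c, mode="edge")
    out = np.zeros((H, W))
    for u in range(K):
        for v in range(K):
            w = ker[u, v]
            if w != 0.0:
                out += w * padded[u:u + H, v:v + W]
    return out


def _conv2d_threaded(img, ker):
    H, W = img.shape
    c = ker.shape[0] // 2
    padded = np.pad(img, c, mode="edge")
    n_chunks = min(_N_WORKERS, H)
    bounds = np.linspace(0, H, n_chunks + 1).astype(int)

    def work(r0, r1):
        # padded rows r0 .. r1-1+2c give 'valid' correlation rows r0..r1-1
        return signal.correlate2d(padded[r0:r1 + 2 * c, :], ker, mode="valid")

    with ThreadPoolExecutor(max_workers=n_chunks) as pool:
        parts = list(pool.map(lambda b: work(*b), zip(bounds[:-1], bounds[1:])))
    return np.vstack(parts)


def conv2d(image, kernel, impl_id: str = "vectorized", *, registry=None) -> np.ndarray:
    """Correlate ``image`` with a square odd-sized ``kernel``, edge-clamped.

    out[i, j] = sum_{u,v} kernel[u, v] * image[clamp(i+u-K//2), clamp(j+v-K//2)]
    """
    img = _as_image2d(image)
    ker = _as_kernel(kernel)
    entry = (registry or default_registry).get(CONV2D, impl_id)
    return entry.runner(img, ker)


# ---------------------------------------------------------------------------
# Catmull-Rom integer-factor upsampling
# ---------------------------------------------------------------------------
#
# Cubic convolution basis (a = -1/2):
#   w(t) = 1.5|t|^3 - 2.5|t|^2 + 1            for |t| <= 1
#   w(t) = -0.5|t|^3 + 2.5|t|^2 - 4|t| + 2    for 1 < |t| <= 2
# Output pixel (i, j) samples input position (i/m, j/m); pixel centers at
# integer coordinates, 0-based; border taps edge-clamped.

@njit(cache=True)
def _crw(t):
    t = abs(t)
    if t <= 1.0:
        return (1.5 * t - 2.5) * t * t + 1.0
    if t <= 2.0:
        return ((-0.5 * t + 2.5) * t - 4.0) * t + 2.0
    return 0.0


@njit(cache=True)
def _cr_phase_weights(m):
    # wts[p, k] = basis weight of tap (base + k - 1) for sub-pixel phase p/m
    wts = np.empty((m, 4))
    for p in range(m):
        f = p / m
        wts[p, 0] = _crw(f + 1.0)
        wts[p, 1] = _crw(f)
        wts[p, 2] = _crw(1.0 - f)
        wts[p, 3] = _crw(2.0 - f)
    return wts


@njit(cache=True)
def _cr_frame_scalar(frame, m):
    H, W = frame.shape
    wts = _cr_phase_weights(m)
    out = np.empty((m * H, m * W))
    for oi in range(m * H):
        bi = oi // m
        pi = oi % m
        for oj in range(m * W):
            bj = oj // m
            pj = oj % m
            acc = 0.0
            for ty in range(4):
                ii = bi + ty - 1
                if ii < 0:
                    ii = 0
                elif ii >= H:
                    ii = H - 1
                wy = wts[pi, ty]
                for tx in range(4):
                    jj = bj + tx - 1
                    if jj < 0:
                        jj = 0
                    elif jj >= W:
                        jj = W - 1
                    acc += wy * wts[pj, tx] * frame[ii, jj]
            out[oi, oj] = acc
    return out


def _cr_axis_taps(n: int, m: int):
    """Per-output-pixel tap indices (4, m*n) and weights (4, m*n) for one axis."""
    wts = np.asarray(_cr_phase_weights(m))
    o = np.arange(m * n)
    base = o // m
    phase = o % m
    idx = np.empty((4, m * n), dtype=np.intp)
    w = np.empty((4, m * n))
    for t in range(4):
        idx[t] = np.clip(base + t - 1, 0, n - 1)
        w[t] = wts[phase, t]
    return idx, w


def _cr_frame_rows(frame, m, iy, wy, ix, wx, r0, r1):
    out = np.zeros((r1 - r0, ix.shape[1]))
    for ty in range(4):
        rows = frame[iy[ty, r0:r1], :]
        wrow = wy[ty, r0:r1][:, None]
        for tx in range(4):
            out += (wrow * wx[tx][None, :]) * rows[:, ix[tx]]
    return out


def _cr_frame_vectorized(frame, m):
    H, W = frame.shape
    iy, wy = _cr_axis_taps(H, m)
    ix, wx = _cr_axis_taps(W, m)
    return _cr_frame_rows(frame, m, iy, wy, ix, wx, 0, m * H)


def _cr_frame_threaded(frame, m):
    H, W = frame.shape
    iy, wy = _cr_axis_taps(H, m)
    ix, wx = _cr_axis_taps(W, m)
    n_out = m * H
    n_chunks = min(_N_WORKERS, n_out)
    bounds = np.linspace(0, n_out, n_chunks + 1).astype(int)
    with ThreadPoolExecutor(max_workers=n_chunks) as pool:
        parts = list(
            pool.map(
                lambda b: _cr_frame_rows(frame, m, iy, wy, ix, wx, b[0], b[1]),
                zip(bounds[:-1], bounds[1:]),
            )
        )
    return np.vstack(parts)


def _make_cr_runner(frame_fn):
    def run(stack, magnification):
        out = np.empty(
            (
                stack.shape[0],
                magnification * stack.shape[1],
                magnification * stack.shape[2],
            )
        )
        for t in range(stack.shape[0]):
            out[t] = frame_fn(stack[t], magnification)
        return out

    return run


def catmull_rom_zoom(stack, magnification: int, impl_id: str = "vectorized",
                     *, registry=None) -> np.ndarray:
    """Upsample a stack (or single frame) by an integer factor.

    Each frame is interpolated independently with the Catmull-Rom cubic
    convolution kernel; output shape is T × (m·H) × (m·W).
    """
    if int(magnification) != magnification or magnification < 1:
        raise InvalidParameterError(
            f"magnification must be a positive integer, got {magnification!r}"
        )
    vol, was_2d = _as_stack(stack)
    entry = (registry or default_registry).get(CATMULL_ROM_ZOOM, impl_id)
    out = entry.runner(vol, int(magnification))
    return out[0] if was_2d else out


# ---------------------------------------------------------------------------
# Nonlocal-means denoising
# ---------------------------------------------------------------------------
#
# For pixel i and every in-image neighbor j with |j - i|_inf <= patch_distance:
#   d2(i, j) = mean_q (img[clamp(i+q)] - img[clamp(j+q)])^2,  q in the patch
#   w(i, j)  = exp(-max(d2 - 2 sigma^2, 0) / h^2)
#   out(i)   = sum_j w(i, j) img[j] / sum_j w(i, j)
#
# All implementations use the offset decomposition: for a fixed displacement
# o = j - i, d2 for every pixel at once is a box sum of the squared difference
# field D_o(p) = (img[clamp(p)] - img[clamp(p+o)])^2 evaluated on a grid
# extended by the patch radius. Weight symmetry w(i, j) = w(j, i) lets each
# half-plane offset serve both directions; the self weight is exactly 1.

@njit(cache=True)
def _nlm_scalar(img, ps, pd, sigma, h):
    H, W = img.shape
    r = ps // 2
    eh = H + 2 * r
    ew = W + 2 * r
    num = img.copy()              # self term, weight exactly 1
    den = np.ones((H, W))
    D = np.empty((eh, ew))
    S = np.empty((eh, ew))
    two_s2 = 2.0 * sigma * sigma
    inv_h2 = 1.0 / (h * h)
    area = float(ps * ps)
    for dy in range(0, pd + 1):
        dx0 = 1 if dy == 0 else -pd
        for dx in range(dx0, pd + 1):
            y0 = 0 if dy >= 0 else -dy
            y1 = H - dy if dy >= 0 else H
            x0 = 0 if dx >= 0 else -dx
            x1 = W - dx if dx >= 0 else W
            if y0 >= y1 or x0 >= x1:
                continue
            # squared-difference field on the extended grid (indices = coord + r)
            for ey in range(y0, y1 + 2 * r):
                py = ey - r
                ay = 0 if py < 0 else (H - 1 if py >= H else py)
                qy = py + dy
                by = 0 if qy < 0 else (H - 1 if qy >= H else qy)
                for ex in range(x0, x1 + 2 * r):
                    px = ex - r
                    ax = 0 if px < 0 else (W - 1 if px >= W else px)
                    qx = px + dx
                    bx = 0 if qx < 0 else (W - 1 if qx >= W else qx)
                    d = img[ay, ax] - img[by, bx]
                    D[ey, ex] = d * d
            # horizontal running box sums: S[ey, cx] = sum of D[ey, cx..cx+2r]
            for ey in range(y0, y1 + 2 * r):
                acc = 0.0
                for ex in range(x0, x0 + 2 * r):
                    acc += D[ey, ex]
                for cx in range(x0, x1):
                    acc += D[ey, cx + 2 * r]
                    S[ey, cx] = acc
                    acc -= D[ey, cx]
            # vertical running sums -> d2, weight, symmetric accumulation
            for cx in range(x0, x1):
                acc = 0.0
                for ey in range(y0, y0 + 2 * r):
                    acc += S[ey, cx]
                for cy in range(y0, y1):
                    acc += S[cy + 2 * r, cx]
                    d2 = acc / area
                    acc -= S[cy, cx]
                    e = d2 - two_s2
                    if e < 0.0:
                        e = 0.0
                    w = np.exp(-e * inv_h2)
                    num[cy, cx] += w * img[cy + dy, cx + dx]
                    den[cy, cx] += w
                    num[cy + dy, cx + dx] += w * img[cy, cx]
                    den[cy + dy, cx + dx] += w
    return num / den


def _nlm_half_offsets(pd: int):
    offs = []
    for dy in range(0, pd + 1):
        for dx in range(1 if dy == 0 else -pd, pd + 1):
            offs.append((dy, dx))
    return offs


def _nlm_accumulate_numpy(img, ps, pd, sigma, h, offsets, num, den):
    H, W = img.shape
    r = ps // 2
    A = np.pad(img, r, mode="edge")
    py = np.arange(-r, H + r)
    px = np.arange(-r, W + r)
    two_s2 = 2.0 * sigma * sigma
    inv_h2 = 1.0 / (h * h)
    for dy, dx in offsets:
        y0, y1 = max(0, -dy), min(H, H - dy)
        x0, x1 = max(0, -dx), min(W, W - dx)
        if y0 >= y1 or x0 >= x1:
            continue
        by = np.clip(py + dy, 0, H - 1)
        bx = np.clip(px + dx, 0, W - 1)
        diff = A - img[np.ix_(by, bx)]
        np.square(diff, out=diff)
        mean = ndimage.uniform_filter(diff, size=ps, mode="constant")
        d2 = mean[r:r + H, r:r + W]
        w = np.exp(-np.maximum(d2 - two_s2, 0.0) * inv_h2)
        wv = w[y0:y1, x0:x1]
        num[y0:y1, x0:x1] += wv * img[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
        den[y0:y1, x0:x1] += wv
        num[y0 + dy:y1 + dy, x0 + dx:x1 + dx] += wv * img[y0:y1, x0:x1]
        den[y0 + dy:y1 + dy, x0 + dx:x1 + dx] += wv
    return num, den


def _nlm_vectorized(img, ps, pd, sigma, h):
    num = img.copy()
    den = np.ones_like(img)
    _nlm_accumulate_numpy(img, ps, pd, sigma, h, _nlm_half_offsets(pd), num, den)
    return num / den


def _nlm_threaded(img, ps, pd, sigma, h):
    offsets = _nlm_half_offsets(pd)
    n_chunks = min(_N_WORKERS, len(offsets))
    chunks = [offsets[k::n_chunks] for k in range(n_chunks)]

    def work(chunk):
        return _nlm_accumulate_numpy(
            img, ps, pd, sigma, h, chunk,
            np.zeros_like(img), np.zeros_like(img),
        )

    num = img.copy()
    den = np.ones_like(img)
    with ThreadPoolExecutor(max_workers=n_chunks) as pool:
        for pnum, pden in pool.map(work, chunks):
            num += pnum
            den += pden
    return num / den


def nlm_denoise(image, params: NLMParams, impl_id: str = "vectorized",
                *, registry=None) -> np.ndarray:
    """Nonlocal-means denoise a 2D image (see module notes for the weights)."""
    img = _as_image2d(image)
    if not isinstance(params, NLMParams):
        params = NLMParams(**params)
    entry = (registry or default_registry).get(NLM_DENOISE, impl_id)
    return entry.runner(img, params)


def _make_nlm_runner(core):
    def run(img, params: NLMParams):
        return core(
            img,
            params.effective_patch_size,
            int(params.patch_distance),
            float(params.sigma),
            float(params.h),
        )

    return run


# ---------------------------------------------------------------------------
# implementation registry
# ---------------------------------------------------------------------------

@dataclass
class ImplementationEntry:
    """A registered variant of a method."""

    method_id: str
    impl_id: str
    runner: Callable
    available: bool = True


class Registry:
    """Ordered registry of method implementations.

    Entries are kept in registration order; unavailable entries stay listed
    (so the user can see them) but are excluded from ``only_available``
    listings and never selected by the agent.
    """

    def __init__(self):
        self._methods: dict[str, list[ImplementationEntry]] = {}

    def register(self, entry: ImplementationEntry) -> int:
        entries = self._methods.setdefault(entry.method_id, [])
        if any(e.impl_id == entry.impl_id for e in entries):
            raise DuplicateImplementationError(
                f"{entry.method_id}/{entry.impl_id} already registered"
            )
        entries.append(entry)
        return sum(len(v) for v in self._methods.values())

    def methods(self) -> list[str]:
        return list(self._methods)

    def list(self, method_id: str, only_available: bool = False) -> list[ImplementationEntry]:
        if method_id not in self._methods:
            raise UnknownMethodError(f"unknown method {method_id!r}")
        entries = self._methods[method_id]
        if only_available:
            entries = [e for e in entries if e.available]
        return list(entries)

    def get(self, method_id: str, impl_id: str) -> ImplementationEntry:
        for e in self.list(method_id):
            if e.impl_id == impl_id:
                if not e.available:
                    raise UnknownImplementationError(
                        f"{method_id}/{impl_id} is registered but unavailable"
                    )
                return e
        raise UnknownImplementationError(f"unknown implementation {method_id}/{impl_id}")

    def __len__(self):
        return sum(len(v) for v in self._methods.values())


def register_implementation(entry: ImplementationEntry, registry: Registry | None = None) -> int:
    """Register a variant; returns the registry size after insertion."""
    return (registry or default_registry).register(entry)


def list_implementations(method_id: str, only_available: bool = False,
                         registry: Registry | None = None) -> list[ImplementationEntry]:
    return (registry or default_registry).list(method_id, only_available)


def build_default_registry() -> Registry:
    """Fresh registry holding the nine shipped implementations."""
    reg = Registry()
    reg.register(ImplementationEntry(CONV2D, "unthreaded", _conv2d_scalar))
    reg.register(ImplementationEntry(CONV2D, "threaded", _conv2d_threaded))
    reg.register(ImplementationEntry(CONV2D, "vectorized", _conv2d_vectorized))
    reg.register(ImplementationEntry(
        CATMULL_ROM_ZOOM, "unthreaded", _make_cr_runner(_cr_frame_scalar)))
    reg.register(ImplementationEntry(
        CATMULL_ROM_ZOOM, "threaded", _make_cr_runner(_cr_frame_threaded)))
    reg.register(ImplementationEntry(
        CATMULL_ROM_ZOOM, "vectorized", _make_cr_runner(_cr_frame_vectorized)))
    reg.register(ImplementationEntry(NLM_DENOISE, "unthreaded", _make_nlm_runner(_nlm_scalar)))
    reg.register(ImplementationEntry(NLM_DENOISE, "threaded", _make_nlm_runner(_nlm_threaded)))
    reg.register(ImplementationEntry(NLM_DENOISE, "vectorized", _make_nlm_runner(_nlm_vectorized)))
    return reg


#: registry holding the shipped implementations
default_registry = build_default_registry()


# ---------------------------------------------------------------------------
# input signatures
# ---------------------------------------------------------------------------

def signature_of(method_id: str, *args) -> tuple[float, ...]:
    """Feature vector describing a call's input, in the documented order."""
    if method_id == CONV2D:
        img, ker = args
        img = np.asarray(img)
        ker = np.asarray(ker)
        return (float(img.shape[0]), float(img.shape[1]), float(ker.shape[0]))
    if method_id == CATMULL_ROM_ZOOM:
        stack, m = args
        vol = np.asarray(stack)
        if vol.ndim == 2:
            vol = vol[None]
        return (float(vol.shape[0]), float(vol.shape[1]), float(vol.shape[2]), float(m))
    if method_id == NLM_DENOISE:
        img, params = args
        img = np.asarray(img)
        if not isinstance(params, NLMParams):
            params = NLMParams(**params)
        return (
            float(img.shape[0]), float(img.shape[1]),
            float(params.patch_size), float(params.patch_distance),
            float(params.sigma), float(params.h),
        )
    raise UnknownMethodError(f"unknown method {method_id!r}")
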