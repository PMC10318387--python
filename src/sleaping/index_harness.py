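"""Index-only sampling harness for accuracy and draw-count experiments.

Runs any of the four samplers over the virtual stream ``0 .. n-1`` without
materialising items.  Algorithm R and s-leaping are vectorised here —
phase 1 in uniform-block chunks, phase 2 in per-window blocks — which is
what makes runs at ``n = 1e8`` practical on one core.  The vectorised
paths consume the *same* uniform stream, in the same order, as the scalar
streaming samplers in :mod:`sleaping.samplers`, so for a given seed the
reservoir they return is bitwise identical to feeding ``range(n)`` through
the streaming code.  Algorithms L and Z already run in
``O(k log(n/k))`` via skips, so their index paths are thin scalar loops.

The selected indices can be written either as newline-delimited decimal
text or as a small versioned binary blob (see :func:`save_indices`).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .rng import CountingRandomSource
from .samplers import LeapState, Method, leap_size, sample_skip_z

__all__ = [
    "index_reservoir",
    "run_index_sampler",
    "save_indices",
    "load_indices",
]

_CHUNK = 1 << 20
_TINY = 5e-324


def _apply_writes(res: np.ndarray, slots: np.ndarray, values: np.ndarray) -> None:
    """Apply (slot, value) writes in order; last write to a slot wins."""
    if slots.size == 0:
        return
    # first occurrence in the reversed arrays == last occurrence in order
    uniq, first_rev = np.unique(slots[::-1], return_index=True)
    res[uniq] = values[::-1][first_rev]


def _index_algorithm_r(
    n: int, k: int, source: CountingRandomSource, upto: Optional[int] = None
) -> np.ndarray:
    """Vectorised Algorithm R over indices ``0 .. min(n, upto) - 1``."""
    m = n if upto is None else min(upto, n)
    if m <= k:
        return np.arange(m, dtype=np.int64)
    res = np.arange(k, dtype=np.int64)
    for start in range(k, m, _CHUNK):
        stop = min(start + _CHUNK, m)
        u = source.uniforms(stop - start)
        idx = np.arange(start, stop, dtype=np.int64)
        j = (u * (idx + 1)).astype(np.int64)
        sel = j < k
        _apply_writes(res, j[sel], idx[sel])
    return res


def _index_s_leaping(
    n: int, k: int, epsilon: float, source: CountingRandomSource
) -> np.ndarray:
    """Vectorised s-leaping over indices ``0 .. n-1``."""
    if n <= 2 * k:
        return _index_algorithm_r(n, k, source)
    res = _index_algorithm_r(n, k, source, upto=2 * k)
    s = leap_size(k, epsilon)
    i = 2 * k - 1
    while i < n - 1:
        state = LeapState.window_start(i=i, k=k, s=s)
        lam = state.lam
        j = 0
        # expected selections per window is ~ p*s; draw pairs with headroom
        est = int(2.5 * state.p * s) + 16
        while True:
            block = source.uniforms(2 * est)
            us = np.maximum(block[0::2], _TINY)
            rs = block[1::2]
            nu = (np.log(us) / lam).astype(np.int64) + 1
            cj = j + np.cumsum(nu)
            stop = (cj > s) | (i + cj > n - 1)
            if not stop.any():
                # the whole block is in-window selections
                _apply_writes(res, (rs * k).astype(np.int64), i + cj)
                j = int(cj[-1])
                continue
            t = int(np.argmax(stop))
            _apply_writes(res, (rs[:t] * k).astype(np.int64), i + cj[:t])
            consumed = 2 * t + 1  # t full (nu, slot) pairs plus the stopping nu
            source.unread(block[consumed:])
            if cj[t] > s:
                i += s
                break  # window closed by the overshooting draw
            return res  # stream ends mid-skip
    return res


def _index_algorithm_l(n: int, k: int, source: CountingRandomSource) -> np.ndarray:
    if n <= k:
        return np.arange(n, dtype=np.int64)
    res = np.arange(k, dtype=np.int64)
    c = k - 1
    w = math.exp(math.log(max(source.uniform(), _TINY)) / k)
    while True:
        c += math.floor(math.log(max(source.uniform(), _TINY)) / math.log1p(-w)) + 1
        if c > n - 1:
            return res
        res[source.integer(k)] = c
        w *= math.exp(math.log(max(source.uniform(), _TINY)) / k)


def _index_algorithm_z(n: int, k: int, source: CountingRandomSource) -> np.ndarray:
    if n <= k:
        return np.arange(n, dtype=np.int64)
    res = np.arange(k, dtype=np.int64)
    c = k - 1
    w: Optional[float] = None
    while True:
        skip, w = sample_skip_z(source, k, c + 1, w)
        c += skip + 1
        if c > n - 1:
            return res
        res[source.integer(k)] = c


def index_reservoir(
    n: int,
    k: int,
    method: Union[Method, str],
    epsilon: float = 0.005,
    source: Optional[CountingRandomSource] = None,
    seed: int = 0,
) -> np.ndarray:
    """Run one sampler over the index stream; return slots in reservoir order.

    Slot order is the raw reservoir layout (useful for bitwise-equivalence
    checks); use :func:`run_index_sampler` for the sorted view.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    m = Method.parse(method) if isinstance(method, str) else method
    src = source if source is not None else CountingRandomSource(seed)
    if m is Method.SLEAPING:
        return _index_s_leaping(n, k, epsilon, src)
    if m is Method.ALG_R:
        return _index_algorithm_r(n, k, src)
    if m is Method.ALG_L:
        return _index_algorithm_l(n, k, src)
    if m is Method.ALG_Z:
        return _index_algorithm_z(n, k, src)
    raise ValueError(f"unknown method {method!r}")


def run_index_sampler(
    n: int,
    k: int,
    method: Union[Method, str] = Method.SLEAPING,
    epsilon: float = 0.005,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``min(k, n)`` distinct indices from ``0..n-1``, sorted ascending.

    This is the harness behind every accuracy experiment: the reservoir
    holds indices instead of records, so uniformity can be measured
    directly on the selected positions.
    """
    res = index_reservoir(n, k, method, epsilon=epsilon, seed=seed)
    out = np.sort(res)
    return out


# ---------------------------------------------------------------------------
# on-disk index formats
# ---------------------------------------------------------------------------

#: magic + format version for the binary sorted-index blob
_MAGIC = b"SLIDX001"


def save_indices(indices: np.ndarray, path: Union[str, Path], binary: bool = False) -> None:
    """Write selected indices to disk.

    Text mode writes one decimal index per line.  Binary mode writes the
    magic ``SLIDX001``, a little-endian uint64 count, then the indices as
    little-endian int64 — a stable, versioned layout.
    """
    arr = np.asarray(indices, dtype=np.int64)
    path = Path(path)
    if binary:
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(np.uint64(arr.size).astype("<u8").tobytes())
            fh.write(arr.astype("<i8").tobytes())
    else:
        with open(path, "w") as fh:
            fh.writelines(f"{v}\n" for v in arr.tolist())


def load_indices(path: Union[str, Path]) -> np.ndarray:
    """Read indices written by :func:`save_indices` (either mode)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(len(_MAGIC))
        if head == _MAGIC:
            count = int(np.frombuffer(fh.read(8), dtype="<u8")[0])
            data = np.frombuffer(fh.read(8 * count), dtype="<i8")
            if data.size != count:
                raise ValueError(f"truncated index blob: {path}")
            return data.astype(np.int64)
    return np.loadtxt(path, dtype=np.int64, ndmin=1)
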