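"""Seedable counting random source shared by all samplers.

Every sampler in this package draws its randomness through
:class:`CountingRandomSource`, which wraps a PCG64 generator and counts the
number of variates handed out.  The count is the quantity the draw-number
theory (``sleaping.theory``) predicts, so instrumentation has to be exact:

* one unit uniform == one counted draw;
* one bounded integer == one counted draw (it is derived from a single
  uniform via ``floor(u * bound)``, inverse-transform style, rather than a
  rejection scheme that would consume a variable number of variates);
* vectorised requests consume the same underlying uniform stream as scalar
  requests, in the same order, so a vectorised sampler and its scalar
  streaming twin produce bitwise-identical output for the same seed.

``unread`` pushes unconsumed uniforms back onto the front of the stream;
the vectorised s-leaping window loop uses it to over-draw a block, find the
window boundary, and return the tail.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CountingRandomSource"]

_BLOCK = 4096


class CountingRandomSource:
    """PCG64-backed uniform stream with exact draw accounting.

    Parameters
    ----------
    seed : int
        Seed for the underlying :class:`numpy.random.PCG64` bit generator.
        Identical seeds yield identical variate sequences.
    """

    __slots__ = ("seed", "_rng", "_buf", "_pos", "draws")

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._rng = np.random.Generator(np.random.PCG64(self.seed))
        self._buf = np.empty(0, dtype=np.float64)
        self._pos = 0
        #: number of variates handed out so far
        self.draws = 0

    # -- scalar interface -------------------------------------------------

    def uniform(self) -> float:
        """One unit uniform in [0, 1)."""
        if self._pos >= self._buf.shape[0]:
            self._buf = self._rng.random(_BLOCK)
            self._pos = 0
        u = self._buf[self._pos]
        self._pos += 1
        self.draws += 1
        return float(u)

    def integer(self, bound: int) -> int:
        """One integer uniform on {0, ..., bound-1}; costs one draw."""
        if bound < 1:
            raise ValueError(f"bound must be >= 1, got {bound}")
        return int(self.uniform() * bound)

    # -- vector interface --------------------------------------------------

    def uniforms(self, m: int) -> np.ndarray:
        """``m`` unit uniforms, continuing the same stream as :meth:`uniform`."""
        if m < 0:
            raise ValueError("m must be >= 0")
        avail = self._buf.shape[0] - self._pos
        if m <= avail:
            out = self._buf[self._pos : self._pos + m].copy()
            self._pos += m
        else:
            head = self._buf[self._pos :]
            self._pos = self._buf.shape[0]
            out = np.concatenate([head, self._rng.random(m - avail)])
        self.draws += m
        return out

    def unread(self, tail: np.ndarray) -> None:
        """Push back uniforms that were drawn but not consumed.

        ``tail`` must be the trailing, unconsumed portion of the most recent
        draws, in stream order; subsequent requests will see it again.
        """
        if tail.size == 0:
            return
        self._buf = np.concatenate([np.asarray(tail, dtype=np.float64), self._buf[self._pos :]])
        self._pos = 0
        self.draws -= tail.size
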