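"""Single-pass reservoir samplers over streams of unknown length.

Four samplers share one contract: consume a stream once, in order, and
return a :class:`Reservoir` of at most ``k`` items.

* :func:`algorithm_r` — Waterman's classic method: after the reservoir is
  filled, the *i*-th element (zero-based) replaces a random slot with
  probability ``k/(i+1)``.  One bounded-integer variate per element, used
  both for the accept test and the slot choice, so the total draw count is
  exactly ``n - k``.
* :func:`algorithm_l` — Li's skip-based method: jumps straight to the next
  selected element using exponentially distributed skips; three uniforms
  per selection.
* :func:`algorithm_z` — Vitter's skip-based method: sequential-search skips
  while the stream is short, then rejection sampling from a continuous
  envelope; about two uniforms per selection plus rejection retries.
* :func:`s_leaping` — the approximate hybrid this package exists for:
  exact Algorithm R over the first ``2k`` elements, then windowed
  next-selection with geometric step sizes.  Within a window of ``s``
  elements the selection probability is frozen at ``k/(i+1+0.5s)``, which
  turns the awkward exact step-size distribution into a plain geometric
  one (one uniform per step draw, one per slot choice).

All randomness flows through a :class:`~sleaping.rng.CountingRandomSource`
so draw counts can be checked against the closed forms in
:mod:`sleaping.theory`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

from .rng import CountingRandomSource

__all__ = [
    "Method",
    "SamplerConfig",
    "Reservoir",
    "LeapState",
    "StepDraw",
    "selection_probability",
    "sample_geometric_step",
    "exact_next_step_pmf",
    "algorithm_r",
    "algorithm_l",
    "algorithm_z",
    "s_leaping",
    "sample_skip_z",
    "leap_size",
    "make_sampler",
]

# smallest positive double; guards log(u) for the (astronomically rare)
# u == 0.0 draw so skips stay finite
_TINY = 5e-324

#: Vitter's threshold constant: sequential search while t <= 22 k
_Z_SWITCH = 22


class Method(str, Enum):
    """Sampler selector. Values double as CLI spellings."""

    SLEAPING = "sleaping"
    ALG_R = "algR"
    ALG_L = "algL"
    ALG_Z = "algZ"

    @classmethod
    def parse(cls, name: str) -> "Method":
        aliases = {
            "sleaping": cls.SLEAPING,
            "s-leaping": cls.SLEAPING,
            "sleap": cls.SLEAPING,
            "algr": cls.ALG_R,
            "r": cls.ALG_R,
            "algl": cls.ALG_L,
            "l": cls.ALG_L,
            "algz": cls.ALG_Z,
            "z": cls.ALG_Z,
        }
        try:
            return aliases[name.lower()]
        except KeyError:
            raise ValueError(f"unknown sampling method: {name!r}") from None


def leap_size(k: int, epsilon: float) -> int:
    """Leap size ``s = max(1, floor(epsilon * k))``.

    The floor of ``epsilon * k`` can be zero for tiny reservoirs; clamping
    to 1 keeps the window loop well defined.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return max(1, math.floor(epsilon * k))


@dataclass(frozen=True)
class SamplerConfig:
    """Resolved sampler configuration.

    Attributes
    ----------
    k : reservoir size (number of items, or read pairs, to keep)
    epsilon : leap-size factor; the leap size is ``s = max(1, floor(eps*k))``
    method : which sampler to run
    seed : seed for the counting random source
    """

    k: int
    epsilon: float = 0.005
    method: Method = Method.SLEAPING
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @property
    def s(self) -> int:
        return leap_size(self.k, self.epsilon)


@dataclass
class Reservoir:
    """The sampled items plus a count of stream items consumed."""

    slots: list
    n_seen: int

    def __post_init__(self):
        if len(self.slots) > self.n_seen:
            raise ValueError("reservoir cannot hold more items than were seen")


@dataclass(frozen=True)
class LeapState:
    """Window bookkeeping for the s-leaping inner loop.

    ``i`` is the zero-based index of the last element accounted for by
    completed windows; ``j`` the candidate offset inside the current
    window; ``p`` the frozen window selection probability; ``lam`` is
    ``ln(1 - p)``.
    """

    i: int
    j: int
    p: float
    lam: float

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"window probability must be in (0,1), got {self.p}")
        if self.lam >= 0.0:
            raise ValueError("lam must be negative")

    @classmethod
    def window_start(cls, i: int, k: int, s: int) -> "LeapState":
        p = selection_probability(k, i + 1, s)
        return cls(i=i, j=0, p=p, lam=math.log1p(-p))


@dataclass(frozen=True)
class StepDraw:
    """One geometric step draw: the uniform consumed and the step size."""

    u: float
    nu: int


def selection_probability(k: int, window_start: int, s: int) -> float:
    """Frozen selection probability ``k / (window_start + 0.5 s)``.

    With ``s = 0`` this reduces to the exact per-element probability
    ``k / i`` used by the exact samplers; with ``s > 0`` it is the
    midpoint approximation s-leaping holds constant over one window.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if window_start < 1:
        raise ValueError("window_start must be >= 1")
    if s < 0:
        raise ValueError("s must be >= 0")
    return k / (window_start + 0.5 * s)


def sample_geometric_step(source: CountingRandomSource, lam: float) -> StepDraw:
    """Draw a Geometric(p) step size via inverse transform.

    ``lam`` must be ``ln(1 - p) < 0``; the returned step is
    ``floor(ln(u)/lam) + 1 >= 1`` and costs exactly one uniform.
    """
    if lam >= 0.0:
        raise ValueError("lam must be negative (ln of a probability complement)")
    u = source.uniform()
    nu = math.floor(math.log(max(u, _TINY)) / lam) + 1
    return StepDraw(u=u, nu=nu)


def exact_next_step_pmf(k: int, i: int, nu: int) -> float:
    """Exact probability that the next selection happens ``nu`` steps ahead.

    For a stream position ``i >= k`` (elements 1..i processed, 1-based),
    the next selected element is ``i + nu`` with probability
    ``(k/(i+nu)) * prod_{j=1}^{nu-1} (i+j-k)/(i+j)``.

    This is the brute-force oracle the approximate geometric step
    distribution is tested against.
    """
    if k < 1 or i < k:
        raise ValueError("require i >= k >= 1")
    if nu < 1:
        raise ValueError("nu must be >= 1")
    log_p = math.log(k) - math.log(i + nu)
    for j in range(1, nu):
        log_p += math.log(i + j - k) - math.log(i + j) if i + j - k > 0 else -math.inf
    return math.exp(log_p)


# ---------------------------------------------------------------------------
# stream plumbing
# ---------------------------------------------------------------------------

_SENTINEL = object()


class _Stream:
    """Single-pass cursor over an iterable with one-item lookahead."""

    __slots__ = ("_it", "_pending", "n_read")

    def __init__(self, items: Iterable):
        self._it = iter(items)
        self._pending = _SENTINEL
        self.n_read = 0

    def take(self, m: int):
        """Deliver ``m`` items; return ``(got, last_item)``."""
        got = 0
        last = None
        if m > 0 and self._pending is not _SENTINEL:
            last = self._pending
            self._pending = _SENTINEL
            got = 1
        while got < m:
            try:
                last = next(self._it)
            except StopIteration:
                return got, last
            self.n_read += 1
            got += 1
        return got, last

    def at_eof(self) -> bool:
        if self._pending is _SENTINEL:
            try:
                self._pending = next(self._it)
            except StopIteration:
                return True
            self.n_read += 1
        return False


def _fill(stream: _Stream, k: int) -> list:
    slots = []
    for _ in range(k):
        got, item = stream.take(1)
        if not got:
            break
        slots.append(item)
    return slots


# ---------------------------------------------------------------------------
# the samplers
# ---------------------------------------------------------------------------


def algorithm_r(stream: Iterable, k: int, source: CountingRandomSource) -> Reservoir:
    """Waterman's Algorithm R: one bounded-integer draw per element past k.

    The single-variate trick draws ``r`` uniform on ``[0, i]`` and replaces
    slot ``r`` iff ``r < k`` — the accept decision and the slot choice come
    from the same variate, so exactly ``n - k`` draws are consumed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    st = _Stream(stream)
    slots = _fill(st, k)
    if len(slots) < k:
        return Reservoir(slots, st.n_read)
    i = k - 1
    while True:
        got, item = st.take(1)
        if not got:
            return Reservoir(slots, st.n_read)
        i += 1
        r = source.integer(i + 1)
        if r < k:
            slots[r] = item


def algorithm_l(stream: Iterable, k: int, source: CountingRandomSource) -> Reservoir:
    """Li's Algorithm L: exponential jumps to the next selected element.

    Maintains ``W``, the running maximum-order-statistic factor; each
    selection costs three uniforms (skip, slot, W update), plus one to
    initialise ``W`` and one final skip that overruns the stream.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    st = _Stream(stream)
    slots = _fill(st, k)
    if len(slots) < k or st.at_eof():
        return Reservoir(slots, st.n_read)
    w = math.exp(math.log(max(source.uniform(), _TINY)) / k)
    while True:
        skip = math.floor(math.log(max(source.uniform(), _TINY)) / math.log1p(-w)) + 1
        got, item = st.take(skip)
        if got < skip:
            return Reservoir(slots, st.n_read)
        slots[source.integer(k)] = item
        w *= math.exp(math.log(max(source.uniform(), _TINY)) / k)


def sample_skip_z(
    source: CountingRandomSource, k: int, t: int, w: Optional[float] = None
) -> tuple[int, Optional[float]]:
    """Vitter's skip sampler: number of elements skipped before the next pick.

    ``t`` is the number of elements processed so far (``t >= k``).  While
    ``t <= 22 k`` the skip is found by sequential search (Algorithm X, one
    uniform); afterwards by rejection from the continuous envelope
    ``g(x) = (k/t) (t/(t+x))^(k+1)``, with a cheap majorant test first and
    the exact pmf only on near-misses.  ``w`` carries the envelope variate
    across calls; pass the value returned by the previous call.

    Returns ``(skip, w)``.
    """
    if t < k or k < 1:
        raise ValueError("require t >= k >= 1")
    if t <= _Z_SWITCH * k:
        v = source.uniform()
        s_ = 0
        tt = t
        quot = (tt + 1 - k) / (tt + 1)
        while quot > v:
            s_ += 1
            tt += 1
            quot *= (tt + 1 - k) / (tt + 1)
        return s_, w
    if w is None:
        w = math.exp(-math.log(max(source.uniform(), _TINY)) / k)
    term = t - k + 1
    while True:
        u = max(source.uniform(), _TINY)
        x = t * (w - 1.0)
        s_ = math.floor(x)
        # quick accept: U <= h(s)/(c g(X))
        lhs = math.exp(math.log(((u * ((t + 1) / term) ** 2) * (term + s_)) / (t + x)) / k)
        rhs = (((t + x) / (term + s_)) * term) / t
        if lhs <= rhs:
            w = rhs / lhs
            return s_, w
        # full test: U <= f(s)/(c g(X))
        y = (((u * (t + 1)) / term) * (t + s_ + 1)) / (t + x)
        if k < s_:
            denom = t
            numer_lim = term + s_
        else:
            denom = t - k + s_
            numer_lim = t + 1
        for numer in range(t + s_, numer_lim - 1, -1):
            y = (y * numer) / denom
            denom -= 1
        w = math.exp(-math.log(max(source.uniform(), _TINY)) / k)
        if math.exp(math.log(y) / k) <= (t + x) / t:
            return s_, w


def algorithm_z(stream: Iterable, k: int, source: CountingRandomSource) -> Reservoir:
    """Vitter's Algorithm Z: skip sampling via :func:`sample_skip_z`."""
    if k < 1:
        raise ValueError("k must be >= 1")
    st = _Stream(stream)
    slots = _fill(st, k)
    if len(slots) < k or st.at_eof():
        return Reservoir(slots, st.n_read)
    t = k
    w: Optional[float] = None
    while True:
        skip, w = sample_skip_z(source, k, t, w)
        got, item = st.take(skip + 1)
        if got < skip + 1:
            return Reservoir(slots, st.n_read)
        t += skip + 1
        slots[source.integer(k)] = item


def s_leaping(
    stream: Iterable, k: int, epsilon: float, source: CountingRandomSource
) -> Reservoir:
    """Approximate reservoir sampling with leaping.

    Phase 1 runs Algorithm R over the first ``2k`` elements (identical
    draw sequence, so the two methods agree bitwise while ``n <= 2k``).
    Phase 2 processes the stream in windows of ``s = max(1, floor(eps*k))``
    elements.  Per window the selection probability is frozen at
    ``p = k/(i+1+0.5s)``; candidate offsets advance by Geometric(p) steps
    (one uniform each), and each candidate landing inside the window
    (offset ``1..s``) replaces a uniformly chosen slot (a second uniform).
    A step landing beyond the window closes it with no selection — the
    overshooting draw is discarded, which is part of the approximation.
    Because geometric gaps restarted at each window boundary make the
    per-element arrival indicators independent Bernoulli(p), every element
    of a window is selected at the frozen probability ``p``, and the only
    bias relative to exact sampling is the frozen-vs-exact probability
    discrepancy bounded by ``0.5 eps/(2 + 0.5 eps)``.  If the stream ends
    mid-skip the current reservoir is returned as-is.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    st = _Stream(stream)
    slots = _fill(st, k)
    if len(slots) < k:
        return Reservoir(slots, st.n_read)
    s = leap_size(k, epsilon)
    # phase 1: Algorithm R over elements k .. 2k-1
    i = k - 1
    while i < 2 * k - 1:
        got, item = st.take(1)
        if not got:
            return Reservoir(slots, st.n_read)
        i += 1
        r = source.integer(i + 1)
        if r < k:
            slots[r] = item
    # phase 2: windowed approximate next selection
    c = i  # index of the last element consumed from the stream
    log = math.log
    while not st.at_eof():
        j = 0
        p = k / (i + 1 + 0.5 * s)
        lam = math.log1p(-p)
        while True:
            u = source.uniform()
            nu = math.floor(log(max(u, _TINY)) / lam) + 1
            j += nu
            if j > s:
                # close the window: the overshooting draw selects nothing
                need = i + s - c
                got, _ = st.take(need)
                c += got
                if got < need:
                    return Reservoir(slots, st.n_read)
                i += s
                break
            need = i + j - c
            got, item = st.take(need)
            c += got
            if got < need:
                return Reservoir(slots, st.n_read)
            slots[source.integer(k)] = item
    return Reservoir(slots, st.n_read)


def make_sampler(config: SamplerConfig, source: Optional[CountingRandomSource] = None):
    """Bind a config to a ``stream -> Reservoir`` callable."""
    src = source if source is not None else CountingRandomSource(config.seed)
    m = config.method
    if m is Method.SLEAPING:
        return lambda stream: s_leaping(stream, config.k, config.epsilon, src)
    if m is Method.ALG_R:
        return lambda stream: algorithm_r(stream, config.k, src)
    if m is Method.ALG_L:
        return lambda stream: algorithm_l(stream, config.k, src)
    if m is Method.ALG_Z:
        return lambda stream: algorithm_z(stream, config.k, src)
    raise ValueError(f"unknown method {m!r}")
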