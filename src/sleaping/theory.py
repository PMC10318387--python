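"""Closed-form expected random-number counts for the reservoir samplers.

All formulas are natural-log approximations of harmonic sums.  The exact
harmonic-sum counterparts (via the digamma function) are provided so the
approximations can be checked rather than trusted.

Conventions: ``k`` is the reservoir size, ``n`` the population size,
``x = k/n`` the reservoir-size proportional factor, and ``t`` the number of
random numbers a next-selection method spends on one step-size draw.

A note on the s-leaping count: the two-per-selection form
``k + 2k ln(n/(2k))`` omits the one geometric draw each window spends on
the overshooting step that closes it.  That adds ``(n - 2k)/s`` draws,
negligible when ``s * ln(n/(2k)) >> (n - 2k)/k`` (always true at the data
scales the method targets) but visible for small ``k`` with a small leap
factor.  :func:`expected_draws_sleaping` takes an optional ``epsilon`` to
include the window term.
"""

from __future__ import annotations

import csv
import io
import math
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma

__all__ = [
    "expected_selections",
    "harmonic_selections",
    "expected_draws_next_selection",
    "expected_draws_optimal",
    "expected_draws_algorithm_r",
    "expected_draws_sleaping",
    "sleaping_draws_asymptotic",
    "sleaping_saving_coefficient",
    "efficiency_ratio",
    "efficiency_percent",
    "crossover_fraction",
    "discrepancy_bound",
    "half_ratio_r_vs_optimal",
    "fig_efficiency_table",
]


def _check_kn(k: float, n: float) -> None:
    if not (1 <= k <= n):
        raise ValueError(f"require 1 <= k <= n, got k={k}, n={n}")


def expected_selections(k: float, n: float) -> float:
    """Expected number of reservoir replacements after the fill: ``k ln(n/k)``."""
    _check_kn(k, n)
    return k * math.log(n / k)


def harmonic_selections(k: float, n: float) -> float:
    """Exact harmonic-sum form ``sum_{i=k+1}^{n} k/i`` (digamma identity)."""
    _check_kn(k, n)
    return k * (digamma(n + 1) - digamma(k + 1))


def expected_draws_next_selection(k: float, n: float, t: float) -> float:
    """Draws for a next-selection method spending ``t`` per step: ``k(t+1)ln(n/k)``."""
    _check_kn(k, n)
    if t < 1:
        raise ValueError("every step-size sampler needs t >= 1")
    return k * (t + 1) * math.log(n / k)


def expected_draws_optimal(k: float, n: float) -> float:
    """Best possible next-selection count (``t = 1``): ``2k ln(n/k)``."""
    return expected_draws_next_selection(k, n, 1)


def expected_draws_algorithm_r(k: float, n: float) -> float:
    """Algorithm R consumes exactly one variate per element past the fill."""
    _check_kn(k, n)
    return n - k


def expected_draws_sleaping(k: float, n: float, epsilon: Optional[float] = None) -> float:
    """Expected s-leaping draws: ``k + 2k ln(n/(2k))``.

    Phase 1 (Algorithm R over ``2k`` elements) costs ``k`` draws; phase 2
    about two per selection.  With ``epsilon`` given, the once-per-window
    overshoot draw — ``(n - 2k)/s`` in total — is added (see module note).
    """
    _check_kn(k, n)
    if n < 2 * k:
        raise ValueError("phase 2 requires n >= 2k; below that s-leaping is Algorithm R")
    base = k + 2 * k * math.log(n / (2 * k))
    if epsilon is not None:
        s = max(1, math.floor(epsilon * k))
        base += (n - 2 * k) / s
    return base


def sleaping_saving_coefficient() -> float:
    """Per-k draw saving of s-leaping over the optimal next selection: ``2 ln 2 - 1``."""
    return 2 * math.log(2) - 1


def sleaping_draws_asymptotic(k: float, n: float) -> float:
    """Equivalent asymptotic form ``2k ln(n/k) - (2 ln 2 - 1) k``."""
    _check_kn(k, n)
    return 2 * k * math.log(n / k) - sleaping_saving_coefficient() * k


def efficiency_ratio(x: float, method: str = "sleaping") -> float:
    """Expected draws of a method relative to Algorithm R, as a function of ``x = k/n``.

    * ``sleaping``: ``(x + 2x ln(1/(2x))) / (1 - x)`` on ``0 < x < 0.5``
    * ``optimal``:  ``2x ln(1/x) / (1 - x)``          on ``0 < x < 1``

    Values below 1 mean fewer draws than Algorithm R.
    """
    if method == "sleaping":
        if not (0.0 < x < 0.5):
            raise ValueError("s-leaping ratio needs 0 < x < 0.5 (phase 2 requires n >= 2k)")
        return (x + 2 * x * math.log(1 / (2 * x))) / (1 - x)
    if method == "optimal":
        if not (0.0 < x < 1.0):
            raise ValueError("optimal-next-selection ratio needs 0 < x < 1")
        return 2 * x * math.log(1 / x) / (1 - x)
    raise ValueError(f"unknown method {method!r}; expected 'sleaping' or 'optimal'")


def efficiency_percent(x: float, method: str = "sleaping") -> int:
    """Signed integer percent advantage over Algorithm R.

    ``+15`` means the method needs 15% fewer random numbers than Algorithm R
    at this ``x`` (equivalently, R would need 15% more); negative values
    mean the method is less efficient.  Rounded to the nearest percent.
    """
    ratio = efficiency_ratio(x, method)
    return round(100 * (1 / ratio - 1))


def crossover_fraction() -> float:
    """The ``x = k/n`` where the optimal next selection ties Algorithm R.

    Root of ``2x ln(1/x) = 1 - x`` on (0, 1), bracketed to 1e-9; rounds to
    0.3 at one decimal.
    """
    f = lambda x: 2 * x * math.log(1 / x) - (1 - x)
    return float(brentq(f, 0.05, 0.49, xtol=1e-9))


def discrepancy_bound(epsilon: float) -> float:
    """Maximum relative overestimate of the frozen selection probability.

    The worst case is the last element of the first window (``i = 2k + s``),
    where the frozen ``k/(2k + 0.5 s)`` overshoots the exact ``k/i`` by a
    relative ``0.5 eps / (2 + 0.5 eps)`` — 0.00125 at the default
    ``eps = 0.005``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return 0.5 * epsilon / (2 + 0.5 * epsilon)


def half_ratio_r_vs_optimal() -> float:
    """Algorithm R draws over the first ``2k`` elements relative to the optimum.

    ``k / (2k ln 2) = 1/(2 ln 2) ~ 0.72`` — i.e. R spends about 28% fewer
    random numbers than the best next-selection method up to element 2k,
    which is why s-leaping starts with an Algorithm-R phase.
    """
    return 1 / (2 * math.log(2))


def fig_efficiency_table(
    xs: Optional[Sequence[float]] = None,
    out: Union[None, str, io.TextIOBase] = None,
) -> list[tuple[float, float, float]]:
    """Tabulate ``(x, ratio_sleaping, ratio_optimal)`` efficiency curves.

    With ``out`` given (path or text file object), also writes the rows as
    CSV with a header.  The s-leaping column is NaN where ``x >= 0.5``.
    """
    if xs is None:
        xs = np.round(np.arange(0.01, 0.50, 0.01), 4)
    rows = []
    for x in xs:
        x = float(x)
        r_s = efficiency_ratio(x, "sleaping") if 0 < x < 0.5 else math.nan
        r_o = efficiency_ratio(x, "optimal")
        rows.append((x, r_s, r_o))
    if out is not None:
        is_path = not hasattr(out, "write")
        fh = open(out, "w", newline="") if is_path else out
        try:
            writer = csv.writer(fh)
            writer.writerow(["x", "ratio_sleaping", "ratio_optimal"])
            writer.writerows(rows)
        finally:
            if is_path:
                fh.close()
    return rows
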