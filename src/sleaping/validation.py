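"""Uniformity validation of sampler output.

An unbiased reservoir sample of indices from ``0..n-1``, rescaled to
[0, 1), should look uniform.  The accuracy statistic used throughout is
the binned maximum D: the empirical CDF of the normalized selected indices
is evaluated at 1000 equispaced bin boundaries (permille resolution) and
compared against the identity CDF; the largest absolute difference is
``d_max``.  This is the one-sample Kolmogorov–Smirnov sup-distance coarsened
to the bin grid, and the exact statistic (:func:`max_d_exact`) never
differs from it by more than ``1/bins``.

:func:`uniformity_experiment` repeats a sampler run over consecutive seeds
and summarises the per-run ``d_max`` values, which is how the accuracy of
the approximate sampler is compared against the exact ones.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .index_harness import run_index_sampler
from .samplers import Method

__all__ = [
    "MaxDResult",
    "UniformityReport",
    "max_d_binned",
    "max_d_exact",
    "ks_threshold",
    "uniformity_experiment",
    "ratio_ci_taylor",
    "reports_to_csv",
    "reports_to_json",
    "plot_maxd",
]

DEFAULT_BINS = 1000


@dataclass(frozen=True)
class MaxDResult:
    """Binned maximum discrepancy of selected indices against uniform."""

    d_max: float
    bins: int
    k_points: int
    n_total: int

    def __post_init__(self):
        if not (0.0 <= self.d_max <= 1.0):
            raise ValueError("d_max must lie in [0, 1]")


@dataclass
class UniformityReport:
    """Per-run d_max values for one (method, k, n, epsilon) setting."""

    method: str
    k: int
    n: int
    epsilon: float
    reps: int
    seeds: list[int] = field(default_factory=list)
    d_values: list[float] = field(default_factory=list)
    mean_d: float = math.nan
    sd_d: Optional[float] = None


def max_d_binned(
    indices: np.ndarray, n: int, bins: int = DEFAULT_BINS
) -> MaxDResult:
    """Binned maximum D of sorted, distinct indices in ``[0, n)``.

    Indices are normalized to [0, 1) by dividing by ``n``; the
    right-continuous ECDF is evaluated at the boundaries ``b/bins`` for
    ``b = 1..bins`` and compared with the uniform CDF at the same points.
    """
    idx = np.asarray(indices)
    if idx.ndim != 1 or idx.size == 0:
        raise ValueError("indices must be a nonempty 1-d sequence")
    if idx[0] < 0 or idx[-1] >= n:
        raise ValueError("indices must lie in [0, n)")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("indices must be sorted ascending and distinct")
    fracs = idx / float(n)
    bounds = np.arange(1, bins + 1) / bins
    ecdf = np.searchsorted(fracs, bounds, side="right") / idx.size
    d = float(np.max(np.abs(ecdf - bounds)))
    return MaxDResult(d_max=d, bins=bins, k_points=int(idx.size), n_total=int(n))


def max_d_exact(samples: Sequence[float]) -> float:
    """One-sample KS sup-distance of values in [0, 1) against uniform.

    The exact statistic over the sample points themselves; used as the
    oracle for :func:`max_d_binned`.
    """
    x = np.sort(np.asarray(samples, dtype=np.float64))
    m = x.size
    if m == 0:
        raise ValueError("need at least one sample")
    hi = np.arange(1, m + 1) / m
    lo = np.arange(0, m) / m
    return float(max(np.max(hi - x), np.max(x - lo)))


def ks_threshold(alpha_label: float, n_points: int, bins: Optional[int] = None) -> float:
    """Asymptotic one-sample KS critical value ``K / sqrt(n_points)``.

    ``alpha_label`` is the quoted significance label; the threshold is the
    value a max-D sample exceeds with probability ``1 - alpha_label`` under
    the null, i.e. ``kstwobign.isf(1 - alpha_label) / sqrt(n_points)``.
    Reported for context in experiment summaries only — the label's exact
    interpretation in the literature this mirrors is ambiguous, so nothing
    is ever asserted against it.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not (0.0 < alpha_label < 1.0):
        raise ValueError("alpha_label must be in (0, 1)")
    kappa = float(stats.kstwobign.isf(1.0 - alpha_label))
    return kappa / math.sqrt(n_points)


def uniformity_experiment(
    method: Union[Method, str],
    k: int,
    n: int,
    epsilon: float = 0.005,
    reps: int = 10,
    base_seed: int = 0,
    bins: int = DEFAULT_BINS,
) -> UniformityReport:
    """Run a sampler ``reps`` times and summarise the binned max-D values.

    Seeds are ``base_seed .. base_seed + reps - 1``.  With a single rep the
    standard deviation is undefined and reported as ``None``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    m = Method.parse(method) if isinstance(method, str) else method
    seeds = list(range(base_seed, base_seed + reps))
    d_values = []
    for seed in seeds:
        idx = run_index_sampler(n, k, m, epsilon=epsilon, seed=seed)
        d_values.append(max_d_binned(idx, n, bins=bins).d_max)
    arr = np.asarray(d_values)
    return UniformityReport(
        method=m.value,
        k=k,
        n=n,
        epsilon=epsilon,
        reps=reps,
        seeds=seeds,
        d_values=d_values,
        mean_d=float(arr.mean()),
        sd_d=float(arr.std(ddof=1)) if reps > 1 else None,
    )


def ratio_ci_taylor(
    mean_num: float,
    sd_num: float,
    mean_den: float,
    sd_den: float,
    n_pairs: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Delta-method CI for the ratio of two independent sample means.

    Second-order Taylor expansion of ``X/Y`` around the means with zero
    covariance: the point estimate carries the curvature correction
    ``m_x s_y^2 / (N m_y^3)`` and the variance is
    ``s_x^2/(N m_y^2) + m_x^2 s_y^2/(N m_y^4)``.
    """
    if mean_den == 0:
        raise ValueError("denominator mean must be nonzero")
    if n_pairs < 2:
        raise ValueError("need at least two pairs")
    var_num = sd_num**2 / n_pairs
    var_den = sd_den**2 / n_pairs
    center = mean_num / mean_den + mean_num * var_den / mean_den**3
    se = math.sqrt(var_num / mean_den**2 + mean_num**2 * var_den / mean_den**4)
    z = float(stats.norm.ppf(0.5 + level / 2))
    return (center - z * se, center + z * se)


# ---------------------------------------------------------------------------
# report emitters
# ---------------------------------------------------------------------------


def reports_to_csv(reports: Sequence[UniformityReport], out) -> None:
    """Write per-run rows (method, k, n, epsilon, seed, d_max) plus summary rows."""
    is_path = not hasattr(out, "write")
    fh = open(out, "w", newline="") if is_path else out
    try:
        w = csv.writer(fh)
        w.writerow(["row", "method", "k", "n", "epsilon", "seed", "d_max", "mean_d", "sd_d"])
        for rep in reports:
            for seed, d in zip(rep.seeds, rep.d_values):
                w.writerow(["run", rep.method, rep.k, rep.n, rep.epsilon, seed, f"{d:.6e}", "", ""])
            sd = "" if rep.sd_d is None else f"{rep.sd_d:.6e}"
            w.writerow(["summary", rep.method, rep.k, rep.n, rep.epsilon, "", "", f"{rep.mean_d:.6e}", sd])
    finally:
        if is_path:
            fh.close()


def reports_to_json(reports: Sequence[UniformityReport], out) -> None:
    payload = [asdict(rep) for rep in reports]
    is_path = not hasattr(out, "write")
    fh = open(out, "w") if is_path else out
    try:
        json.dump(payload, fh, indent=2)
    finally:
        if is_path:
            fh.close()


def plot_maxd(reports: Sequence[UniformityReport], path: Union[str, Path]) -> None:
    """Violin summary of per-run max-D distributions, one violin per report.

    Optional hook; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(reports) + 2, 4))
    ax.violinplot([r.d_values for r in reports], showmeans=True)
    ax.set_xticks(range(1, len(reports) + 1))
    ax.set_xticklabels(
        [f"{r.method}\nk={r.k:g}\nn={r.n:g}\neps={r.epsilon:g}" for r in reports],
        fontsize=7,
    )
    ax.set_ylabel("maximum D vs uniform")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
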