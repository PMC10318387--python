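"""Unit and property tests for the streaming samplers and their primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sleaping.rng import CountingRandomSource
from sleaping.samplers import (
    Method,
    Reservoir,
    SamplerConfig,
    algorithm_l,
    algorithm_r,
    algorithm_z,
    exact_next_step_pmf,
    leap_size,
    s_leaping,
    sample_geometric_step,
    sample_skip_z,
    selection_probability,
)
from sleaping.index_harness import index_reservoir

STREAM_FNS = {
    "algR": algorithm_r,
    "algL": algorithm_l,
    "algZ": algorithm_z,
}


def _planted(values):
    """A source whose next uniforms are the given values."""
    src = CountingRandomSource(0)
    src.unread(np.asarray(values, dtype=float))
    src.draws = 0
    return src


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "k,window_start,s,expected",
    [
        (10, 20, 0, 0.5),
        (20_000_000, 40_000_001, 100_000, 20_000_000 / 40_050_001.0),
    ],
)
def test_selection_probability_values(k, window_start, s, expected):
    assert selection_probability(k, window_start, s) == pytest.approx(expected, rel=1e-12)


def test_selection_probability_rejects_bad_inputs():
    with pytest.raises(ValueError):
        selection_probability(0, 10, 5)
    with pytest.raises(ValueError):
        selection_probability(10, 0, 5)
    with pytest.raises(ValueError):
        selection_probability(10, 10, -1)


def test_frozen_probability_discrepancy_at_first_window_end():
    """The frozen window probability overshoots exact k/i by 0.5e/(2+0.5e) at i=2k+s."""
    k = 10_000_000
    eps = 0.005
    s = leap_size(k, eps)
    frozen = selection_probability(k, 2 * k + 1, s)  # window start m = 2k+1 ~ 2k
    # worst case at the window's last element, i = 2k + s (1-based)
    frozen_exact_style = k / (2 * k + 0.5 * s)
    exact = k / (2 * k + s)
    rel = (frozen_exact_style - exact) / exact
    assert rel == pytest.approx(0.5 * eps / (2 + 0.5 * eps), rel=1e-9)
    assert frozen == pytest.approx(frozen_exact_style, rel=1e-6)


@pytest.mark.parametrize("u,p,expected", [(0.6, 0.5, 1), (0.2, 0.5, 3)])
def test_geometric_step_worked_values(u, p, expected):
    src = _planted([u])
    draw = sample_geometric_step(src, math.log(1 - p))
    assert draw.nu == expected
    assert draw.u == u
    assert src.draws == 1


def test_geometric_step_rejects_nonnegative_lam():
    with pytest.raises(ValueError):
        sample_geometric_step(CountingRandomSource(0), 0.0)


def test_geometric_step_distribution_matches_geometric_pmf():
    """Empirical pmf of inverse-transform steps agrees with Geometric(0.1)."""
    p = 0.1
    lam = math.log1p(-p)
    src = CountingRandomSource(2024)
    n_draws = 300_000
    draws = np.array([sample_geometric_step(src, lam).nu for _ in range(n_draws)])
    assert src.draws == n_draws
    kmax = 60
    observed = np.bincount(np.minimum(draws, kmax + 1), minlength=kmax + 2)[1:]
    pmf = p * (1 - p) ** (np.arange(1, kmax + 1) - 1)
    expected = np.append(pmf, 1 - pmf.sum()) * n_draws
    chi2 = stats.chisquare(observed, expected)
    assert chi2.pvalue > 0.01


def test_exact_next_step_pmf_values():
    assert exact_next_step_pmf(4, 9, 1) == pytest.approx(4 / 10)
    assert exact_next_step_pmf(2, 2, 2) == pytest.approx(1 / 6)


def test_exact_next_step_pmf_total_probability():
    """Step pmf plus the no-further-selection mass sums to one."""
    k, i, n = 3, 5, 20
    total = sum(exact_next_step_pmf(k, i, nu) for nu in range(1, n - i + 1))
    p_none = math.prod((i + j - k) / (i + j) for j in range(1, n - i + 1))
    assert total + p_none == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# config / reservoir types
# ---------------------------------------------------------------------------


def test_sampler_config_derives_leap_size():
    cfg = SamplerConfig(k=10_000_000, epsilon=0.005)
    assert cfg.s == 50_000
    assert SamplerConfig(k=10, epsilon=0.005).s == 1  # clamped
    with pytest.raises(ValueError):
        SamplerConfig(k=0)
    with pytest.raises(ValueError):
        SamplerConfig(k=10, epsilon=0.0)


def test_method_parsing():
    assert Method.parse("s-leaping") is Method.SLEAPING
    assert Method.parse("ALGZ") is Method.ALG_Z
    with pytest.raises(ValueError):
        Method.parse("bogus")


# ---------------------------------------------------------------------------
# sampler behaviour
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name", ["algR", "algL", "algZ", "sleaping"])
def test_short_stream_is_kept_verbatim_with_no_draws(name):
    src = CountingRandomSource(1)
    if name == "sleaping":
        res = s_leaping(range(5), 5, 0.05, src)
    else:
        res = STREAM_FNS[name](range(5), 5, src)
    assert res.slots == [0, 1, 2, 3, 4]
    assert res.n_seen == 5
    assert src.draws == 0


@pytest.mark.parametrize("name", ["algR", "algL", "algZ", "sleaping"])
def test_empty_stream(name):
    src = CountingRandomSource(1)
    if name == "sleaping":
        res = s_leaping(iter([]), 3, 0.1, src)
    else:
        res = STREAM_FNS[name](iter([]), 3, src)
    assert res.slots == [] and res.n_seen == 0 and src.draws == 0


def test_single_pass_in_order():
    """Each stream item is requested exactly once, in stream order."""
    for name in ["algR", "algL", "algZ", "sleaping"]:
        seen = []

        def gen(n=200):
            for i in range(n):
                seen.append(i)
                yield i

        src = CountingRandomSource(3)
        if name == "sleaping":
            s_leaping(gen(), 20, 0.1, src)
        else:
            STREAM_FNS[name](gen(), 20, src)
        assert seen == list(range(200)), name


@pytest.mark.parametrize("name", ["algR", "algL", "algZ", "sleaping"])
@pytest.mark.parametrize("n,k,seed", [(500, 50, 1), (1000, 7, 3), (60, 7, 9),
                                      (40, 40, 2), (41, 40, 5), (3, 8, 0)])
def test_streaming_and_index_paths_agree_bitwise(name, n, k, seed):
    """The vectorised index harness replays the exact scalar draw stream."""
    s1, s2 = CountingRandomSource(seed), CountingRandomSource(seed)
    if name == "sleaping":
        res = s_leaping(range(n), k, 0.05, s1)
        vec = index_reservoir(n, k, name, epsilon=0.05, source=s2)
    else:
        res = STREAM_FNS[name](range(n), k, s1)
        vec = index_reservoir(n, k, name, source=s2)
    assert list(vec) == list(res.slots)
    assert s1.draws == s2.draws


@pytest.mark.parametrize(
    "n,k,eps,seed",
    [(5000, 100, 0.05, 1), (5000, 100, 0.005, 2), (300, 40, 0.1, 5),
     (1000, 100, 0.5, 7), (201, 100, 0.05, 6), (100_000, 500, 0.01, 8)],
)
def test_sleaping_streaming_and_index_paths_agree_bitwise(n, k, eps, seed):
    s1, s2 = CountingRandomSource(seed), CountingRandomSource(seed)
    res = s_leaping(range(n), k, eps, s1)
    vec = index_reservoir(n, k, "sleaping", epsilon=eps, source=s2)
    assert list(vec) == list(res.slots)
    assert s1.draws == s2.draws
    assert res.n_seen == n


def test_sleaping_identical_to_algorithm_r_below_2k():
    """Phase 1 is Algorithm R, so the two agree bitwise whenever n <= 2k."""
    rng = np.random.default_rng(0)
    for _ in range(30):
        k = int(rng.integers(2, 300))
        n = int(rng.integers(1, 2 * k + 1))
        seed = int(rng.integers(0, 2**31))
        a = index_reservoir(n, k, "algR", seed=seed)
        b = index_reservoir(n, k, "sleaping", epsilon=0.05, seed=seed)
        assert np.array_equal(a, b), (n, k, seed)


def test_algorithm_r_draw_count_is_exactly_n_minus_k():
    for n, k, seed in [(10**6, 10**5, 0), (5000, 17, 3), (100, 100, 1)]:
        src = CountingRandomSource(seed)
        index_reservoir(n, k, "algR", source=src)
        assert src.draws == n - k


def test_sleaping_never_draws_more_than_algorithm_r():
    """Draw-count monotonicity in the regime the leap is designed for.

    The saving argument needs a nondegenerate window (floor(eps*k) well
    above 1, so the once-per-window overshoot draw amortises) and n
    comfortably above 2k (the first windows, where p ~ 0.5, cost about as
    much per element as Algorithm R and are only paid back later).
    """
    rng = np.random.default_rng(42)
    for _ in range(25):
        k = int(rng.integers(100, 400))
        n = int(rng.integers(10 * k, 50 * k))
        seed = int(rng.integers(0, 2**31))
        s_r, s_s = CountingRandomSource(seed), CountingRandomSource(seed)
        index_reservoir(n, k, "algR", source=s_r)
        index_reservoir(n, k, "sleaping", epsilon=0.05, source=s_s)
        assert s_s.draws <= s_r.draws, (n, k, seed)


def test_algorithm_l_mean_draws_is_three_per_selection():
    """Algorithm L spends ~3 k ln(n/k) random numbers on average."""
    n, k = 10**6, 10**3
    draws = []
    for seed in range(100):
        src = CountingRandomSource(seed)
        index_reservoir(n, k, "algL", source=src)
        draws.append(src.draws)
    expected = 3 * k * math.log(n / k)
    assert np.mean(draws) == pytest.approx(expected, rel=0.10)


def test_algorithm_z_draws_at_least_two_per_selection():
    n, k = 200_000, 500
    tot_draws = 0
    reps = 20
    for seed in range(reps):
        src = CountingRandomSource(seed)
        index_reservoir(n, k, "algZ", source=src)
        tot_draws += src.draws
    selections = k * math.log(n / k)  # expected replacement count
    per_sel = tot_draws / reps / selections
    assert 2.0 <= per_sel < 3.5


@pytest.mark.parametrize(
    "k,t,n_draws",
    [(50, 500, 200_000),    # sequential-search branch (t <= 22k)
     (5, 200, 200_000)],    # rejection branch (t > 22k)
)
def test_z_skip_distribution_matches_exact_pmf(k, t, n_draws):
    """Vitter's skip sampler reproduces the exact next-step distribution."""
    src = CountingRandomSource(99)
    skips = np.empty(n_draws, dtype=np.int64)
    w = None
    for i in range(n_draws):
        skips[i], w = sample_skip_z(src, k, t, w)
    nu = skips + 1  # step size = skip + 1
    kmax = int(np.percentile(nu, 99.5))
    observed = np.bincount(np.minimum(nu, kmax + 1), minlength=kmax + 2)[1:]
    pmf = np.array([exact_next_step_pmf(k, t, v) for v in range(1, kmax + 1)])
    expected = np.append(pmf, 1 - pmf.sum()) * n_draws
    keep = expected >= 5
    chi2 = stats.chisquare(observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum())
    assert chi2.pvalue > 0.01


@given(
    n=st.integers(0, 120),
    k=st.integers(1, 40),
    seed=st.integers(0, 10_000),
    name=st.sampled_from(["algR", "algL", "algZ", "sleaping"]),
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_reservoir_invariants(n, k, seed, name):
    """Size is min(k, n); items are distinct stream elements; prefix kept when n<=k."""
    src = CountingRandomSource(seed)
    if name == "sleaping":
        res = s_leaping(range(n), k, 0.1, src)
    else:
        res = STREAM_FNS[name](range(n), k, src)
    assert len(res.slots) == min(k, n)
    assert res.n_seen == n
    assert len(set(res.slots)) == len(res.slots)
    assert all(0 <= v < n for v in res.slots)
    if n <= k:
        assert res.slots == list(range(n))


def test_reservoir_rejects_impossible_counts():
    with pytest.raises(ValueError):
        Reservoir(slots=[1, 2, 3], n_seen=2)
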