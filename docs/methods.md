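# Methods

## Problem and model

Downsampling selects exactly `k` reads uniformly at random from a
sequencing file of unknown total size `n` in a single pass — the reservoir
sampling problem. Every element must end with inclusion probability
`k/n`. Exact solutions come in two families:

* **Per-element testing** (Algorithm R): after filling the reservoir with
  the first `k` elements, element `i` (1-based) replaces a uniformly
  chosen slot with probability `k/i`. With the single-variate trick
  (draw an integer uniform on `[0, i-1]`; replace that slot iff it is
  `< k`), the accept decision and the slot choice share one variate, so
  the total cost is exactly `n - k` random numbers.
* **Next-selection methods** (Algorithms L and Z): sample the gap to the
  next replaced element directly. The exact gap distribution
  `p(ν|i) = (k/(i+ν)) ∏_{j=1}^{ν-1} (i+j-k)/(i+j)` is awkward, so L
  (Li 1994) uses exponential jumps driven by a running maximum-order-
  statistic factor (three uniforms per selection) and Z (Vitter 1985)
  uses rejection sampling from the envelope `g(x) = (k/t)(t/(t+x))^{k+1}`
  (about two uniforms per selection, with retries). Expected selections
  after the fill: `k ln(n/k)`.

**s-leaping** is the approximate hybrid this package is built around.
Phase 1 runs Algorithm R over the first `2k` elements (where the
selection probability is ≥ 0.5 and per-element testing is cheapest — R
spends `1/(2 ln 2) ≈ 0.72` of what the best next-selection method would
spend on that prefix). Phase 2 processes the remaining stream in windows
of `s = max(1, floor(ε·k))` elements. Within a window starting after
element `i`, the selection probability is frozen at the midpoint value
`p = k/(i+1+0.5s)`, which collapses the exact gap distribution to
Geometric(p): gaps are `ν = floor(ln(u)/ln(1-p)) + 1`, one uniform each,
plus one uniform per selection for the slot. A gap landing beyond the
window closes it (the overshooting draw is discarded) and the next
window refreshes `p`.

### Window-boundary convention

With geometric gaps restarted at each window boundary, the per-element
selection indicators inside a window are i.i.d. Bernoulli(p) — provided
every one of the `s` window offsets is selectable. We therefore close a
window when the accumulated offset *exceeds* `s` (offsets `1..s` can be
selected; the window then advances by `s`). Under the alternative
reading, which closes at offset ≥ `s`, the last element of every window
would have selection probability exactly zero; at desk scales (`s` of a
few units) that produces inclusion biases of tens of percent and
contradicts the error bound below, while at production scales
(`s ≥ 20 000`) the two conventions are statistically indistinguishable.
We use the convention consistent with the error analysis.

### Error bound

The only bias of the method is the frozen probability versus the exact
`k/i`. The worst case over the whole stream is the last element of the
first window (`i = 2k + s`), where the relative overestimate is

    (k/(2k+0.5s) - k/(2k+s)) / (k/(2k+s)) = 0.5ε / (2 + 0.5ε)

— `0.00125` at the default `ε = 0.005`, and still only `~2.4%` at
`ε = 0.1`. `theory.discrepancy_bound` is this closed form; a test checks
it against brute-force maximization over the window.

## Random-number accounting

All randomness flows through `CountingRandomSource` (PCG64), which
counts one per unit uniform and one per bounded integer (derived from a
single uniform by inverse transform, never by rejection — this is what
makes the counts exact and the closed forms testable). Closed forms:

| method | expected draws |
|---|---|
| Algorithm R | `n - k` (exact, any seed) |
| next selection, `t` per step | `k (t+1) ln(n/k)` |
| optimal next selection (`t=1`) | `2k ln(n/k)` |
| s-leaping | `k + 2k ln(n/(2k)) = 2k ln(n/k) - (2 ln 2 - 1) k` |

so s-leaping saves `≈ 0.39k` draws over the optimal next-selection
method, and beats Algorithm R for `k/n` below ≈ 0.5 (the optimal method
only does so below the crossover `x* ≈ 0.285`, the root of
`2x ln(1/x) = 1 - x`, which rounds to 0.3).

**Caveat we document rather than hide:** the s-leaping closed form counts
only the two-per-selection draws. The discarded overshoot draw costs one
uniform per window, `(n-2k)/s` in total. At production scale (`k = 10⁷`,
`n = 10⁸`, `ε = 0.005`: 1600 windows against 3.2×10⁷ selection draws)
this is negligible; at small `k` with a small leap factor it is not
(`k = 10⁴`, `n = 10⁶`, `ε = 0.005`: ≈ +22%). The calibration tests
therefore run at `ε = 0.1` (window overhead ≈ 1%) and additionally
verify a refined predictor that includes the `(n-2k)/s` term at
`ε = 0.005`. Similarly, the draw-count advantage over Algorithm R is an
expectation that holds per-seed only when `s ≫ 1` and `n` is well above
`2k`; with the clamp `s = max(1, floor(ε·k)) = 1` every window costs at
least one draw per element and s-leaping is *more* expensive than R.
The clamp exists only to keep tiny-`k` configurations well defined.

## Uniformity validation

Accuracy is measured by the binned maximum D: selected indices are
sorted, normalized by `n`, and the empirical CDF is evaluated at the
1000 permille boundaries; `d_max` is the largest absolute deviation from
the uniform CDF. This is the one-sample Kolmogorov–Smirnov statistic
coarsened to the bin grid; it never differs from the exact statistic by
more than `1/bins` (tested on random index sets), and we use the
right-continuous ECDF convention (the convention choice moves `d_max` by
at most `1/k`, far below every tolerance used). The experiment driver
runs a sampler over consecutive seeds and reports per-run `d` values
with their mean and (for ≥ 2 runs) sample sd.

At the full experimental scale (`k = 2×10⁷` from `n = 10⁸`) ten seeded
s-leaping runs at `ε = 0.1` give mean `d_max ≈ 1.9×10⁻⁴` (sd
`≈ 5.6×10⁻⁵`), indistinguishable from Algorithm R at the same setting,
and every run across `ε ∈ [0.001, 0.1]` stays below `4×10⁻⁴`. A
reported asymptotic KS critical value is included in reports for context
only; its significance-level convention (`α = 0.999`) is ambiguous in
the literature this mirrors, so nothing is asserted against it.

The `ratio_ci_taylor` helper provides the second-order-Taylor
(delta-method, zero covariance) confidence interval for a ratio of two
independent sample means; its ~95% nominal coverage is checked by
simulation.

## Problem sizes used by the test suite

Routine tests run at index scales up to `n = 10⁶` and Monte-Carlo sizes
of 2×10⁴–10⁵ replicates; the large-scale uniformity checks run the
vectorized harness at `k = 2×10⁷`, `n = 10⁸` (about 8 s per run on one
core). The vectorization is exact: the blocked phase-1 and per-window
draws consume the same PCG64 uniform stream, in the same order, as the
scalar streaming samplers, and bitwise equality of the two paths is
itself a test. The full 12-combination grid with `n` up to 5×10⁸ that
the grand-mean accuracy figure summarizes is reproducible with
`uniformity_experiment` but takes hours; the suite instead checks the
equivalent desk-scale property (two-sample KS indistinguishability of
s-leaping and Algorithm R max-D distributions at `k = 10⁵`, `n = 10⁶`,
50 runs each).

## Synthetic data

`synthetic.generate_fastq` writes deterministic 4-line FASTQ with the
read ordinal embedded in each header, i.i.d. uniform A/C/G/T sequences
and constant quality. It emulates nothing about real base-call error or
quality profiles — deliberately: samplers must be content-blind, and
constant quality makes accidental content dependence easy to catch
(a test shuffles sequence content and asserts identical selections).
Passing FASTQ tests therefore demonstrate correct *selection* behavior,
not robustness to real-world FASTQ quirks beyond the strict 4-line
dialect.

## Design choices

* **Strict 4-line FASTQ only**; multi-line records are rejected with an
  error naming the record ordinal. Gzip is detected by magic bytes.
* **Output order**: selected records are written in original file order
  (deterministic, friendliest to downstream tools).
* **Paired-end**: the sampling unit is the read pair; one reservoir
  decision covers both mates, read in lockstep, which is the only
  unbiased single-pass-compatible contract. Divergent mate files are an
  error at the point of divergence.
* **k > n** keeps all reads and warns rather than failing.
* **Seeds**: the CLI defaults to a fixed seed (42) so pipelines are
  reproducible unless the user opts into varying it.
* **EOF mid-skip** returns the current reservoir unchanged; the draws
  already spent on the unfinished skip are counted.

## Known limitations

* s-leaping is approximate; although the bias bound is tiny, exactness-
  critical applications should use Algorithms R, L or Z (all provided).
* Single-threaded by design; no weighted or stratified sampling; no
  fraction-based subsampling mode; no SAM/BAM/CRAM input.
* The reservoir holds full records in memory: peak memory is O(k)
  records (or pairs) plus constant buffers.
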