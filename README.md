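# sleaping

Fast, single-pass downsampling of large read sets by reservoir sampling,
including **s-leaping** — an approximate sampler designed for streams of
hundreds of millions of reads — alongside the exact Algorithms R, L and
Z, the closed-form random-number-count theory that motivates the method,
and a FASTQ downsampling engine for single- and paired-end data.

## Who this is for

Sequencing-coverage titration (e.g. generating low-coverage WGS from
deep WGS to benchmark imputation, or choosing a cost-effective coverage)
routinely needs "give me exactly *k* random reads from this FASTQ of
unknown size, in one pass". Reservoir sampling does exactly that; this
package provides the standard exact algorithms and a faster approximate
one, with instrumented randomness so every draw-count claim is testable.

## The algorithms

Reservoir sampling keeps `k` items from a stream of unknown length `n`
so that every item ends with inclusion probability `k/n`:

* **Algorithm R** — per-element testing: element `i` replaces a random
  slot with probability `k/i`; exactly `n − k` random numbers.
* **Algorithm L** (Li 1994) and **Algorithm Z** (Vitter 1985) — exact
  *next selection* methods that jump straight to the next replaced
  element; about `(t+1)·k ln(n/k)` random numbers with `t = 3`- and
  `t ≈ 2`-per-selection step sampling respectively.
* **s-leaping** — exact Algorithm R over the first `2k` elements, then
  windows of `s = ε·k` elements in which the selection probability is
  frozen at `p = k/(i+1+0.5s)`, so step sizes become cheap Geometric(p)
  draws: `ν = ⌊ln(u)/ln(1−p)⌋ + 1`. Total cost `k + 2k ln(n/(2k))`
  random numbers — about `0.39k` fewer than the best exact
  next-selection method and below Algorithm R whenever `k < 0.5n`.
  The price is a bounded bias in selection probability of at most
  `0.5ε/(2+0.5ε)` (0.00125 at the default `ε = 0.005`).

See `docs/methods.md` for derivations, numerical conventions and the
validation methodology (binned maximum-D uniformity statistics).

## Worked example

Downsample a FASTQ file (plain or gzipped, detected by content) to
exactly 10 000 reads:

```sh
$ sleaping downsample -i reads.fastq -o subset.fastq -k 10000 --seed 7
downsampled 100000 -> 10000 reads (k=10000, method=sleaping, epsilon=0.005, seed=7, 0.18s)
```

The summary line (on stderr) reports reads in and out, the sampler, the
leap factor and the seed; `subset.fastq` holds exactly 10 000 reads in
their original order, each kept with probability 0.1. Paired-end mode
(`-I`/`-O`) samples read *pairs* with one decision, preserving mate
pairing. `--method algR|algL|algZ` selects an exact sampler instead.

Measure sampler accuracy and cost without any file, on an index stream:

```sh
$ sleaping simulate --n 1000000 --k 100000 --method sleaping --epsilon 0.1 \
    --reps 3 --seed 1 --emit maxd --emit draws
method,k,n,epsilon,seed,d_max,draws
sleaping,100000,1000000,0.1,1,2.140000e-03,422194
sleaping,100000,1000000,0.1,2,3.770000e-03,422054
sleaping,100000,1000000,0.1,3,1.890000e-03,422122
```

Each row is one seeded run. `d_max` is the 1000-bin maximum discrepancy
of the selected indices against the uniform distribution (~2×10⁻³ is
what an *exact* sampler gives at `k = 10⁵`, so s-leaping at a leap
factor as coarse as 0.1 is indistinguishable from exact here), and
`draws` counts random numbers: ≈ 422 000 against the 900 000 Algorithm R
would need (`n − k`), matching the closed form
`k + 2k ln(n/2k) ≈ 421 888` plus the small once-per-window overhead.

Closed-form quantities:

```sh
$ sleaping theory --curve bound --epsilon 0.005
0.0012484
$ sleaping theory --curve crossover
0.3
```

From Python:

```pycon
>>> from sleaping import theory as th
>>> round(th.efficiency_ratio(0.3, "sleaping"), 4)   # draws relative to Algorithm R
0.8664
>>> th.efficiency_percent(0.3, "sleaping")           # i.e. 15% fewer random numbers
15
```

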