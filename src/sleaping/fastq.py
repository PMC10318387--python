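"""Strict 4-line FASTQ I/O and reservoir-based downsampling.

The downsampling engine streams records through the samplers in
:mod:`sleaping.samplers`, holding at most ``k`` records (or read pairs) in
memory.  Sampling decisions depend only on record ordinals — the sampler
never looks at sequence content — and the selected records are written in
their original file order.  For a given (seed, method, k, epsilon) the set
of selected ordinals is identical to what the index-only harness selects,
because both run the same sampler code over the same counted draw stream.

Only the plain 4-line FASTQ dialect is accepted (multi-line records are
rejected), matching what short-read downsampling tools expect.  Gzip input
is detected from the magic bytes, not the file extension.
"""

from __future__ import annotations

import gzip
import io
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .rng import CountingRandomSource
from .samplers import Method, SamplerConfig, make_sampler

__all__ = [
    "FastqRecord",
    "FastqParseError",
    "PairSyncError",
    "DownsampleReport",
    "read_fastq",
    "write_fastq",
    "downsample_single",
    "downsample_paired",
]

_GZIP_MAGIC = b"\x1f\x8b"


class FastqParseError(ValueError):
    """Malformed or truncated FASTQ input; message names the record ordinal."""


class PairSyncError(ValueError):
    """Paired inputs diverged: one file ended before the other."""


@dataclass
class FastqRecord:
    """One 4-line FASTQ entry, stored byte-preserving (no '@'/'+' stripping)."""

    header: str
    sequence: str
    separator: str
    quality: str

    def __post_init__(self):
        if not self.header.startswith("@") or len(self.header) < 2:
            raise FastqParseError(f"header must start with '@': {self.header!r}")
        if not self.separator.startswith("+"):
            raise FastqParseError(f"separator must start with '+': {self.separator!r}")
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"sequence/quality length mismatch ({len(self.sequence)} vs {len(self.quality)})"
            )

    def to_lines(self) -> str:
        return f"{self.header}\n{self.sequence}\n{self.separator}\n{self.quality}\n"


@dataclass
class DownsampleReport:
    """What a downsampling run consumed and produced."""

    n_in: int
    n_out: int
    k: int
    method: str
    seed: int
    epsilon: float
    paired: bool
    elapsed_s: float

    def summary(self) -> str:
        unit = "pairs" if self.paired else "reads"
        return (
            f"downsampled {self.n_in} -> {self.n_out} {unit} "
            f"(k={self.k}, method={self.method}, epsilon={self.epsilon}, seed={self.seed}, "
            f"{self.elapsed_s:.2f}s)"
        )


def _open_text_auto(path: Union[str, Path]) -> io.TextIOBase:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw, mode="rb"))
    return io.TextIOWrapper(raw)


def read_fastq(path: Union[str, Path]) -> Iterator[FastqRecord]:
    """Lazily yield strict 4-line FASTQ records from a plain or gzipped file.

    Raises :class:`FastqParseError` naming the 1-based record ordinal on a
    malformed or truncated record.
    """
    with _open_text_auto(path) as fh:
        ordinal = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            ordinal += 1
            seq = fh.readline()
            sep = fh.readline()
            qual = fh.readline()
            if qual == "":
                raise FastqParseError(f"record {ordinal}: truncated (fewer than 4 lines)")
            header, seq = header.rstrip("\r\n"), seq.rstrip("\r\n")
            sep, qual = sep.rstrip("\r\n"), qual.rstrip("\r\n")
            if not header.startswith("@"):
                raise FastqParseError(f"record {ordinal}: header does not start with '@'")
            if not sep.startswith("+"):
                raise FastqParseError(
                    f"record {ordinal}: separator line does not start with '+' "
                    "(multi-line FASTQ is not supported)"
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {ordinal}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            try:
                yield FastqRecord(header, seq, sep, qual)
            except FastqParseError as exc:
                raise FastqParseError(f"record {ordinal}: {exc}") from None


def write_fastq(
    records: Iterable[FastqRecord], path: Union[str, Path], gzip_out: bool = False
) -> int:
    """Write records as 4-line FASTQ (optionally gzipped); return the count."""
    opener = gzip.open if gzip_out else open
    count = 0
    with opener(path, "wt") as fh:
        for rec in records:
            fh.write(rec.to_lines())
            count += 1
    return count


def _numbered(records: Iterator[FastqRecord]):
    for ordinal, rec in enumerate(records):
        yield ordinal, rec


def downsample_single(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    k: int,
    method: Union[Method, str] = Method.SLEAPING,
    epsilon: float = 0.005,
    seed: int = 0,
    gzip_out: bool = False,
) -> DownsampleReport:
    """Stream a FASTQ file through a reservoir sampler; keep ``min(k, n)`` reads.

    At most ``k`` records are resident at any time.  Selected records are
    written sorted by original file position.  If the input holds fewer
    than ``k`` reads, all of them are written and a warning is emitted.
    """
    t0 = time.perf_counter()
    m = Method.parse(method) if isinstance(method, str) else method
    config = SamplerConfig(k=k, epsilon=epsilon, method=m, seed=seed)
    sampler = make_sampler(config)
    reservoir = sampler(_numbered(read_fastq(in_path)))
    if reservoir.n_seen < k:
        warnings.warn(
            f"input has only {reservoir.n_seen} reads, fewer than k={k}; keeping all",
            stacklevel=2,
        )
    selected = sorted(reservoir.slots, key=lambda pair: pair[0])
    n_out = write_fastq((rec for _, rec in selected), out_path, gzip_out=gzip_out)
    return DownsampleReport(
        n_in=reservoir.n_seen,
        n_out=n_out,
        k=k,
        method=m.value,
        seed=seed,
        epsilon=epsilon,
        paired=False,
        elapsed_s=time.perf_counter() - t0,
    )


def _paired_stream(path1, path2):
    """Yield (ordinal, rec1, rec2); fail at the first point of divergence."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    ordinal = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = "first" if r1 is None else "second"
            raise PairSyncError(
                f"paired inputs diverge: {short} file ended at pair {ordinal + 1}"
            )
        yield ordinal, r1, r2
        ordinal += 1


def downsample_paired(
    in1: Union[str, Path],
    in2: Union[str, Path],
    out1: Union[str, Path],
    out2: Union[str, Path],
    k: int,
    method: Union[Method, str] = Method.SLEAPING,
    epsilon: float = 0.005,
    seed: int = 0,
    gzip_out: bool = False,
) -> DownsampleReport:
    """Downsample mate files in lockstep; the sampling unit is the read pair.

    One reservoir decision covers both mates, so pairing is preserved and
    ``k`` counts pairs.  Both outputs are sorted by original position.
    Inputs with unequal record counts raise :class:`PairSyncError` at the
    point of divergence.
    """
    t0 = time.perf_counter()
    m = Method.parse(method) if isinstance(method, str) else method
    config = SamplerConfig(k=k, epsilon=epsilon, method=m, seed=seed)
    sampler = make_sampler(config)
    reservoir = sampler(_paired_stream(in1, in2))
    if reservoir.n_seen < k:
        warnings.warn(
            f"input has only {reservoir.n_seen} pairs, fewer than k={k}; keeping all",
            stacklevel=2,
        )
    selected = sorted(reservoir.slots, key=lambda trip: trip[0])
    n_out = write_fastq((r1 for _, r1, _ in selected), out1, gzip_out=gzip_out)
    write_fastq((r2 for _, _, r2 in selected), out2, gzip_out=gzip_out)
    return DownsampleReport(
        n_in=reservoir.n_seen,
        n_out=n_out,
        k=k,
        method=m.value,
        seed=seed,
        epsilon=epsilon,
        paired=True,
        elapsed_s=time.perf_counter() - t0,
    )
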