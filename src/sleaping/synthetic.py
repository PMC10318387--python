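"""Deterministic synthetic FASTQ generation for tests and experiments.

Stands in, at desk scale, for the hundreds-of-millions-of-reads WGS inputs
the samplers target.  Every generated header embeds the read's zero-based
ordinal as a parseable token (``@sr000000123``), so ordinals selected by a
FASTQ-level downsampling run can be recovered exactly and compared against
the index-only harness.  Quality strings are constant on purpose: samplers
must ignore record content, and uniform quality makes any accidental
content dependence stick out.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .fastq import read_fastq

__all__ = ["SyntheticSpec", "generate_fastq", "recover_selected_ordinals"]

_BASES = np.array(list("ACGT"))
_ORDINAL_RE = re.compile(r"^@sr(\d+)")
_QUAL_CHAR = "I"


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape of a synthetic read set.

    ``mate_suffix=True`` appends ``/1`` and ``/2`` to paired headers;
    ``False`` uses the bare-duplicate-header dialect.
    """

    n_reads: int
    read_len: int = 101
    seed: int = 0
    paired: bool = False
    gzip: bool = False
    mate_suffix: bool = True

    def __post_init__(self):
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")


def _open_out(path: Union[str, Path], gz: bool):
    return gzip.open(path, "wt") if gz else open(path, "w")


def generate_fastq(
    spec: SyntheticSpec,
    path: Union[str, Path],
    path2: Optional[Union[str, Path]] = None,
) -> int:
    """Write a deterministic synthetic FASTQ file (or mate pair of files).

    Returns the number of reads (pairs, when paired) written.  Sequences
    are i.i.d. uniform over {A, C, G, T} from a generator seeded with
    ``spec.seed``; identical specs produce byte-identical files.
    """
    if spec.paired and path2 is None:
        raise ValueError("paired generation needs a second output path")
    if not spec.paired and path2 is not None:
        raise ValueError("path2 given but spec is single-end")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    qual = _QUAL_CHAR * spec.read_len
    chunk = 10_000
    fh1 = _open_out(path, spec.gzip)
    fh2 = _open_out(path2, spec.gzip) if spec.paired else None
    try:
        for start in range(0, spec.n_reads, chunk):
            stop = min(start + chunk, spec.n_reads)
            count = stop - start
            draws = rng.integers(0, 4, size=(2 if spec.paired else 1, count, spec.read_len))
            seqs1 = ["".join(row) for row in _BASES[draws[0]]]
            seqs2 = ["".join(row) for row in _BASES[draws[1]]] if spec.paired else None
            for off in range(count):
                i = start + off
                if spec.paired:
                    tag1, tag2 = ("/1", "/2") if spec.mate_suffix else ("", "")
                    fh1.write(f"@sr{i:09d}{tag1}\n{seqs1[off]}\n+\n{qual}\n")
                    fh2.write(f"@sr{i:09d}{tag2}\n{seqs2[off]}\n+\n{qual}\n")
                else:
                    fh1.write(f"@sr{i:09d}\n{seqs1[off]}\n+\n{qual}\n")
    finally:
        fh1.close()
        if fh2 is not None:
            fh2.close()
    return spec.n_reads


def recover_selected_ordinals(fastq_path: Union[str, Path]) -> np.ndarray:
    """Parse the ordinal token out of every header; return sorted ordinals.

    The bridge that lets FASTQ-level downsampling runs reuse the
    index-level oracles: a file produced by :func:`generate_fastq` and then
    downsampled yields exactly the ordinals the sampler selected.
    """
    ordinals = []
    for rec in read_fastq(fastq_path):
        match = _ORDINAL_RE.match(rec.header)
        if match is None:
            raise ValueError(f"header lacks an ordinal token: {rec.header!r}")
        ordinals.append(int(match.group(1)))
    return np.sort(np.asarray(ordinals, dtype=np.int64))
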