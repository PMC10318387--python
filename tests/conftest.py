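import numpy as np
import pytest

from sleaping.synthetic import SyntheticSpec, generate_fastq


@pytest.fixture
def small_fastq(tmp_path):
    """A 200-read synthetic single-end FASTQ file with ordinal headers."""
    path = tmp_path / "reads.fastq"
    generate_fastq(SyntheticSpec(n_reads=200, read_len=40, seed=11), path)
    return path


@pytest.fixture
def paired_fastq(tmp_path):
    """A 150-pair synthetic paired-end FASTQ file pair."""
    p1 = tmp_path / "reads_R1.fastq"
    p2 = tmp_path / "reads_R2.fastq"
    generate_fastq(SyntheticSpec(n_reads=150, read_len=36, seed=7, paired=True), p1, p2)
    return p1, p2
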