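import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from uorfkit.simulate import rnaseh1_like_transcript
from uorfkit.transcript_model import GenomeSequence, TranscriptRecord


@pytest.fixture(scope="session")
def rnaseh1_like():
    """Synthetic stand-in with the RNASEH1 uORF architecture: one
    overlapping uORF encoding a 9-aa peptide."""
    record, manifest = rnaseh1_like_transcript()
    return record, manifest


@pytest.fixture
def plain_transcript():
    """Factory for a single-exon plus-strand transcript given (sequence,
    cds_start_tx) directly, bypassing genome plumbing."""

    def make(seq: str, cds_start: int, tid: str = "toy") -> TranscriptRecord:
        return TranscriptRecord(
            transcript_id=tid, chrom=tid, strand="+", exons=[(0, len(seq))],
            cds_start_genomic=cds_start, cds_end_genomic=len(seq),
            sequence=seq, cds_start_tx=cds_start,
        )

    return make


def random_exon_structure(rng: np.random.Generator, chrom_len: int = 400):
    """Random non-overlapping ascending exons inside a chromosome."""
    n_exons = int(rng.integers(1, 5))
    cuts = np.sort(rng.choice(np.arange(1, chrom_len), size=2 * n_exons, replace=False))
    exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons)]
    return [iv for iv in exons if iv[1] > iv[0]]


def random_transcript(rng: np.random.Generator, tid: str = "rt") -> TranscriptRecord:
    exons = random_exon_structure(rng)
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptRecord(transcript_id=tid, chrom="chrZ", strand=strand, exons=exons)


def random_genome(rng: np.random.Generator, chrom: str = "chrZ", length: int = 400):
    seq = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=length))
    return GenomeSequence({chrom: seq})
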