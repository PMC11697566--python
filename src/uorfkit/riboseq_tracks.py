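"""Coverage-track aggregation, transcript projection, and uORF translation
evidence.

Tracks come in three kinds mirroring ribosome-profiling resources:
``footprint`` (elongating ribosomes), ``initiation`` (initiating
ribosomes), and ``mrna`` (RNA-Seq abundance). Many per-dataset tracks of
one kind are aggregated per genomic coordinate (sum by default, which
amplifies signal in low-coverage regions; mean available for
depth-normalized inputs), projected strand-aware onto transcript
coordinates, and summarized into per-uORF evidence: footprint occupancy
over the uORF span and an initiation-peak ratio comparing the uORF start
codon (uATG) with the pORF start codon (pATG).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .transcript_model import TranscriptRecord
from .uorf_scanner import UorfCall

__all__ = [
    "CoverageTrack",
    "TranscriptCoverage",
    "TranslationEvidence",
    "aggregate_tracks",
    "project_track",
    "initiation_score",
    "uorf_occupancy",
    "translation_evidence",
    "evidence_to_tsv",
]

logger = logging.getLogger(__name__)

TRACK_KINDS = ("footprint", "initiation", "mrna")

DEFAULT_PEAK_WINDOW = 3  # nt either side of the start-codon A; footprint-offset slop
DEFAULT_PSEUDOCOUNT = 0.5  # epsilon for init_ratio; guards unexpressed pATGs


@dataclass
class CoverageTrack:
    """Sparse per-genomic-coordinate signal: chrom -> {position: value}.

    Absent positions are zero; values are non-negative.
    """

    kind: str
    data: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")

    def add(self, chrom: str, pos: int, value: float) -> None:
        if value < 0:
            raise ValueError("coverage values must be non-negative")
        if value:
            chrom_data = self.data.setdefault(chrom, {})
            chrom_data[pos] = chrom_data.get(pos, 0.0) + value

    def value_at(self, chrom: str, pos: int) -> float:
        return self.data.get(chrom, {}).get(pos, 0.0)

    def total(self) -> float:
        return sum(v for chrom_data in self.data.values() for v in chrom_data.values())

    # -- text I/O ------------------------------------------------------

    @classmethod
    def from_bedgraph(cls, source, kind: str) -> "CoverageTrack":
        """4-column bedGraph, 0-based half-open."""
        text = source.read() if hasattr(source, "read") else source
        if "\n" not in text:
            with open(text) as fh:
                text = fh.read()
        track = cls(kind)
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"bedGraph line {lineno}: expected 4 columns")
            chrom, start, end, value = fields
            for pos in range(int(start), int(end)):
                track.add(chrom, pos, float(value))
        return track

    def to_bedgraph(self) -> str:
        """Merge runs of equal adjacent values into intervals."""
        lines = []
        for chrom in sorted(self.data):
            positions = sorted(self.data[chrom])
            run_start = None
            run_val = None
            prev = None
            for pos in positions:
                val = self.data[chrom][pos]
                if run_start is not None and pos == prev + 1 and val == run_val:
                    prev = pos
                    continue
                if run_start is not None:
                    lines.append(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}")
                run_start, run_val, prev = pos, val, pos
            if run_start is not None:
                lines.append(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}")
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_wiggle(cls, source, kind: str) -> "CoverageTrack":
        """fixedStep / variableStep wiggle (1-based, per UCSC convention)."""
        text = source.read() if hasattr(source, "read") else source
        if "\n" not in text:
            with open(text) as fh:
                text = fh.read()
        track = cls(kind)
        mode = chrom = None
        pos = step = span = 1
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                params = dict(p.split("=") for p in line.split()[1:])
                mode = line.split()[0]
                chrom = params["chrom"]
                span = int(params.get("span", 1))
                if mode == "fixedStep":
                    pos = int(params["start"])
                    step = int(params.get("step", 1))
                continue
            if mode == "fixedStep":
                value = float(line)
                for k in range(span):
                    track.add(chrom, pos - 1 + k, value)
                pos += step
            elif mode == "variableStep":
                p, value = line.split()
                for k in range(span):
                    track.add(chrom, int(p) - 1 + k, float(value))
            else:
                raise ValueError("wiggle data before any fixedStep/variableStep header")
        return track

    @classmethod
    def from_bigwig(cls, path: str, kind: str) -> "CoverageTrack":
        """Optional bigwig reader, behind a capability check on pyBigWig."""
        try:
            import pyBigWig
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError("bigwig support requires the pyBigWig package") from exc
        track = cls(kind)
        bw = pyBigWig.open(path)
        try:
            for chrom, length in bw.chroms().items():
                for start, end, value in (bw.intervals(chrom) or []):
                    for pos in range(start, end):
                        track.add(chrom, pos, float(value))
        finally:
            bw.close()
        return track

    def to_bigwig(self, path: str, chrom_sizes: dict[str, int]) -> None:
        try:
            import pyBigWig
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError("bigwig support requires the pyBigWig package") from exc
        bw = pyBigWig.open(path, "w")
        header = sorted(chrom_sizes.items())
        bw.addHeader(header)
        for chrom, _size in header:
            if chrom not in self.data:
                continue
            positions = sorted(self.data[chrom])
            starts = positions
            ends = [p + 1 for p in positions]
            values = [float(self.data[chrom][p]) for p in positions]
            bw.addEntries([chrom] * len(starts), starts, ends=ends, values=values)
        bw.close()


@dataclass
class TranscriptCoverage:
    """Aggregate signal projected onto one transcript, 5'->3'."""

    transcript_id: str
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def aggregate_tracks(tracks: list[CoverageTrack], method: str = "sum") -> CoverageTrack:
    """Per-coordinate aggregate of same-kind tracks (sum by default)."""
    if not tracks:
        raise ValueError("need at least one track to aggregate")
    kinds = {t.kind for t in tracks}
    if len(kinds) != 1:
        raise ValueError(f"cannot aggregate mixed track kinds {sorted(kinds)}")
    if method not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    out = CoverageTrack(tracks[0].kind)
    for track in tracks:
        for chrom, chrom_data in track.data.items():
            dest = out.data.setdefault(chrom, {})
            for pos, value in chrom_data.items():
                dest[pos] = dest.get(pos, 0.0) + value
    if method == "mean":
        n = len(tracks)
        for chrom_data in out.data.values():
            for pos in chrom_data:
                chrom_data[pos] /= n
    return out


def project_track(agg: CoverageTrack, t: TranscriptRecord) -> TranscriptCoverage:
    """Project a genomic track onto transcript coordinates, strand-aware.

    Intronic signal contributes nothing; a transcript on a chromosome the
    track has never seen projects to all zeros (with a logged warning).
    """
    values = np.zeros(t.length, dtype=float)
    if t.chrom not in agg.data:
        logger.warning("chromosome %r absent from %s track; projecting zeros for %s",
                       t.chrom, agg.kind, t.transcript_id)
        warnings.warn(f"chromosome {t.chrom!r} absent from {agg.kind} track", stacklevel=2)
        return TranscriptCoverage(t.transcript_id, agg.kind, values)
    chrom_data = agg.data[t.chrom]
    offset = 0
    for start, end in t.exons:
        for g in range(start, end):
            v = chrom_data.get(g, 0.0)
            if v:
                plus = offset + (g - start)
                tpos = plus if t.strand == "+" else t.length - 1 - plus
                values[tpos] = v
        offset += end - start
    return TranscriptCoverage(t.transcript_id, agg.kind, values)


def initiation_score(cov: TranscriptCoverage, tpos: int, window: int = DEFAULT_PEAK_WINDOW) -> float:
    """Windowed initiation signal: sum over [tpos-w, tpos+w], truncated at
    transcript ends."""
    n = len(cov.values)
    if not (0 <= tpos < n):
        raise IndexError(f"tpos {tpos} outside [0, {n})")
    lo = max(0, tpos - window)
    hi = min(n, tpos + window + 1)
    return float(cov.values[lo:hi].sum())


def uorf_occupancy(cov: TranscriptCoverage, u: UorfCall) -> float:
    """Mean footprint signal over the uORF span (start through stop)."""
    end = u.stop_end_tx if u.stop_end_tx is not None else u.start_tx + 3 * u.peptide_len
    if not (0 <= u.start_tx < end <= len(cov.values)):
        raise IndexError(f"uORF span [{u.start_tx}, {end}) escapes transcript bounds")
    return float(cov.values[u.start_tx : end].mean())


@dataclass(frozen=True)
class TranslationEvidence:
    """Per-uORF Ribo-Seq evidence summary.

    ``init_ratio`` = (uatg_init + eps) / (patg_init + eps): >> 1 when the
    initiation signal concentrates at the uORF start rather than the pORF
    start — the signature of uORF-mediated translational repression.
    """

    transcript_id: str
    start_tx: int
    uorf_occupancy: float
    uatg_init: float
    patg_init: float
    init_ratio: float


def translation_evidence(
    t: TranscriptRecord,
    u: UorfCall,
    footprint: TranscriptCoverage,
    initiation: TranscriptCoverage,
    window: int = DEFAULT_PEAK_WINDOW,
    epsilon: float = DEFAULT_PSEUDOCOUNT,
) -> TranslationEvidence:
    if footprint.kind != "footprint" or initiation.kind != "initiation":
        raise ValueError("translation_evidence needs one footprint and one initiation track")
    if epsilon <= 0:
        raise ValueError("pseudocount must be positive")
    uatg = initiation_score(initiation, u.start_tx, window)
    patg = initiation_score(initiation, t.cds_start_tx, window)
    return TranslationEvidence(
        transcript_id=t.transcript_id,
        start_tx=u.start_tx,
        uorf_occupancy=uorf_occupancy(footprint, u),
        uatg_init=uatg,
        patg_init=patg,
        init_ratio=(uatg + epsilon) / (patg + epsilon),
    )


def evidence_to_tsv(rows: list[TranslationEvidence]) -> str:
    header = "transcript_id\tstart_tx\tuorf_occupancy\tuatg_init\tpatg_init\tinit_ratio\n"
    body = [
        f"{r.transcript_id}\t{r.start_tx}\t{r.uorf_occupancy:g}\t{r.uatg_init:g}\t"
        f"{r.patg_init:g}\t{r.init_ratio:g}"
        for r in rows
    ]
    return header + "\n".join(body) + ("\n" if body else "")
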