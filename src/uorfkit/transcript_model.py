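"""Spliced transcript models and genomic<->transcript coordinate arithmetic.

All internal coordinates are 0-based, half-open, regardless of the input
dialect (GTF/GFF3 are 1-based inclusive and are converted at the boundary).
Exons are stored in ascending genomic order for both strands; transcript
orientation is handled by the coordinate-mapping methods, so a minus-strand
transcript's ``sequence`` is the reverse complement of its concatenated
exon sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AnnotationError",
    "GenomeSequence",
    "TranscriptRecord",
    "read_annotation",
    "read_genome",
    "spliced_sequence",
    "transcripts_to_tsv",
    "transcripts_to_bed12",
    "normalize_chrom",
]

_VALID_ALPHABET = set("ACGTN")


class AnnotationError(ValueError):
    """Raised for malformed annotation or genome inputs."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix. Off by default everywhere; chromosome
    matching is exact string comparison unless the caller opts in."""
    return name[3:] if name.startswith("chr") and len(name) > 3 else name


@dataclass
class GenomeSequence:
    """Chromosome name -> uppercased nucleotide string (alphabet ACGTN)."""

    chroms: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_fasta(cls, source) -> "GenomeSequence":
        """Read a (multi-record, wrapped or unwrapped) FASTA file or handle."""
        handle = io.StringIO(source) if isinstance(source, str) and "\n" in source else source
        chroms: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in chroms:
                raise AnnotationError(f"duplicate chromosome name {rec.id!r}")
            seq = str(rec.seq).upper()
            bad = set(seq) - _VALID_ALPHABET
            if bad:
                raise AnnotationError(f"non-ACGTN characters in {rec.id!r}: {sorted(bad)}")
            chroms[rec.id] = seq
        return cls(chroms)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.chroms:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        seq = self.chroms[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise AnnotationError(
                f"interval [{start}, {end}) outside {chrom!r} bounds [0, {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms


def read_genome(source) -> GenomeSequence:
    return GenomeSequence.from_fasta(source)


@dataclass
class TranscriptRecord:
    """One spliced transcript.

    ``exons`` are genomic intervals (0-based half-open), ascending and
    non-overlapping. ``cds_start_genomic``/``cds_end_genomic`` bound the
    annotated coding region (stop codon included) or are None for
    non-coding transcripts. ``sequence`` and ``cds_start_tx`` are unset
    until :func:`spliced_sequence` is applied.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_genomic: int | None = None
    cds_end_genomic: int | None = None
    sequence: str | None = None
    cds_start_tx: int | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: strand must be '+' or '-'")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at [{start}, {end})"
                )
            prev_end = end

    # -- basic geometry ------------------------------------------------

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_genomic is not None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a transcript coordinate to its genomic source position."""
        if not (0 <= tpos < self.length):
            raise IndexError(f"tpos {tpos} outside [0, {self.length})")
        # walk exons in plus orientation; minus strand reads from the 3' end
        offset = tpos if self.strand == "+" else self.length - 1 - tpos
        for start, end in self.exons:
            if offset < end - start:
                return start + offset
            offset -= end - start
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Inverse of :meth:`transcript_to_genomic`; None for intronic or
        out-of-transcript positions (the sentinel, not an error)."""
        offset = 0
        for start, end in self.exons:
            if start <= gpos < end:
                plus = offset + (gpos - start)
                return plus if self.strand == "+" else self.length - 1 - plus
            offset += end - start
        return None

    def cds_tx_interval(self) -> tuple[int, int]:
        """CDS as a transcript-space half-open interval (stop included)."""
        if not self.is_coding:
            raise AnnotationError(f"{self.transcript_id} is non-coding")
        a = self.genomic_to_transcript(self.cds_start_genomic)
        b = self.genomic_to_transcript(self.cds_end_genomic - 1)
        if a is None or b is None:
            raise AnnotationError(f"{self.transcript_id}: CDS bounds fall outside exons")
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1


# -- annotation readers ------------------------------------------------


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def _sniff_dialect(lines: list[str]) -> str:
    for line in lines:
        if line.startswith("##gff-version"):
            return "gff3"
        if line.startswith("#") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 9:
            return "gff3" if "=" in fields[8] and '"' not in fields[8] else "gtf"
        if len(fields) >= 10:
            return "refflat"
    raise AnnotationError("could not determine annotation dialect from input")


def _extend_3prime(exons: list[tuple[int, int]], strand: str, lo: int, hi: int, n: int = 3):
    """Extend a genomic CDS interval by n exonic bases in the transcript
    3' direction (walking across junctions), for annotations whose CDS
    excludes the stop codon."""
    starts = [s for s, _ in exons]
    ends = [e for _, e in exons]
    if strand == "+":
        pos = hi
        for _ in range(n):
            idx = next((i for i, (s, e) in enumerate(exons) if s < pos <= e), None)
            if idx is None:
                raise AnnotationError("CDS stop-codon extension escapes exons")
            if pos == ends[idx]:
                if idx + 1 >= len(exons):
                    raise AnnotationError("CDS stop-codon extension escapes transcript")
                pos = starts[idx + 1]
            pos += 1
        return lo, pos
    pos = lo
    for _ in range(n):
        idx = next((i for i, (s, e) in enumerate(exons) if s <= pos < e), None)
        if idx is None:
            raise AnnotationError("CDS stop-codon extension escapes exons")
        if pos == starts[idx]:
            if idx == 0:
                raise AnnotationError("CDS stop-codon extension escapes transcript")
            pos = ends[idx - 1]
        pos -= 1
    return pos, hi


def _records_from_features(
    feats: dict[str, dict], cds_includes_stop: bool
) -> list[TranscriptRecord]:
    records = []
    for tid in sorted(feats):
        info = feats[tid]
        exons = sorted(info["exons"])
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationError(f"transcript {tid}: overlapping exons [{s1},{e1}) [{s2},{e2})")
        cds_lo = cds_hi = None
        if info["cds"]:
            cds_lo = min(s for s, _ in info["cds"])
            cds_hi = max(e for _, e in info["cds"])
            for s, e in info["cds"]:
                if not any(xs <= s and e <= xe for xs, xe in exons):
                    raise AnnotationError(f"transcript {tid}: CDS [{s},{e}) outside exons")
            if not cds_includes_stop:
                cds_lo, cds_hi = _extend_3prime(exons, info["strand"], cds_lo, cds_hi)
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exons,
                cds_start_genomic=cds_lo,
                cds_end_genomic=cds_hi,
                gene_id=info.get("gene_id"),
            )
        )
    return records


def _read_gtf_like(lines: list[str], dialect: str, cds_includes_stop: bool):
    parse_attrs = _parse_gtf_attributes if dialect == "gtf" else _parse_gff3_attributes
    id_keys = ("transcript_id",) if dialect == "gtf" else ("Parent", "transcript_id", "ID")
    feats: dict[str, dict] = {}
    for lineno, line in enumerate(lines, 1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise AnnotationError(f"line {lineno}: expected 9 tab-separated fields")
        chrom, _source, ftype, start, end, _score, strand, _frame, attr_text = fields
        if ftype.lower() not in ("exon", "cds"):
            continue
        attrs = parse_attrs(attr_text)
        tid = next((attrs[k] for k in id_keys if k in attrs), None)
        if tid is None:
            raise AnnotationError(f"line {lineno}: missing transcript_id attribute")
        iv = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
        entry = feats.setdefault(
            tid,
            {"chrom": chrom, "strand": strand, "exons": [], "cds": [],
             "gene_id": attrs.get("gene_id")},
        )
        if entry["chrom"] != chrom or entry["strand"] != strand:
            raise AnnotationError(f"line {lineno}: transcript {tid} changes chrom/strand")
        entry["exons" if ftype.lower() == "exon" else "cds"].append(iv)
    return _records_from_features(feats, cds_includes_stop)


def _read_refflat(lines: list[str], cds_includes_stop: bool):
    """10-column refFlat-like TSV: geneName, name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (starts/ends
    comma-separated, 0-based half-open, UCSC convention)."""
    feats: dict[str, dict] = {}
    for lineno, line in enumerate(lines, 1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise AnnotationError(f"line {lineno}: refFlat rows need 11 columns")
        gene, tid, chrom, strand, _tx_s, _tx_e, cds_s, cds_e, n_exons, starts, ends = fields[:11]
        exon_starts = [int(x) for x in starts.rstrip(",").split(",")]
        exon_ends = [int(x) for x in ends.rstrip(",").split(",")]
        if len(exon_starts) != int(n_exons) or len(exon_ends) != int(n_exons):
            raise AnnotationError(f"line {lineno}: exonCount disagrees with block lists")
        cds_s, cds_e = int(cds_s), int(cds_e)
        feats[tid] = {
            "chrom": chrom,
            "strand": strand,
            "exons": list(zip(exon_starts, exon_ends)),
            "cds": [] if cds_s >= cds_e else [(cds_s, cds_e)],
            "gene_id": gene,
        }
        # refFlat CDS bounds may span introns; clip to exons for validation
        if feats[tid]["cds"]:
            lo, hi = feats[tid]["cds"][0]
            pieces = [
                (max(lo, s), min(hi, e))
                for s, e in feats[tid]["exons"]
                if max(lo, s) < min(hi, e)
            ]
            if not pieces:
                raise AnnotationError(f"line {lineno}: CDS outside exons")
            feats[tid]["cds"] = pieces
    return _records_from_features(feats, cds_includes_stop)


def read_annotation(source, dialect: str | None = None, cds_includes_stop: bool = True):
    """Parse GTF 2.2, GFF3, or a refFlat-like TSV into TranscriptRecords.

    ``cds_includes_stop``: when False the annotated CDS excludes the stop
    codon and bounds are extended by 3 nt in the 3' direction, so that CDS
    bounds always include the stop codon internally.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    lines = text.splitlines()
    dialect = dialect or _sniff_dialect(lines)
    if dialect in ("gtf", "gff3"):
        return _read_gtf_like(lines, dialect, cds_includes_stop)
    if dialect in ("refflat", "refFlat"):
        return _read_refflat(lines, cds_includes_stop)
    raise AnnotationError(f"unknown annotation dialect {dialect!r}")


# -- sequence ----------------------------------------------------------


def spliced_sequence(t: TranscriptRecord, genome: GenomeSequence) -> TranscriptRecord:
    """Return a copy of ``t`` with ``sequence`` and ``cds_start_tx`` set.

    Minus-strand transcripts get the reverse complement of the ascending
    exon concatenation; ``cds_start_tx`` indexes the first base of the
    pORF initiator codon in transcript orientation.
    """
    parts = [genome.fetch(t.chrom, s, e) for s, e in t.exons]
    seq = "".join(parts)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    out = replace(t, sequence=seq)
    if t.is_coding:
        if t.strand == "+":
            out.cds_start_tx = out.genomic_to_transcript(t.cds_start_genomic)
        else:
            out.cds_start_tx = out.genomic_to_transcript(t.cds_end_genomic - 1)
        if out.cds_start_tx is None:
            raise AnnotationError(f"{t.transcript_id}: CDS start not exonic")
    return out


# -- writers -----------------------------------------------------------


def transcripts_to_tsv(records: list[TranscriptRecord]) -> str:
    header = "transcript_id\tchrom\tstrand\tn_exons\tlength\tcds_start_tx\tcoding\n"
    rows = [
        f"{t.transcript_id}\t{t.chrom}\t{t.strand}\t{len(t.exons)}\t{t.length}\t"
        f"{t.cds_start_tx if t.cds_start_tx is not None else '.'}\t{int(t.is_coding)}"
        for t in records
    ]
    return header + "\n".join(rows) + "\n"


def transcripts_to_bed12(records: list[TranscriptRecord]) -> str:
    lines = []
    for t in records:
        tx_start = t.exons[0][0]
        tx_end = t.exons[-1][1]
        thick_s = t.cds_start_genomic if t.is_coding else tx_start
        thick_e = t.cds_end_genomic if t.is_coding else tx_start
        sizes = ",".join(str(e - s) for s, e in t.exons) + ","
        starts = ",".join(str(s - tx_start) for s, _ in t.exons) + ","
        lines.append(
            "\t".join(
                map(
                    str,
                    [t.chrom, tx_start, tx_end, t.transcript_id, 0, t.strand,
                     thick_s, thick_e, 0, len(t.exons), sizes, starts],
                )
            )
        )
    return "\n".join(lines) + "\n"
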