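"""Detection and classification of upstream open reading frames (uORFs).

A uORF is a start codon in a transcript's 5' UTR followed by an in-frame
stop codon. Each start position upstream of the primary ORF (pORF) start
is walked codon by codon to its first in-frame stop and classified:

* ``upstream`` — the stop codon ends at or before the pORF start.
* ``overlapping`` — the stop lies downstream of the pORF start (this
  forces a shifted reading frame relative to the pORF).
* ``n_terminal_extension`` — an in-frame upstream start with no stop
  before the pORF start; it is not a uORF (it extends the pORF's own
  protein) and is excluded from default output.
* ``no_stop`` — an out-of-frame start with no stop anywhere downstream;
  surfaced rather than silently dropped, with the stop coordinate absent.

The in-silico start-codon ablation (ATG -> TTG) mirrors the mutant
construct used to disrupt a uORF experimentally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .transcript_model import TranscriptRecord

__all__ = [
    "UorfCall",
    "ScanOptions",
    "scan_uorfs",
    "translate_orf",
    "ablate_start",
    "uorfs_to_tsv",
    "uorfs_to_bed",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NEAR_COGNATE_STARTS = frozenset({"CTG", "GTG", "TTG", "ACG"})

CATEGORIES = ("upstream", "overlapping", "n_terminal_extension", "no_stop")


@dataclass(frozen=True)
class UorfCall:
    """One detected uORF, in transcript coordinates (0-based half-open)."""

    transcript_id: str
    start_tx: int
    stop_end_tx: int | None  # one past the stop codon; None for no_stop
    category: str
    frame_vs_porf: int  # (start_tx - cds_start_tx) mod 3
    peptide: str
    peptide_len: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.stop_end_tx is not None and (self.stop_end_tx - self.start_tx) % 3:
            raise ValueError("uORF span must be a whole number of codons")


@dataclass
class ScanOptions:
    start_codons: frozenset[str] = frozenset({"ATG"})
    min_peptide_len: int = 0
    report_near_cognate: bool = False
    collapse_same_stop: bool = False
    include_extensions: bool = False

    def effective_starts(self) -> frozenset[str]:
        starts = set(self.start_codons)
        if self.report_near_cognate:
            starts |= NEAR_COGNATE_STARTS
        for codon in starts:
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise ValueError(f"invalid start codon {codon!r}")
        return frozenset(starts)


def translate_orf(nt: str) -> str:
    """Translate an ORF with the standard genetic code, stopping at (and
    excluding) the first stop codon."""
    if len(nt) % 3:
        raise ValueError(f"ORF length {len(nt)} is not divisible by 3")
    nt = nt.upper()
    if "N" in nt:
        raise ValueError("ambiguous base N inside ORF")
    return str(Seq(nt).translate(to_stop=True))


def scan_uorfs(t: TranscriptRecord, opts: ScanOptions | None = None) -> list[UorfCall]:
    """Scan the 5' UTR of a coding transcript for uORFs.

    Every UTR position whose codon is in ``opts.start_codons`` yields at
    most one call; calls are ordered by start position. N-terminal
    extensions are returned only when ``opts.include_extensions``.
    """
    opts = opts or ScanOptions()
    if t.sequence is None:
        raise ValueError(f"{t.transcript_id}: sequence unset; apply spliced_sequence first")
    if not t.is_coding or t.cds_start_tx is None:
        raise ValueError(f"{t.transcript_id}: uORF scanning requires a coding transcript")
    seq = t.sequence
    cds_start = t.cds_start_tx
    starts = opts.effective_starts()

    calls: list[UorfCall] = []
    for p in range(cds_start):
        if seq[p : p + 3] not in starts:
            continue
        call = _walk_orf(t.transcript_id, seq, p, cds_start)
        if call is None:
            continue
        if call.peptide_len < opts.min_peptide_len:
            continue
        if call.category == "n_terminal_extension" and not opts.include_extensions:
            continue
        calls.append(call)

    if opts.collapse_same_stop:
        seen: dict[int | None, UorfCall] = {}
        for call in calls:  # already ordered 5'->3'; keep the 5'-most per stop
            seen.setdefault(call.stop_end_tx, call)
        calls = list(seen.values())
    return calls


def _walk_orf(tid: str, seq: str, start: int, cds_start: int) -> UorfCall | None:
    frame = (start - cds_start) % 3
    stop_end = None
    for q in range(start, len(seq) - 2, 3):
        if frame == 0 and q >= cds_start:
            # in-frame start reading cleanly into the pORF: not a uORF
            return UorfCall(tid, start, None, "n_terminal_extension", 0,
                            translate_orf(seq[start:cds_start]),
                            (cds_start - start) // 3)
        if q > start and seq[q : q + 3] in STOP_CODONS:
            stop_end = q + 3
            break
    if stop_end is None:
        tail = seq[start : start + 3 * ((len(seq) - start) // 3)]
        return UorfCall(tid, start, None, "no_stop", frame,
                        translate_orf(tail), len(tail) // 3)
    category = "upstream" if stop_end <= cds_start else "overlapping"
    peptide = translate_orf(seq[start:stop_end])
    return UorfCall(tid, start, stop_end, category, frame, peptide, len(peptide))


def ablate_start(t: TranscriptRecord, u: UorfCall) -> TranscriptRecord:
    """Mutate a uORF's ATG start codon to TTG (A->T at the first base),
    returning a mutated copy of the transcript. Rescanning the mutant
    yields no call at ``u.start_tx``."""
    if t.sequence is None:
        raise ValueError("sequence unset")
    codon = t.sequence[u.start_tx : u.start_tx + 3]
    if codon != "ATG":
        raise ValueError(
            f"cannot ablate {t.transcript_id}:{u.start_tx}: codon is {codon!r}, not 'ATG'"
        )
    seq = t.sequence[: u.start_tx] + "T" + t.sequence[u.start_tx + 1 :]
    return replace(t, sequence=seq)


# -- writers -----------------------------------------------------------


def uorfs_to_tsv(calls: list[UorfCall]) -> str:
    header = ("transcript_id\tstart_tx\tstop_end_tx\tcategory\tframe_vs_porf\t"
              "peptide_len\tpeptide\n")
    rows = [
        f"{c.transcript_id}\t{c.start_tx}\t{c.stop_end_tx if c.stop_end_tx is not None else '.'}"
        f"\t{c.category}\t{c.frame_vs_porf}\t{c.peptide_len}\t{c.peptide}"
        for c in calls
    ]
    return header + "\n".join(rows) + ("\n" if rows else "")


def uorfs_to_bed(calls: list[UorfCall], t: TranscriptRecord | None = None) -> str:
    """BED for uORF calls. Without a transcript: transcript-space BED4.
    With one: genome-space BED12 whose blocks split spans across exons."""
    lines = []
    for i, c in enumerate(calls):
        end = c.stop_end_tx if c.stop_end_tx is not None else c.start_tx + 3 * c.peptide_len
        name = f"{c.transcript_id}.uorf{i + 1}.{c.category}"
        if t is None:
            lines.append(f"{c.transcript_id}\t{c.start_tx}\t{end}\t{name}")
            continue
        gpos = sorted(t.transcript_to_genomic(p) for p in range(c.start_tx, end))
        blocks: list[tuple[int, int]] = []
        for g in gpos:
            if blocks and g == blocks[-1][1]:
                blocks[-1] = (blocks[-1][0], g + 1)
            else:
                blocks.append((g, g + 1))
        chrom_start, chrom_end = blocks[0][0], blocks[-1][1]
        sizes = ",".join(str(e - s) for s, e in blocks) + ","
        offsets = ",".join(str(s - chrom_start) for s, _ in blocks) + ","
        lines.append(
            "\t".join(map(str, [t.chrom, chrom_start, chrom_end, name, 0, t.strand,
                                chrom_start, chrom_end, 0, len(blocks), sizes, offsets]))
        )
    return "\n".join(lines) + ("\n" if lines else "")
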