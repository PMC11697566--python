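"""Fetch a RefSeq transcript record by accession (network required).

Builds a single-exon :class:`TranscriptRecord` in transcript coordinates
(the transcript is its own "chromosome"), which is exactly what uORF
scanning and ASO design need; genome-anchored work should go through a
genome FASTA + annotation instead.
"""

from __future__ import annotations

import io

from Bio import Entrez, SeqIO

from .transcript_model import GenomeSequence, TranscriptRecord, spliced_sequence

__all__ = ["fetch_refseq", "transcript_from_genbank"]

Entrez.email = "uorfkit@example.org"  # NCBI requires a contact address


def transcript_from_genbank(handle_or_text) -> TranscriptRecord:
    """Build a TranscriptRecord from a GenBank-format mRNA record (its CDS
    feature supplies the pORF bounds; stop codon included)."""
    if isinstance(handle_or_text, str):
        handle_or_text = io.StringIO(handle_or_text)
    rec = SeqIO.read(handle_or_text, "genbank")
    cds_feats = [f for f in rec.features if f.type == "CDS"]
    if not cds_feats:
        raise ValueError(f"{rec.id}: no CDS feature in GenBank record")
    cds = cds_feats[0]
    t = TranscriptRecord(
        transcript_id=rec.id,
        chrom=rec.id,
        strand="+",
        exons=[(0, len(rec.seq))],
        cds_start_genomic=int(cds.location.start),
        cds_end_genomic=int(cds.location.end),
    )
    genome = GenomeSequence({rec.id: str(rec.seq).upper()})
    return spliced_sequence(t, genome)


def fetch_refseq(accession: str) -> TranscriptRecord:
    """Download one RefSeq mRNA record (e.g. ``NM_002936.5``) via NCBI
    efetch and return it as a scan-ready TranscriptRecord."""
    with Entrez.efetch(db="nuccore", id=accession, rettype="gb", retmode="text") as handle:
        return transcript_from_genbank(handle.read())
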