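"""Deterministic synthetic data: toy genomes/annotations with planted
uORFs, coverage tracks with planted initiation peaks, and qPCR/luciferase/
western tables with planted fold effects.

Construction guarantees, by design rather than by luck:

* every planted uORF is recoverable by the scanner with exactly the
  planted category and peptide length;
* background 5' UTR sequence contains no accidental ATG trigram (the
  sampler excludes G whenever the two preceding bases read "AT");
* identical spec + seed gives byte-identical output files.

The single fixture seed expands to per-component child seeds through a
fixed counter scheme (genome/annotation = 0, coverage = 1, quantification
tables = 2), so adding a new output never perturbs existing ones.

Coverage noise is Poisson; quantification noise is lognormal
multiplicative — the simplest models matching non-negative signal. The
planted-effect defaults mirror the study conditions this toolkit was
built around: a >5-fold luciferase de-repression when the uORF start is
ablated (planted at 5.5), no transcript-level change, and a null ASO
effect; replicates default to 4 independent measurements at 10%
coefficient of variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .riboseq_tracks import CoverageTrack
from .transcript_model import GenomeSequence, TranscriptRecord, spliced_sequence
from .uorf_scanner import STOP_CODONS, ScanOptions, scan_uorfs

__all__ = [
    "FixtureError",
    "UorfPlan",
    "TranscriptPlan",
    "CoveragePlan",
    "QuantPlan",
    "FixtureSpec",
    "make_genome_and_annotation",
    "make_coverage",
    "make_quant_tables",
    "write_fixture",
    "rnaseh1_like_transcript",
]

# child-seed counter scheme (documented contract; never reorder)
_SEED_GENOME, _SEED_COVERAGE, _SEED_QUANT = 0, 1, 2

# uORF interior codons: G-free (so no ATG can form at any offset) and
# stop-free (TAA is the only G-free stop)
_SAFE_CODONS = ["".join(c) for c in product("ACT", repeat=3) if "".join(c) != "TAA"]
_NONSTOP_CODONS = ["".join(c) for c in product("ACGT", repeat=3)
                   if "".join(c) not in STOP_CODONS]


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass(frozen=True)
class UorfPlan:
    category: str = "upstream"
    peptide_len: int = 3

    def __post_init__(self) -> None:
        if self.category not in ("upstream", "overlapping", "n_terminal_extension", "no_stop"):
            raise FixtureError(f"unknown uORF category {self.category!r}")
        if self.peptide_len < 1:
            raise FixtureError("peptide_len must be >= 1")


@dataclass(frozen=True)
class TranscriptPlan:
    utr5_len: int = 90
    cds_len: int = 120  # nt, start and stop codons included
    utr3_len: int = 45
    uorfs: tuple[UorfPlan, ...] = (UorfPlan(),)
    strand: str = "+"
    n_exons: int = 1
    has_init_peak: bool = True  # plant an initiation spike at each uATG

    def __post_init__(self) -> None:
        if self.cds_len < 6 or self.cds_len % 3:
            raise FixtureError("cds_len must be a multiple of 3 and >= 6")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise FixtureError("UTR lengths must be non-negative")
        if self.n_exons < 1:
            raise FixtureError("n_exons must be >= 1")


@dataclass(frozen=True)
class CoveragePlan:
    background_rate: float = 0.2   # Poisson lambda per exonic nt
    uatg_peak: float = 30.0        # initiation spike at each planted uORF start
    patg_peak: float = 2.0         # initiation signal at the pORF start
    uorf_footprint: float = 8.0    # extra footprint density over uORF spans
    footprint_background: float = 0.5
    mrna_rate: float = 5.0


@dataclass(frozen=True)
class QuantPlan:
    replicates: int = 4
    experiments: int = 1
    cv: float = 0.10               # lognormal coefficient of variation
    dlr_folds: tuple[tuple[str, float], ...] = (("WT", 1.0), ("TTG", 5.5))
    qpcr_folds: tuple[tuple[str, float], ...] = (("WT", 1.0), ("TTG", 1.0))
    western_folds: tuple[tuple[str, float], ...] = (("untreated", 1.0), ("ASO", 1.0))
    e_target: float = 1.95
    e_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise FixtureError("noise CV must be non-negative")
        for table in (self.dlr_folds, self.qpcr_folds, self.western_folds):
            if any(f <= 0 for _, f in table):
                raise FixtureError("planted folds must be positive")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    transcripts: tuple[TranscriptPlan, ...] = (TranscriptPlan(),)
    coverage: CoveragePlan = CoveragePlan()
    quant: QuantPlan = QuantPlan()


# -- sequence assembly -------------------------------------------------


def _plant(arr: list, pos: int, text: str) -> None:
    for k, ch in enumerate(text):
        if arr[pos + k] is not None and arr[pos + k] != ch:
            raise FixtureError(f"planting conflict at transcript position {pos + k}")
        arr[pos + k] = ch


def _fill_codon(arr: list, pos: int, rng, candidates: list[str]) -> None:
    fixed = arr[pos : pos + 3]
    ok = [c for c in candidates
          if all(f is None or f == ch for f, ch in zip(fixed, c))]
    if not ok:
        # fully constrained by overlapping plants; leave fixed chars be
        for k in range(3):
            if arr[pos + k] is None:
                arr[pos + k] = "C"
        return
    _plant(arr, pos, ok[int(rng.integers(len(ok)))] if len(ok) > 1 else ok[0])


def _place_uorfs(plan: TranscriptPlan, rng) -> list[dict]:
    """Choose non-colliding start positions for the planted uORFs and
    return ground-truth call descriptions."""
    cds_start = plan.utr5_len
    length = plan.utr5_len + plan.cds_len + plan.utr3_len
    reserved: list[tuple[int, int]] = []
    planted = []

    def collides(lo: int, hi: int) -> bool:
        return any(lo < e and s < hi for s, e in reserved)

    # place junction-constrained categories first, free-roaming ones after
    priority = {"overlapping": 0, "n_terminal_extension": 1, "upstream": 2, "no_stop": 3}
    for u in sorted(plan.uorfs, key=lambda u: priority[u.category]):
        span = 3 * (u.peptide_len + 1)
        if u.category == "upstream":
            choices = [s for s in range(0, cds_start - span + 1) if not collides(s, s + span)]
            if not choices:
                raise FixtureError(f"5' UTR of {cds_start} nt cannot host an upstream "
                                   f"uORF of {span} nt")
            start = int(choices[int(rng.integers(len(choices)))])
            planted.append({"category": "upstream", "start_tx": start,
                            "stop_end_tx": start + span, "peptide_len": u.peptide_len})
            reserved.append((start, start + span))
        elif u.category == "overlapping":
            # d is the overlap depth: uORF ATG fully in the UTR (d >= 3) and
            # the uORF stop codon clear of the pORF ATG (d <= span - 6)
            dists = [d for d in range(3, span - 5) if d % 3
                     and cds_start - d >= 0
                     and cds_start - d + span <= cds_start + plan.cds_len - 3
                     and not collides(cds_start - d, cds_start - d + span)]
            if not dists:
                raise FixtureError("no room for an overlapping uORF with this geometry")
            d = int(dists[int(rng.integers(len(dists)))])
            start = cds_start - d
            planted.append({"category": "overlapping", "start_tx": start,
                            "stop_end_tx": start + span, "peptide_len": u.peptide_len})
            reserved.append((start, start + span))
        elif u.category == "n_terminal_extension":
            start = cds_start - 3 * u.peptide_len
            if start < 0 or collides(start, cds_start):
                raise FixtureError("no room for the requested N-terminal extension")
            planted.append({"category": "n_terminal_extension", "start_tx": start,
                            "stop_end_tx": None, "peptide_len": u.peptide_len})
            reserved.append((start, cds_start))
        else:  # no_stop
            frames = [s for s in range(0, cds_start - 2)
                      if (s - cds_start) % 3 and not collides(s, s + 3)]
            if not frames:
                raise FixtureError("no room for a no_stop uORF start")
            start = int(frames[int(rng.integers(len(frames)))])
            planted.append({"category": "no_stop", "start_tx": start,
                            "stop_end_tx": None,
                            "peptide_len": (length - start) // 3})
            reserved.append((start, start + 3))
    return planted


def _assemble_sequence(plan: TranscriptPlan, planted: list[dict], rng) -> str:
    cds_start = plan.utr5_len
    length = plan.utr5_len + plan.cds_len + plan.utr3_len
    arr: list = [None] * length

    _plant(arr, cds_start, "ATG")  # pORF initiator
    _plant(arr, cds_start + plan.cds_len - 3, "TAA")  # pORF stop

    for p in planted:
        start = p["start_tx"]
        _plant(arr, start, "ATG")
        if p["category"] in ("upstream", "overlapping"):
            span = 3 * (p["peptide_len"] + 1)
            for off in range(3, span - 3, 3):
                _fill_codon(arr, start + off, rng, _SAFE_CODONS)
            _plant(arr, start + span - 3, "TAA")
        elif p["category"] == "n_terminal_extension":
            for off in range(3, cds_start - start, 3):
                _fill_codon(arr, start + off, rng, _SAFE_CODONS)

    # pORF interior codons: any non-stop codon compatible with plants
    for pos in range(cds_start + 3, cds_start + plan.cds_len - 3, 3):
        _fill_codon(arr, pos, rng, _NONSTOP_CODONS)

    # free fill; in the 5' UTR never complete an A-T-G trigram
    for i in range(length):
        if arr[i] is not None:
            continue
        alphabet = "ACGT"
        if i < cds_start and i >= 2 and arr[i - 2] == "A" and arr[i - 1] == "T":
            alphabet = "ACT"
        arr[i] = alphabet[int(rng.integers(len(alphabet)))]

    # no_stop plants: scrub stop codons from their reading frame by turning
    # one free (non-planted) base of the offending codon into C, which can
    # create neither a stop nor an ATG
    fixed = set()
    for p in planted:
        start = p["start_tx"]
        if p["category"] == "n_terminal_extension":
            fixed.update(range(start, cds_start))
        else:
            end = p["stop_end_tx"] if p["stop_end_tx"] is not None else start + 3
            fixed.update(range(start, end))
    fixed.update(range(cds_start, cds_start + 3))
    fixed.update(range(cds_start + plan.cds_len - 3, cds_start + plan.cds_len))
    for p in planted:
        if p["category"] != "no_stop":
            continue
        for pos in range(p["start_tx"] + 3, length - 2, 3):
            if "".join(arr[pos : pos + 3]) in STOP_CODONS:
                free = [pos + k for k in range(3) if pos + k not in fixed]
                if not free:
                    raise FixtureError(
                        "no_stop uORF frame collides with a planted stop codon"
                    )
                arr[free[0]] = "C"
    return "".join(arr)


def _embed_in_genome(seq: str, plan: TranscriptPlan, chrom: str, tid: str, rng):
    """Split a spliced sequence into exons with random introns/flanks and
    return (chrom_sequence, TranscriptRecord without sequence)."""
    length = len(seq)
    n_exons = min(plan.n_exons, max(1, length // 10))
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0, *map(int, cuts), length]
    tx_pieces = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
    if plan.strand == "-":
        comp = str.maketrans("ACGTN", "TGCAN")
        genomic_pieces = [p.translate(comp)[::-1] for p in reversed(tx_pieces)]
    else:
        genomic_pieces = tx_pieces

    def rand_seq(n: int) -> str:
        return "".join("ACGT"[int(k)] for k in rng.integers(0, 4, size=n))

    flank5 = rand_seq(int(rng.integers(30, 60)))
    parts = [flank5]
    exons = []
    pos = len(flank5)
    for k, piece in enumerate(genomic_pieces):
        exons.append((pos, pos + len(piece)))
        parts.append(piece)
        pos += len(piece)
        if k < len(genomic_pieces) - 1:
            intron = rand_seq(int(rng.integers(20, 50)))
            parts.append(intron)
            pos += len(intron)
    parts.append(rand_seq(int(rng.integers(30, 60))))
    chrom_seq = "".join(parts)

    record = TranscriptRecord(transcript_id=tid, chrom=chrom, strand=plan.strand,
                              exons=exons, gene_id=f"gene_{tid}")
    cds_a = plan.utr5_len
    cds_b = plan.utr5_len + plan.cds_len
    g = sorted([record.transcript_to_genomic(cds_a), record.transcript_to_genomic(cds_b - 1)])
    record.cds_start_genomic, record.cds_end_genomic = g[0], g[1] + 1
    return chrom_seq, record


def _wrap_fasta(name: str, seq: str, width: int = 60) -> str:
    body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
    return f">{name}\n{body}\n"


def _gtf_lines(record: TranscriptRecord) -> list[str]:
    attrs = f'gene_id "{record.gene_id}"; transcript_id "{record.transcript_id}";'
    lines = []
    for s, e in record.exons:
        lines.append("\t".join([record.chrom, "uorfkit_sim", "exon", str(s + 1), str(e),
                                ".", record.strand, ".", attrs]))
    if record.is_coding:
        for s, e in record.exons:
            lo = max(s, record.cds_start_genomic)
            hi = min(e, record.cds_end_genomic)
            if lo < hi:
                lines.append("\t".join([record.chrom, "uorfkit_sim", "CDS", str(lo + 1),
                                        str(hi), ".", record.strand, ".", attrs]))
    return lines


def make_genome_and_annotation(spec: FixtureSpec):
    """Build the planted genome.

    Returns (fasta_text, gtf_text, manifest) where manifest carries the
    ground-truth uORF calls per transcript. A validation scan is run on
    every transcript; a mismatch between planted and detectable uORFs is
    a bug in the spec geometry and raises FixtureError.
    """
    rng = np.random.default_rng([spec.seed, _SEED_GENOME])
    fasta_parts, gtf_lines, manifest_tx = [], ["##gtf built by uorfkit simulate"], []
    genome = GenomeSequence()
    records = []
    for i, plan in enumerate(spec.transcripts):
        tid = f"TX{i + 1:03d}"
        chrom = f"chr{i + 1}"
        planted = _place_uorfs(plan, rng)
        seq = _assemble_sequence(plan, planted, rng)
        chrom_seq, record = _embed_in_genome(seq, plan, chrom, tid, rng)
        genome.chroms[chrom] = chrom_seq
        record = spliced_sequence(record, genome)
        if record.sequence != seq:
            raise FixtureError("genome embedding failed to round-trip the spliced sequence")
        detected = scan_uorfs(record, ScanOptions(include_extensions=True))
        expect = sorted((p["start_tx"], p["category"], p["peptide_len"]) for p in planted)
        got = sorted((c.start_tx, c.category, c.peptide_len) for c in detected)
        if expect != got:
            raise FixtureError(f"{tid}: planted uORFs {expect} != detectable {got}")
        fasta_parts.append(_wrap_fasta(chrom, chrom_seq))
        gtf_lines.extend(_gtf_lines(record))
        records.append(record)
        manifest_tx.append({
            "transcript_id": tid, "chrom": chrom, "strand": plan.strand,
            "utr5_len": plan.utr5_len, "cds_len": plan.cds_len,
            "cds_start_tx": plan.utr5_len, "has_init_peak": plan.has_init_peak,
            "uorfs": planted,
        })
    manifest = {"seed": spec.seed, "transcripts": manifest_tx}
    return "".join(fasta_parts), "\n".join(gtf_lines) + "\n", manifest, genome, records


def make_coverage(spec: FixtureSpec, records: list[TranscriptRecord], manifest: dict):
    """Per-genomic-coordinate footprint/initiation/mRNA tracks with Poisson
    background and planted initiation spikes at each uATG."""
    rng = np.random.default_rng([spec.seed, _SEED_COVERAGE])
    cov = spec.coverage
    tracks = {kind: CoverageTrack(kind) for kind in ("footprint", "initiation", "mrna")}
    by_id = {t["transcript_id"]: t for t in manifest["transcripts"]}
    for record in records:
        info = by_id[record.transcript_id]
        exonic = [record.transcript_to_genomic(p) for p in range(record.length)]
        for kind, rate in (("footprint", cov.footprint_background),
                           ("initiation", cov.background_rate),
                           ("mrna", cov.mrna_rate)):
            if rate > 0:
                noise = rng.poisson(rate, size=len(exonic))
                for g, v in zip(exonic, noise):
                    if v:
                        tracks[kind].add(record.chrom, g, float(v))
        for u in info["uorfs"]:
            if info["has_init_peak"] and cov.uatg_peak > 0:
                g = record.transcript_to_genomic(u["start_tx"])
                tracks["initiation"].add(record.chrom, g, cov.uatg_peak)
            end = u["stop_end_tx"] if u["stop_end_tx"] is not None else u["start_tx"] + 3
            if cov.uorf_footprint > 0:
                for p in range(u["start_tx"], end):
                    tracks["footprint"].add(record.chrom,
                                            record.transcript_to_genomic(p),
                                            cov.uorf_footprint)
        if cov.patg_peak > 0:
            g = record.transcript_to_genomic(info["cds_start_tx"])
            tracks["initiation"].add(record.chrom, g, cov.patg_peak)
    return tracks


def _lognormal_factor(rng, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)  # mean 1


def make_quant_tables(spec: FixtureSpec):
    """CSV texts for the three quantification inputs, with planted folds.

    Returns (qpcr_csv, luciferase_csv, western_csv, truth) where truth
    records planted folds and assay efficiencies.
    """
    rng = np.random.default_rng([spec.seed, _SEED_QUANT])
    q = spec.quant

    qpcr = ["sample,group,experiment,target_cq,ref_cq"]
    base_target_cq, base_ref_cq = 24.0, 19.0
    for group, fold in q.qpcr_folds:
        for exp in range(1, q.experiments + 1):
            noise_t = _lognormal_factor(rng, q.cv, q.replicates)
            noise_r = _lognormal_factor(rng, q.cv, q.replicates)
            for r in range(q.replicates):
                tcq = base_target_cq - np.log(fold * noise_t[r]) / np.log(q.e_target)
                rcq = base_ref_cq - np.log(noise_r[r]) / np.log(q.e_ref)
                qpcr.append(f"{group}_e{exp}_r{r + 1},{group},{exp},{tcq:.4f},{rcq:.4f}")

    luc = ["group,experiment,rluc,fluc"]
    base_fluc, base_ratio = 2.0e6, 0.8
    for group, fold in q.dlr_folds:
        for exp in range(1, q.experiments + 1):
            f_noise = _lognormal_factor(rng, q.cv, q.replicates)
            r_noise = _lognormal_factor(rng, q.cv, q.replicates)
            for r in range(q.replicates):
                fluc = base_fluc * f_noise[r]
                rluc = base_ratio * fold * fluc * r_noise[r]
                luc.append(f"{group},{exp},{rluc:.2f},{fluc:.2f}")

    western = ["group,experiment,target_signal,loading_signal"]
    base_loading, base_target = 1.0e5, 4.0e4
    for group, fold in q.western_folds:
        for exp in range(1, q.experiments + 1):
            l_noise = _lognormal_factor(rng, q.cv, q.replicates)
            t_noise = _lognormal_factor(rng, q.cv, q.replicates)
            for r in range(q.replicates):
                loading = base_loading * l_noise[r]
                target = base_target / base_loading * loading * fold * t_noise[r]
                western.append(f"{group},{exp},{target:.2f},{loading:.2f}")

    truth = {
        "dlr_folds": dict(q.dlr_folds),
        "qpcr_folds": dict(q.qpcr_folds),
        "western_folds": dict(q.western_folds),
        "e_target": q.e_target,
        "e_ref": q.e_ref,
        "cv": q.cv,
        "replicates": q.replicates,
        "experiments": q.experiments,
    }
    return "\n".join(qpcr) + "\n", "\n".join(luc) + "\n", "\n".join(western) + "\n", truth


def write_fixture(spec: FixtureSpec, outdir) -> Path:
    """Write a self-contained fixture directory: FASTA, GTF, three
    bedGraphs, three quantification tables, and a ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, gtf, manifest, _genome, records = make_genome_and_annotation(spec)
    tracks = make_coverage(spec, records, manifest)
    qpcr, luc, western, truth = make_quant_tables(spec)
    (outdir / "genome.fa").write_text(fasta)
    (outdir / "annotation.gtf").write_text(gtf)
    for kind, track in tracks.items():
        (outdir / f"{kind}.bedGraph").write_text(track.to_bedgraph())
    (outdir / "qpcr_cq.csv").write_text(qpcr)
    (outdir / "luciferase.csv").write_text(luc)
    (outdir / "western.csv").write_text(western)
    manifest = {**manifest, "quant": truth}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def rnaseh1_like_transcript(seed: int = 20240101):
    """A synthetic stand-in for the RNASEH1 transcript architecture.

    This is generated sequence, not the real NM_002936.5 record (use
    :func:`uorfkit.remote.fetch_refseq` online for that): it reproduces
    the architecture of interest — a coding transcript whose 5' UTR holds
    exactly one uORF that overlaps the pORF and encodes a 9-amino-acid
    peptide. Returns (TranscriptRecord with sequence, manifest entry).
    """
    spec = FixtureSpec(
        seed=seed,
        transcripts=(TranscriptPlan(utr5_len=120, cds_len=150, utr3_len=60,
                                    uorfs=(UorfPlan("overlapping", 9),)),),
    )
    _fasta, _gtf, manifest, _genome, records = make_genome_and_annotation(spec)
    return records[0], manifest["transcripts"][0]
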