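"""Fixture generator: determinism, planted-vs-detected agreement, and
coverage/quant ground-truth recovery."""

import numpy as np
import pytest

from uorfkit.riboseq_tracks import CoverageTrack, aggregate_tracks, project_track, \
    translation_evidence
from uorfkit.simulate import (
    CoveragePlan,
    FixtureError,
    FixtureSpec,
    TranscriptPlan,
    UorfPlan,
    make_coverage,
    make_genome_and_annotation,
    make_quant_tables,
    write_fixture,
)
from uorfkit.transcript_model import read_annotation, read_genome, spliced_sequence
from uorfkit.uorf_scanner import ScanOptions, scan_uorfs


def test_fixture_is_byte_deterministic(tmp_path):
    spec = FixtureSpec(seed=9, transcripts=(TranscriptPlan(strand="-", n_exons=2),))
    d1 = write_fixture(spec, tmp_path / "a")
    d2 = write_fixture(spec, tmp_path / "b")
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_written_fixture_round_trips_through_the_readers(tmp_path):
    spec = FixtureSpec(seed=2, transcripts=(TranscriptPlan(n_exons=3, strand="-"),))
    outdir = write_fixture(spec, tmp_path / "fix")
    genome = read_genome(str(outdir / "genome.fa"))
    records = [spliced_sequence(t, genome) for t in read_annotation(str(outdir / "annotation.gtf"))]
    import json

    manifest = json.loads((outdir / "manifest.json").read_text())
    for record, info in zip(records, manifest["transcripts"]):
        calls = scan_uorfs(record, ScanOptions(include_extensions=True))
        assert [(c.start_tx, c.category, c.peptide_len) for c in calls] == [
            (u["start_tx"], u["category"], u["peptide_len"]) for u in info["uorfs"]
        ]


def test_zero_uorf_spec_has_clean_utr():
    spec = FixtureSpec(seed=4, transcripts=(TranscriptPlan(uorfs=()),))
    *_, records = make_genome_and_annotation(spec)
    assert scan_uorfs(records[0], ScanOptions(include_extensions=True)) == []
    assert "ATG" not in records[0].sequence[: records[0].cds_start_tx]


@pytest.mark.parametrize("category,peptide_len", [
    ("upstream", 4),
    ("overlapping", 9),
    ("n_terminal_extension", 5),
    ("no_stop", 2),
])
def test_each_planted_category_is_recovered(category, peptide_len):
    plan = TranscriptPlan(uorfs=(UorfPlan(category, peptide_len),))
    spec = FixtureSpec(seed=8, transcripts=(plan,))
    _fasta, _gtf, manifest, _genome, records = make_genome_and_annotation(spec)
    (call,) = scan_uorfs(records[0], ScanOptions(include_extensions=True))
    assert call.category == category
    if category != "no_stop":  # a no_stop call runs to the transcript end
        assert call.peptide_len == peptide_len
    assert manifest["transcripts"][0]["uorfs"][0]["category"] == category


def test_planted_vs_detected_across_100_seeds():
    """Generator/scanner cross-validation: planted uORFs are recovered
    exactly (position, category, peptide length) over 100 random specs."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        plans = []
        for k in range(2):
            uorfs = []
            if rng.random() < 0.8:
                uorfs.append(UorfPlan("upstream", int(rng.integers(1, 8))))
            if rng.random() < 0.5:
                uorfs.append(UorfPlan("overlapping", int(rng.integers(4, 12))))
            plans.append(
                TranscriptPlan(
                    utr5_len=int(rng.integers(60, 140)),
                    cds_len=3 * int(rng.integers(20, 50)),
                    uorfs=tuple(uorfs),
                    strand="+" if rng.random() < 0.5 else "-",
                    n_exons=int(rng.integers(1, 4)),
                )
            )
        spec = FixtureSpec(seed=seed, transcripts=tuple(plans))
        _, _, manifest, _, records = make_genome_and_annotation(spec)
        for record, info in zip(records, manifest["transcripts"]):
            got = sorted(
                (c.start_tx, c.category, c.peptide_len) for c in scan_uorfs(record)
            )
            want = sorted(
                (u["start_tx"], u["category"], u["peptide_len"]) for u in info["uorfs"]
            )
            assert got == want, f"seed {seed} {record.transcript_id}"


def test_infeasible_specs_raise():
    with pytest.raises(FixtureError, match="cannot host"):
        make_genome_and_annotation(
            FixtureSpec(transcripts=(TranscriptPlan(utr5_len=6, uorfs=(UorfPlan("upstream", 9),)),))
        )


def test_zero_background_coverage_recovers_spikes_exactly():
    spec = FixtureSpec(
        seed=3,
        transcripts=(TranscriptPlan(strand="-", n_exons=2),),
        coverage=CoveragePlan(background_rate=0.0, footprint_background=0.0,
                              mrna_rate=0.0, uatg_peak=12.0, patg_peak=3.0),
    )
    _, _, manifest, _, records = make_genome_and_annotation(spec)
    tracks = make_coverage(spec, records, manifest)
    record = records[0]
    init = project_track(tracks["initiation"], record)
    u = manifest["transcripts"][0]["uorfs"][0]
    assert init.values[u["start_tx"]] == 12.0
    assert init.values[record.cds_start_tx] == 3.0
    assert init.values.sum() == 15.0


def test_split_tracks_aggregate_to_the_unsplit_track():
    spec = FixtureSpec(seed=6)
    _, _, manifest, _, records = make_genome_and_annotation(spec)
    tracks = make_coverage(spec, records, manifest)
    full = tracks["footprint"]
    half_a = CoverageTrack("footprint")
    half_b = CoverageTrack("footprint")
    for chrom, data in full.data.items():
        for pos, v in data.items():
            half_a.add(chrom, pos, v * 0.25)
            half_b.add(chrom, pos, v * 0.75)
    agg = aggregate_tracks([half_a, half_b])
    for chrom, data in full.data.items():
        for pos, v in data.items():
            assert agg.data[chrom][pos] == pytest.approx(v)


def test_planted_initiation_peaks_rank_above_controls():
    """Transcripts with planted uATG peaks outrank no-peak controls by
    init_ratio, under Poisson background noise."""
    plans = tuple(
        TranscriptPlan(has_init_peak=(i < 3)) for i in range(6)
    )
    spec = FixtureSpec(seed=12, transcripts=plans)
    _, _, manifest, _, records = make_genome_and_annotation(spec)
    tracks = make_coverage(spec, records, manifest)
    ratios = {}
    for record, info in zip(records, manifest["transcripts"]):
        fp = project_track(tracks["footprint"], record)
        init = project_track(tracks["initiation"], record)
        (u,) = scan_uorfs(record)
        ev = translation_evidence(record, u, fp, init)
        ratios[record.transcript_id] = (info["has_init_peak"], ev.init_ratio)
    peaked = [r for flag, r in ratios.values() if flag]
    unpeaked = [r for flag, r in ratios.values() if not flag]
    assert min(peaked) > max(unpeaked)


def test_quant_tables_are_deterministic_and_well_formed():
    a = make_quant_tables(FixtureSpec(seed=5))
    b = make_quant_tables(FixtureSpec(seed=5))
    assert a[:3] == b[:3]
    qpcr, luc, western, truth = a
    assert qpcr.splitlines()[0] == "sample,group,experiment,target_cq,ref_cq"
    n_rows = truth["replicates"] * truth["experiments"]
    assert len(luc.strip().splitlines()) == 1 + n_rows * len(truth["dlr_folds"])
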