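"""ASO anchoring, chemistry patterns, scrambled controls, and masses."""

import numpy as np
import pytest

from oracles import oracle_oligo_mass, oracle_revcomp

from uorfkit.aso_designer import (
    GapmerSpec,
    OligoDesign,
    ScrambleError,
    UniformScheme,
    apply_chemistry,
    design_uorf_aso,
    mass_qc,
    oligo_mass,
    oligos_to_fasta,
    oligos_to_json,
    oligos_to_tsv,
    scramble_control,
)
from uorfkit.uorf_scanner import scan_uorfs


@pytest.fixture
def uorf_transcript(plain_transcript):
    # uORF ATG at transcript position 20
    utr = "CCACCTCCACCTACCTCACC"  # 20 nt, no ATG
    t = plain_transcript(utr + "ATGAAATAACC" + "ATGCCCTAA", cds_start=31)
    (u,) = scan_uorfs(t)
    assert u.start_tx == 20
    return t, u


def test_aso_is_anchored_on_the_start_codon(uorf_transcript):
    t, u = uorf_transcript
    aso = design_uorf_aso(t, u, 16)
    assert len(aso) == 16
    assert aso.bases[:3] == "CAT"  # 5' end pairs the ATG
    assert aso.target == (t.transcript_id, (7, 23))
    assert aso.bases == oracle_revcomp(t.sequence[7:23])


def test_longer_design_extends_only_at_the_3_prime_end(uorf_transcript):
    t, u = uorf_transcript
    a16 = design_uorf_aso(t, u, 16)
    a18 = design_uorf_aso(t, u, 18)
    assert len(a18) - len(a16) == 2
    assert a18.bases[:16] == a16.bases  # the two extras sit at the ASO 3' terminus


def test_window_underflow_is_an_error(plain_transcript):
    t = plain_transcript("CC" + "ATGAAATAACC" + "ATGCCCTAA", cds_start=13)
    (u,) = scan_uorfs(t)
    with pytest.raises(ValueError, match="underflow"):
        design_uorf_aso(t, u, 16)  # only 5 nt of target 5' of the codon end


def test_uniform_chemistry_schemes(uorf_transcript):
    t, u = uorf_transcript
    aso = apply_chemistry(design_uorf_aso(t, u, 16), UniformScheme("2OMe", "PO"))
    assert aso.sugars == ["2OMe"] * 16 and aso.linkages == ["PO"] * 15
    moe = apply_chemistry(design_uorf_aso(t, u, 16), UniformScheme("MOE", "PS"))
    assert moe.sugars == ["MOE"] * 16 and moe.linkages == ["PS"] * 15


def test_gapmer_patterns():
    g = apply_chemistry("A" * 16, GapmerSpec("3-10-3", flank_sugar="LNA", backbone="PS"))
    assert g.sugars == ["LNA"] * 3 + ["DNA"] * 10 + ["LNA"] * 3
    assert g.linkages == ["PS"] * 15
    g2 = apply_chemistry("A" * 20, GapmerSpec("5-10-5", flank_sugar="MOE", backbone="PS"))
    assert g2.sugars == ["MOE"] * 5 + ["DNA"] * 10 + ["MOE"] * 5
    with pytest.raises(ValueError, match="totals"):
        apply_chemistry("A" * 16, GapmerSpec("5-10-5", flank_sugar="MOE"))


def test_display_renders_u_for_rna_family_sugars():
    o = apply_chemistry("CATT", UniformScheme("2OMe", "PO"))
    assert o.display_sequence == "CAUU"
    d = apply_chemistry("CATT", UniformScheme("MOE", "PS"))
    assert d.display_sequence == "CATT"  # MOE keeps thymine


def test_scramble_preserves_composition_and_chemistry(uorf_transcript):
    t, u = uorf_transcript
    aso = apply_chemistry(design_uorf_aso(t, u, 16), UniformScheme("MOE", "PS"))
    ctrl = scramble_control(aso, seed=17)
    assert sorted(ctrl.bases) == sorted(aso.bases)
    assert ctrl.bases != aso.bases
    assert ctrl.sugars == aso.sugars and ctrl.linkages == aso.linkages
    # deterministic for a given seed
    again = scramble_control(aso, seed=17)
    assert again.bases == ctrl.bases
    # and seed-sensitive (different stream, overwhelmingly different result)
    other = scramble_control(aso, seed=18)
    assert other.bases != ctrl.bases


def test_scramble_complement_run_constraint(uorf_transcript):
    t, u = uorf_transcript
    aso = apply_chemistry(design_uorf_aso(t, u, 18), UniformScheme("2OMe", "PS"))
    for seed in range(20):
        ctrl = scramble_control(aso, seed=seed, max_complement_run=7)
        # no 7-mer of the control still pairs contiguously with the target
        for k in range(len(ctrl.bases) - 6):
            assert ctrl.bases[k : k + 7] not in aso.bases


def test_scramble_degenerate_and_unsatisfiable_inputs():
    mono = OligoDesign("mono", "AAAA", ["DNA"] * 4, ["PO"] * 3)
    with pytest.raises(ScrambleError, match="distinct"):
        scramble_control(mono, seed=1)
    nearly = OligoDesign("near", "AAAAAAAAAAAAAAAT", ["DNA"] * 16, ["PO"] * 15)
    with pytest.raises(ScrambleError, match="no permutation") as err:
        scramble_control(nearly, seed=1, max_complement_run=3, max_tries=50)
    assert err.value.best_candidate is not None


def test_nucleoside_masses_match_hand_summed_formulas():
    # 2'-deoxyadenosine: C10H13N5O3, average 251.24 Da
    da = OligoDesign("dA", "A", ["DNA"], [])
    assert oligo_mass(da, "average") == pytest.approx(251.24, abs=0.02)
    assert oligo_mass(da, "monoisotopic") == pytest.approx(251.1018, abs=0.001)
    for sugar in ("DNA", "RNA", "2OMe", "MOE", "LNA"):
        for base in "ACGT":
            o = OligoDesign("n", base, [sugar], [])
            assert oligo_mass(o, "average") == pytest.approx(
                oracle_oligo_mass(base, [sugar], [], "average"), rel=1e-4
            )


def test_ps_po_difference_is_sulfur_for_oxygen():
    from pyteomics import mass as pmass

    po = apply_chemistry("ACGTACGTACGTACGT", UniformScheme("DNA", "PO"))
    ps = apply_chemistry("ACGTACGTACGTACGT", UniformScheme("DNA", "PS"))
    d_so = pmass.calculate_mass(formula="S", average=True) - pmass.calculate_mass(
        formula="O", average=True
    )
    assert oligo_mass(ps) - oligo_mass(po) == pytest.approx(15 * d_so, rel=1e-9)


def test_mass_additivity_telescopes_across_chemistries():
    """mass(n+1 nt) - mass(n nt) equals the added nucleoside plus one
    linkage, for every sugar/backbone combination."""
    rng = np.random.default_rng(61)
    for sugar in ("DNA", "RNA", "2OMe", "MOE", "LNA"):
        for backbone in ("PO", "PS"):
            bases = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=9))
            for n in range(1, 9):
                small = OligoDesign("s", bases[:n], [sugar] * n, [backbone] * (n - 1))
                big = OligoDesign("b", bases[: n + 1], [sugar] * (n + 1), [backbone] * n)
                diff = oligo_mass(big) - oligo_mass(small)
                residue = oracle_oligo_mass(bases[n], [sugar], []) + oracle_oligo_mass(
                    "A", ["DNA"], [backbone]
                ) - oracle_oligo_mass("A", ["DNA"], [])
                assert diff == pytest.approx(residue, rel=1e-4)


def test_five_prime_phosphate_option():
    from pyteomics import mass as pmass

    o = apply_chemistry("ACGT", UniformScheme("DNA", "PO"))
    delta = oligo_mass(o, five_prime_phosphate=True) - oligo_mass(o)
    assert delta == pytest.approx(pmass.calculate_mass(formula="HPO3", average=True), rel=1e-9)


def test_mass_qc_contract():
    assert mass_qc(1000.0, 1000.0) == (True, 0.0)
    passed, err = mass_qc(1002.1, 1000.0)
    assert not passed and err == pytest.approx(0.0021)
    rng = np.random.default_rng(67)
    for _ in range(200):
        expected = float(rng.uniform(3000, 8000))
        observed = expected * float(1 + rng.normal(0, 0.002))
        passed, err = mass_qc(observed, expected)
        assert passed == (abs(observed - expected) / expected < 0.002)
    with pytest.raises(ValueError, match="positive"):
        mass_qc(-1.0, 5000.0)


def test_oligo_sheet_writers(uorf_transcript):
    t, u = uorf_transcript
    oligos = [
        apply_chemistry(design_uorf_aso(t, u, 16), UniformScheme("2OMe", "PO")),
        apply_chemistry(design_uorf_aso(t, u, 16), UniformScheme("MOE", "PS")),
    ]
    tsv = oligos_to_tsv(oligos)
    assert len(tsv.strip().splitlines()) == 3
    assert "mass_average" in tsv.splitlines()[0]
    import json

    rows = json.loads(oligos_to_json(oligos))
    assert rows[0]["length"] == 16
    fasta = oligos_to_fasta(oligos)
    assert fasta.count(">") == 2
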