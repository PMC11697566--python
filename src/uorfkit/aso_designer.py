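"""Steric-block ASO design, chemistry patterns, scrambled controls, and
expected-mass calculation for mass-spectrometry QC.

Design anchoring: a uORF-targeting ASO is anchored so that its 5'-terminal
three nucleotides base-pair with the uORF start codon — for an ATG start
the ASO therefore begins "CAT" — and longer variants of the same design
extend only at the ASO 3' terminus (deeper into the upstream target
sequence). Scrambled chemistry controls permute the base sequence while
keeping the per-position sugar pattern and per-linkage backbone pattern
byte-identical.

Sequences are stored in the DNA alphabet (ACGT) with sugar chemistry
carried separately, so all complementarity arithmetic uses one alphabet;
the display layer renders U at RNA-family sugar positions (RNA, 2'-O-Me).
Masses are assembled from elemental compositions (nucleoside = base +
sugar - H2O; each phosphodiester linkage contributes HPO3 - H2O; a
phosphorothioate linkage swaps one non-bridging O for S), so a new
chemistry is one table row. Termini default to 5'-OH/3'-OH.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, replace

from Bio.Seq import Seq
from pyteomics import mass as _pmass

from .transcript_model import TranscriptRecord
from .uorf_scanner import UorfCall

__all__ = [
    "OligoDesign",
    "GapmerSpec",
    "UniformScheme",
    "design_uorf_aso",
    "apply_chemistry",
    "scramble_control",
    "oligo_mass",
    "mass_qc",
    "oligo_composition",
    "oligos_to_tsv",
    "oligos_to_json",
    "oligos_to_fasta",
    "ScrambleError",
]

SUGARS = ("DNA", "RNA", "2OMe", "MOE", "LNA")
LINKAGES = ("PO", "PS")
# sugars whose pyrimidine base is uracil rather than thymine (ribose-like)
_RNA_FAMILY = frozenset({"RNA", "2OMe"})


class ScrambleError(RuntimeError):
    """Scramble constraints unsatisfiable; carries the best candidate found."""

    def __init__(self, message: str, best_candidate: str | None = None):
        super().__init__(message)
        self.best_candidate = best_candidate


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class OligoDesign:
    """An antisense oligo: bases 5'->3' plus per-position sugar and
    per-linkage backbone chemistry."""

    name: str
    bases: str
    sugars: list[str]
    linkages: list[str]
    target: tuple[str, tuple[int, int]] | None = None  # (transcript_id, tx interval)

    def __post_init__(self) -> None:
        if set(self.bases) - set("ACGT"):
            raise ValueError(f"{self.name}: bases must be ACGT (store 2OMe-U as T)")
        if len(self.sugars) != len(self.bases):
            raise ValueError(f"{self.name}: need one sugar per base")
        if len(self.linkages) != max(len(self.bases) - 1, 0):
            raise ValueError(f"{self.name}: need len(bases)-1 linkages")
        for s in self.sugars:
            if s not in SUGARS:
                raise ValueError(f"{self.name}: unknown sugar {s!r}")
        for lk in self.linkages:
            if lk not in LINKAGES:
                raise ValueError(f"{self.name}: unknown linkage {lk!r}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def display_sequence(self) -> str:
        """Render U at RNA-family sugar positions (2OMe "U" is stored as T)."""
        return "".join(
            "U" if base == "T" and sugar in _RNA_FAMILY else base
            for base, sugar in zip(self.bases, self.sugars)
        )

    @property
    def sugar_string(self) -> str:
        return ",".join(self.sugars)

    @property
    def linkage_string(self) -> str:
        return ",".join(self.linkages)


@dataclass(frozen=True)
class UniformScheme:
    """One sugar and one backbone chemistry applied at every position,
    e.g. PO-2OMe (phosphodiester 2'-O-methyl) or PS-MOE."""

    sugar: str
    backbone: str

    def __post_init__(self) -> None:
        if self.sugar not in SUGARS:
            raise ValueError(f"unknown sugar {self.sugar!r}")
        if self.backbone not in LINKAGES:
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass(frozen=True)
class GapmerSpec:
    """Flank-gap-flank chemistry, e.g. "3-10-3" LNA/PS or "5-10-5" MOE/PS
    with a central DNA gap that supports RNase H cleavage."""

    design: str
    flank_sugar: str
    gap_sugar: str = "DNA"
    backbone: str = "PS"

    def __post_init__(self) -> None:
        a, b, c = self.lengths
        if min(a, b, c) < 1:
            raise ValueError(f"gapmer segments must be >= 1 nt, got {self.design!r}")
        if self.flank_sugar not in ("LNA", "MOE", "2OMe"):
            raise ValueError(f"unsupported gapmer flank sugar {self.flank_sugar!r}")
        if self.backbone not in LINKAGES:
            raise ValueError(f"unknown backbone {self.backbone!r}")

    @property
    def lengths(self) -> tuple[int, int, int]:
        parts = self.design.split("-")
        if len(parts) != 3:
            raise ValueError(f"gapmer design must look like 'a-b-c', got {self.design!r}")
        return tuple(int(p) for p in parts)  # type: ignore[return-value]

    @property
    def total(self) -> int:
        return sum(self.lengths)


def design_uorf_aso(
    t: TranscriptRecord, u: UorfCall, length: int, name: str | None = None
) -> OligoDesign:
    """Design a steric-block ASO whose 5'-terminal 3 nt pair with the uORF
    start codon.

    The target window is [start_tx + 3 - L, start_tx + 3): it ends at the
    3' edge of the start codon, so longer designs reach further into the
    upstream target sequence and, on the antisense strand, gain their
    extra nucleotides at the ASO 3' terminus.
    """
    if length < 3:
        raise ValueError("ASO length must be at least 3 nt (the start codon)")
    if t.sequence is None:
        raise ValueError("transcript sequence unset")
    window_start = u.start_tx + 3 - length
    window_end = u.start_tx + 3
    if window_start < 0:
        raise ValueError(
            f"ASO window underflows the transcript 5' end "
            f"(need {length} nt ending at {window_end}, transcript starts at 0)"
        )
    target_seq = t.sequence[window_start:window_end]
    bases = _revcomp(target_seq)
    return OligoDesign(
        name=name or f"{t.transcript_id}_uORF{u.start_tx}_{length}mer",
        bases=bases,
        sugars=["DNA"] * length,
        linkages=["PO"] * (length - 1),
        target=(t.transcript_id, (window_start, window_end)),
    )


def apply_chemistry(design, scheme) -> OligoDesign:
    """Apply a uniform or gapmer chemistry scheme to an oligo (or a plain
    base string), returning a new OligoDesign."""
    if isinstance(design, str):
        design = OligoDesign("oligo", design, ["DNA"] * len(design),
                             ["PO"] * max(len(design) - 1, 0))
    n = len(design)
    if isinstance(scheme, UniformScheme):
        sugars = [scheme.sugar] * n
        backbone = scheme.backbone
    elif isinstance(scheme, GapmerSpec):
        a, b, c = scheme.lengths
        if scheme.total != n:
            raise ValueError(
                f"gapmer design {scheme.design} totals {scheme.total} nt "
                f"but oligo {design.name!r} is {n} nt"
            )
        sugars = [scheme.flank_sugar] * a + [scheme.gap_sugar] * b + [scheme.flank_sugar] * c
        backbone = scheme.backbone
    else:
        raise TypeError(f"unsupported chemistry scheme {type(scheme).__name__}")
    return replace(design, sugars=sugars, linkages=[backbone] * max(n - 1, 0))


# -- scrambled chemistry controls --------------------------------------


def _longest_common_substring(a: str, b: str) -> int:
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def scramble_control(
    o: OligoDesign,
    seed: int,
    max_complement_run: int = 7,
    max_tries: int = 10_000,
) -> OligoDesign:
    """Generate a chemistry-preserving scrambled control.

    The base sequence is permuted (identical base composition) while the
    sugar and linkage patterns are copied unchanged. The permutation must
    differ from the original and must not retain a contiguous
    reverse-complement match of ``max_complement_run`` nt or more against
    the original target window. Deterministic for a given seed.
    """
    if len(o) < 2 or len(set(o.bases)) < 2:
        raise ScrambleError(
            f"{o.name!r}: cannot scramble a sequence with fewer than two distinct bases"
        )
    rng = random.Random(seed)
    letters = list(o.bases)
    best, best_run = None, None
    for _ in range(max_tries):
        rng.shuffle(letters)
        candidate = "".join(letters)
        if candidate == o.bases:
            continue
        # original bases are the reverse complement of the target window, so
        # pairing runs vs the target are common substrings vs the original
        run = _longest_common_substring(candidate, o.bases)
        if best_run is None or run < best_run:
            best, best_run = candidate, run
        if run < max_complement_run:
            return replace(
                o,
                name=f"{o.name}_scr",
                bases=candidate,
                sugars=list(o.sugars),
                linkages=list(o.linkages),
                target=None,
            )
    raise ScrambleError(
        f"{o.name!r}: no permutation with complement run < {max_complement_run} "
        f"found in {max_tries} tries (best candidate run {best_run})",
        best_candidate=best,
    )


# -- expected-mass calculation -----------------------------------------

# free nucleobases
_BASE_FORMULA = {
    "A": "C5H5N5",     # adenine
    "G": "C5H5N5O",    # guanine
    "C": "C4H5N3O",    # cytosine
    "T": "C5H6N2O2",   # thymine (5-methyluracil)
    "U": "C4H4N2O2",   # uracil
}
# free sugars; modifications relative to ribose: 2OMe +CH2, MOE +C3H6O,
# LNA +CH2-H2 (the 2'-O,4'-C methylene bridge)
_SUGAR_FORMULA = {
    "DNA": "C5H10O4",   # 2-deoxyribose
    "RNA": "C5H10O5",   # ribose
    "2OMe": "C6H12O5",  # 2'-O-methylribose
    "MOE": "C8H16O6",   # 2'-O-(2-methoxyethyl)ribose
    "LNA": "C6H10O5",   # locked (bicyclic) ribose
}
_WATER = _pmass.Composition(formula="H2O")
# phosphodiester bridge: +HPO3 -H2O per linkage
_LINKAGE_COMPOSITION = {
    "PO": {"H": -1, "O": 2, "P": 1},
    "PS": {"H": -1, "O": 1, "P": 1, "S": 1},  # one non-bridging O -> S
}
_PHOSPHATE_5P = {"H": 1, "O": 3, "P": 1}  # optional 5'-phosphate terminus


def _nucleoside_composition(base: str, sugar: str) -> _pmass.Composition:
    if sugar not in _SUGAR_FORMULA:
        raise ValueError(f"unknown sugar modification {sugar!r}")
    if base == "T" and sugar in _RNA_FAMILY:
        base = "U"  # RNA-family sugars carry uracil, not thymine
    comp = _pmass.Composition(formula=_BASE_FORMULA[base])
    comp += _pmass.Composition(formula=_SUGAR_FORMULA[sugar])
    comp -= _WATER  # glycosidic bond
    return comp


def oligo_composition(o: OligoDesign, five_prime_phosphate: bool = False) -> _pmass.Composition:
    """Total elemental composition of an oligo (default 5'-OH/3'-OH)."""
    total = _pmass.Composition()
    for base, sugar in zip(o.bases, o.sugars):
        total += _nucleoside_composition(base, sugar)
    for lk in o.linkages:
        if lk not in _LINKAGE_COMPOSITION:
            raise ValueError(f"unknown linkage {lk!r}")
        total += _pmass.Composition(_LINKAGE_COMPOSITION[lk])
    if five_prime_phosphate:
        total += _pmass.Composition(_PHOSPHATE_5P)
    return total


def oligo_mass(o: OligoDesign, kind: str = "average", five_prime_phosphate: bool = False) -> float:
    """Expected neutral mass in Da (``average`` or ``monoisotopic``)."""
    if kind not in ("average", "monoisotopic"):
        raise ValueError(f"mass kind must be 'average' or 'monoisotopic', got {kind!r}")
    comp = oligo_composition(o, five_prime_phosphate=five_prime_phosphate)
    return float(_pmass.calculate_mass(composition=comp, average=(kind == "average")))


def mass_qc(observed: float, expected: float, tol_fraction: float = 0.002):
    """MS integrity check: pass iff |observed - expected| / expected < tol
    (0.2% by default). Returns (passed, relative_error)."""
    if observed <= 0 or expected <= 0:
        raise ValueError("masses must be positive")
    rel_err = abs(observed - expected) / expected
    return rel_err < tol_fraction, rel_err


# -- oligo sheet I/O ---------------------------------------------------


def _sheet_rows(oligos: list[OligoDesign]) -> list[dict]:
    return [
        {
            "name": o.name,
            "bases": o.bases,
            "display_sequence": o.display_sequence,
            "sugars": o.sugar_string,
            "linkages": o.linkage_string,
            "length": len(o),
            "mass_average": round(oligo_mass(o, "average"), 4),
            "mass_monoisotopic": round(oligo_mass(o, "monoisotopic"), 4),
            "target": (f"{o.target[0]}:{o.target[1][0]}-{o.target[1][1]}" if o.target else ""),
        }
        for o in oligos
    ]


def oligos_to_tsv(oligos: list[OligoDesign]) -> str:
    rows = _sheet_rows(oligos)
    cols = list(rows[0]) if rows else []
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(r[c]) for c in cols) for r in rows]
    return "\n".join(lines) + "\n"


def oligos_to_json(oligos: list[OligoDesign]) -> str:
    return json.dumps(_sheet_rows(oligos), indent=2) + "\n"


def oligos_to_fasta(oligos: list[OligoDesign]) -> str:
    return "".join(f">{o.name}\n{o.bases}\n" for o in oligos)
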