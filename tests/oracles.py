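"""Independent reference implementations used only by tests.

Everything here is deliberately naive (per-base enumeration, dense
arrays, hand-frozen formula tables) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

STOPS = {"TAA", "TAG", "TGA"}

# full standard genetic code, written out by hand
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - 2, 3):
        aa = CODON_TABLE[nt[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def transcript_base_sources(exons, strand):
    """Genomic source position of every transcript base, by enumeration."""
    plus_order = [g for start, end in exons for g in range(start, end)]
    return plus_order if strand == "+" else plus_order[::-1]


def oracle_spliced_sequence(chrom_seq, exons, strand):
    if strand == "+":
        return "".join(chrom_seq[g] for g in transcript_base_sources(exons, "+"))
    return "".join(_COMPLEMENT[chrom_seq[g]] for g in transcript_base_sources(exons, "-"))


def oracle_scan(seq: str, cds_start: int, starts=frozenset({"ATG"}),
                include_extensions: bool = False):
    """Exhaustive uORF enumeration: every UTR position, triplet walk,
    naive classification. Returns (start, stop_end|None, category,
    peptide, peptide_len) tuples ordered by start."""
    calls = []
    for p in range(cds_start):
        if seq[p : p + 3] not in starts:
            continue
        stop = None
        q = p + 3
        while q + 3 <= len(seq):
            if seq[q : q + 3] in STOPS:
                stop = q
                break
            q += 3
        frame = (p - cds_start) % 3
        if frame == 0 and (stop is None or stop >= cds_start):
            if include_extensions:
                calls.append((p, None, "n_terminal_extension",
                              oracle_translate(seq[p:cds_start]), (cds_start - p) // 3))
            continue
        if stop is None:
            n_codons = (len(seq) - p) // 3
            calls.append((p, None, "no_stop",
                          oracle_translate(seq[p : p + 3 * n_codons]), n_codons))
            continue
        stop_end = stop + 3
        category = "upstream" if stop_end <= cds_start else "overlapping"
        peptide = oracle_translate(seq[p:stop_end])
        calls.append((p, stop_end, category, peptide, len(peptide)))
    return calls


# -- oligo mass: hand-frozen molecular formulas ------------------------

# standard atomic weights (IUPAC) and monoisotopic masses (CODATA)
ATOMIC_AVG = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}
ATOMIC_MONO = {"H": 1.007825, "C": 12.0, "N": 14.003074, "O": 15.994915,
               "P": 30.973762, "S": 31.972071}

# nucleoside molecular formulas, summed by hand from base + sugar - H2O;
# RNA-family sugars (RNA, 2OMe) carry uracil in place of thymine
NUCLEOSIDE_FORMULAS = {
    ("A", "DNA"): {"C": 10, "H": 13, "N": 5, "O": 3},
    ("C", "DNA"): {"C": 9, "H": 13, "N": 3, "O": 4},
    ("G", "DNA"): {"C": 10, "H": 13, "N": 5, "O": 4},
    ("T", "DNA"): {"C": 10, "H": 14, "N": 2, "O": 5},
    ("A", "RNA"): {"C": 10, "H": 13, "N": 5, "O": 4},
    ("C", "RNA"): {"C": 9, "H": 13, "N": 3, "O": 5},
    ("G", "RNA"): {"C": 10, "H": 13, "N": 5, "O": 5},
    ("T", "RNA"): {"C": 9, "H": 12, "N": 2, "O": 6},   # uridine
    ("A", "2OMe"): {"C": 11, "H": 15, "N": 5, "O": 4},
    ("C", "2OMe"): {"C": 10, "H": 15, "N": 3, "O": 5},
    ("G", "2OMe"): {"C": 11, "H": 15, "N": 5, "O": 5},
    ("T", "2OMe"): {"C": 10, "H": 14, "N": 2, "O": 6},  # 2'-O-methyluridine
    ("A", "MOE"): {"C": 13, "H": 19, "N": 5, "O": 5},
    ("C", "MOE"): {"C": 12, "H": 19, "N": 3, "O": 6},
    ("G", "MOE"): {"C": 13, "H": 19, "N": 5, "O": 6},
    ("T", "MOE"): {"C": 13, "H": 20, "N": 2, "O": 7},
    ("A", "LNA"): {"C": 11, "H": 13, "N": 5, "O": 4},
    ("C", "LNA"): {"C": 10, "H": 13, "N": 3, "O": 5},
    ("G", "LNA"): {"C": 11, "H": 13, "N": 5, "O": 5},
    ("T", "LNA"): {"C": 11, "H": 14, "N": 2, "O": 6},
}
LINKAGE_FORMULAS = {
    "PO": {"H": -1, "O": 2, "P": 1},
    "PS": {"H": -1, "O": 1, "P": 1, "S": 1},
}


def oracle_oligo_mass(bases, sugars, linkages, kind="average") -> float:
    table = ATOMIC_AVG if kind == "average" else ATOMIC_MONO
    total: dict[str, int] = {}
    for base, sugar in zip(bases, sugars):
        for el, n in NUCLEOSIDE_FORMULAS[(base, sugar)].items():
            total[el] = total.get(el, 0) + n
    for lk in linkages:
        for el, n in LINKAGE_FORMULAS[lk].items():
            total[el] = total.get(el, 0) + n
    return sum(table[el] * n for el, n in total.items())
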