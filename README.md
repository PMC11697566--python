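# uorfkit

Toolkit for screening transcripts for upstream open reading frames
(uORFs), scoring their translation with aggregated ribosome-profiling
coverage, and designing chemistry-annotated steric-block antisense
oligonucleotides (ASOs) — with matched scrambled controls, expected-mass
QC for mass spectrometry, and the downstream quantification math
(efficiency-corrected qPCR and dual-luciferase / loading-control
normalization) needed to evaluate uORF-perturbation experiments.

## The biology and the model

A uORF is a start codon in a transcript's 5′ UTR followed by an in-frame
stop codon; uORFs typically repress translation of the downstream primary
ORF (pORF). `uorfkit` scans every UTR position `p < cds_start` whose codon
is a start (AUG by default; near-cognate CUG/GUG/UUG/ACG behind a flag),
walks triplets to the first in-frame stop, and classifies each call:

* **upstream** — stop ends at or before the pORF start;
* **overlapping** — stop lies inside the pORF (necessarily in a shifted
  frame, `(start − cds_start) mod 3 ≠ 0`);
* **n_terminal_extension** — in-frame start with no intervening stop (not
  a uORF; excluded by default);
* **no_stop** — out-of-frame start with no stop before the transcript end.

Peptide lengths count amino acids from the initiator Met and exclude the
stop, so a 9-aa uORF spans 30 nt including its stop codon. The in-silico
ablation mirrors the classic mutant construct: the uORF AUG is mutated to
UUG and the transcript rescanned.

Translation evidence comes from per-genomic-coordinate coverage tracks of
three kinds (ribosome footprints, initiating ribosomes, RNA-Seq), summed
across datasets to amplify low-coverage signal, projected strand-aware
onto transcript coordinates, and summarized per uORF as

```
init_ratio = (init[uAUG ± w] + ε) / (init[pAUG ± w] + ε),   w = 3 nt, ε = 0.5
```

a ratio ≫ 1 — initiation concentrated at the uAUG rather than the pAUG —
is the signature of uORF-mediated repression.

ASO designs are anchored so that the oligo's 5′-terminal three bases pair
with the uORF start codon (an AUG-anchored ASO always begins `CAT`);
longer variants extend only at the ASO 3′ terminus. Uniform chemistries
(e.g. PO-2′OMe, PS-MOE) and gapmers (`3-10-3` LNA/PS, `5-10-5` MOE/PS with
a central DNA gap) are applied per position; scrambled controls permute
the bases while preserving the sugar and backbone patterns byte-for-byte.
Expected neutral masses are assembled from elemental compositions
(nucleoside = base + sugar − H₂O; each phosphodiester linkage adds
HPO₃ − H₂O; phosphorothioate swaps one non-bridging O for S) and checked
against observed masses at the 0.2% instrument tolerance.

Relative quantification follows the Pfaffl model with assay-specific
amplification efficiencies,

```
ratio = E_target^ΔCq_target / E_ref^ΔCq_ref,   ΔCq = Cq_control − Cq_treated
```

(reducing to the Livak 2^−ΔΔCq form at E = 2), and reporter/western
normalization computes per-well Renilla/firefly (or target/loading)
ratios scaled so the control-group mean is exactly 1.

## Worked example

```python
from uorfkit import *
from uorfkit.simulate import rnaseh1_like_transcript

record, _ = rnaseh1_like_transcript()     # synthetic RNASEH1-style fixture
(u,) = scan_uorfs(record)
print(u.category, u.peptide_len, u.peptide)
# overlapping 9 MLLNFTHAN

a16 = design_uorf_aso(record, u, 16)
a18 = design_uorf_aso(record, u, 18)
print(a16.bases)                          # CATCGCTACGACCGTA   (5' CAT pairs the AUG)
print(a18.bases)                          # CATCGCTACGACCGTACC (two extra nt, 3' end)

moe = apply_chemistry(a16, UniformScheme("MOE", "PS"))
print(round(oligo_mass(moe, "average"), 2))   # 6252.4 Da
ctrl = scramble_control(moe, seed=7)
print(ctrl.bases)                         # CTAGGCGCCCACATTA — same composition,
                                          # identical chemistry pattern
```

The transcript here is generated (one overlapping uORF encoding a 9-aa
peptide, the RNASEH1 architecture); to scan the real RefSeq record use
`uorfkit.remote.fetch_refseq("NM_002936.5")` with network access.

A CLI mirrors the library: `uorfkit simulate | scan | design-aso | mass |
evidence | quant` (see `uorfkit --help`).

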