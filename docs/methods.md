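# Methods

## Coordinate model

All internal coordinates are 0-based half-open; GTF/GFF3 (1-based
inclusive) convert at the parser boundary, and refFlat-style tables are
taken as already 0-based half-open (UCSC convention). Exons are stored in
ascending genomic order on both strands; the coordinate maps
(`transcript_to_genomic` / `genomic_to_transcript`) handle orientation,
and a minus-strand spliced sequence is the reverse complement of the
ascending exon concatenation. One convention internally eliminates
off-by-one drift; the round-trip identity is property-tested on 1000
random exon structures per run.

Whether an annotated CDS includes its stop codon varies by source, so the
readers accept `cds_includes_stop` (default true) and normalize so CDS
bounds always include the stop, extending 3 nt in the transcript 3′
direction across exon junctions when needed. Chromosome names are matched
by exact string comparison; a `normalize_chrom` helper strips `chr`
prefixes but is never applied implicitly. Non-coding transcripts are
parsed and retained; the uORF scanner rejects them explicitly.

## uORF scanning

Every UTR position whose codon is in the start set yields at most one
call (default AUG-only; near-cognate starts CUG/GUG/UUG/ACG behind
`report_near_cognate`). The triplet walk halts at the first in-frame
UAA/UAG/UGA. Classification follows the category invariants listed in the
README; two deliberate edge policies:

* an in-frame upstream AUG with no intervening stop is labelled
  `n_terminal_extension` and excluded from default output — it extends
  the pORF protein and is not a uORF under the stop-codon definition;
* an out-of-frame start with no stop before the transcript end is
  labelled `no_stop` and reported with the stop coordinate absent, so
  pathological annotations surface instead of disappearing.

Multiple starts sharing one stop are reported individually (each is a
distinct initiation site, matching the initiation-peak logic);
`collapse_same_stop` keeps the 5′-most. Peptides include the initiator
Met and exclude the stop (9 aa ⇔ 30 nt span including the stop). The
scanner is validated against an independent exhaustive enumerator on 1000
random sequences per test run.

Start-codon ablation replaces the A of the uORF AUG with U (AUG→UUG),
the standard uORF-disrupting mutation; rescanning the mutant drops
exactly the targeted call when its span contains no other call's bases.

## Coverage tracks and translation evidence

Tracks are sparse per-genomic-coordinate maps (absent = 0, values ≥ 0) of
kind footprint / initiation / mrna. Aggregation across datasets is a
per-coordinate **sum** by default: summing amplifies signal in
low-coverage regions, which is the point of aggregating many datasets; a
`mean` option exists for depth-normalized inputs. No claim is made of
matching any particular public aggregate numerically — inputs are
arbitrary bedGraph/wiggle (bigwig behind a pyBigWig capability check, so
desk-scale use needs no binary tooling).

An initiation "peak" is a windowed sum over ±3 nt around the A of the
codon — the window absorbs P-site offset slop between datasets and is
configurable. The evidence ratio uses a pseudocount ε = 0.5 so an
unexpressed pAUG (the qualitative case of interest: strong uAUG signal,
little pAUG signal) yields a large finite ratio rather than a division by
zero. uORF occupancy is the arithmetic mean footprint over the uORF span
including the stop.

## ASO design and masses

"5′ end complementary to the start codon" is implemented as: the ASO's
5′-terminal trinucleotide pairs the AUG, so the target window is
`[start + 3 − L, start + 3)` and a longer design gains bases at the ASO 3′
terminus. Scrambled controls permute the base multiset, copy the sugar
and linkage lists unchanged, and reject candidates retaining a contiguous
reverse-complement run ≥ 7 nt against the original target window (the
run constraint is this package's choice; generation is deterministic per
seed, and unsatisfiable constraints raise with the best candidate found).

Bases are stored in the DNA alphabet with sugars carried separately, so
all complementarity math uses one alphabet; display renders U at
RNA-family positions (RNA, 2′OMe), and mass calculation substitutes
uracil for thymine at those positions. MOE positions keep thymine;
5-methyl-cytosine (common in synthesized MOE/LNA gapmers) is not modelled
— masses for C-containing gapmers are for unmethylated C, a known
limitation. Termini default to 5′-OH/3′-OH (typical for unconjugated
synthesis); a 5′-phosphate option adds HPO₃.

Masses are assembled from elemental compositions, not per-residue
constants, so a new chemistry is one sugar-formula table row:
nucleoside = base + sugar − H₂O; each linkage contributes HPO₃ − H₂O
(net −H +O₂ +P), with PS swapping one non-bridging O for S; evaluation
against average or monoisotopic atomic-mass tables is delegated to
pyteomics. The MS QC check passes when |observed − expected|/expected
< 0.2%, the tolerance routinely quoted for MALDI-TOF/LC-MS oligo
integrity checks.

## Quantification

Pfaffl ratios average replicate Cq values on the Cq scale before
exponentiation (standard practice). Reporter and loading-control
normalization compute per-well ratios first, then divide by the
reference-group mean ratio, making the control mean exactly 1; when an
`experiment` column is present, scaling is per independent experiment
before pooling (default; a pooled mode exists because the alternative
order is also defensible and the choice is not derivable from first
principles). Missing wells are dropped with a logged warning, never
imputed. Group comparisons (t tests, one-way ANOVA + Tukey) are thin
wrappers over scipy routines — reporting conveniences, not bespoke
statistics.

## Synthetic data generator

The generator emulates the structure of the experiments the toolkit
serves, not their molecular detail:

* **Genomes/annotations** — UTR background sequence is sampled with a
  rule that excludes G whenever the two preceding bases read "AT", so no
  accidental AUG can form in a 5′ UTR; planted uORF interiors use G-free
  non-stop codons; overlapping uORFs are constructed to straddle the CDS
  start at a frame-shifted offset with their stop clear of the pAUG.
  Every planted uORF is therefore recoverable exactly (position,
  category, peptide length), and the generator re-scans its own output
  and raises on any mismatch. Transcripts are embedded in chromosomes
  with random flanks and introns, on either strand. pORF interiors may
  contain in-frame stops where a planted overlapping uORF constrains the
  sequence — harmless for scanning, which uses only the CDS start.
* **Coverage** — Poisson background (simplest non-negative count noise)
  plus deterministic spikes: initiation at each planted uAUG (default 30)
  and at the pAUG (default 2), uniform extra footprint over uORF spans.
* **Quantification tables** — lognormal multiplicative noise (simplest
  non-negative multiplicative model) at CV 10% with 4 replicates; planted
  effects default to a 5.5-fold luciferase de-repression for the
  uORF-ablated (TTG) construct, no transcript-level change, and a null
  ASO effect on western signal.

One fixture seed expands to per-component child seeds by a fixed counter
scheme (genome = 0, coverage = 1, quant = 2), so adding outputs never
perturbs existing ones; identical spec + seed gives byte-identical files.

What passing tests on this data do **not** show: real 5′ UTRs have
non-uniform base composition, GC structure, and near-cognate starts;
real Ribo-Seq has P-site offsets, periodicity, and batch effects; real
plates have positional and inter-experiment effects beyond lognormal
noise. The fixtures validate the arithmetic and the contracts, not
biological discovery performance.

The bundled RNASEH1-style worked example is a generated stand-in with the
same architecture as the real transcript (one overlapping uORF, 9-aa
peptide); scanning the actual RefSeq record requires network access via
`uorfkit.remote.fetch_refseq`.

## Problem sizes

Default test and reproduction runs use desk-scale inputs chosen to
exercise every code path: ~100–400 nt transcripts, 1000-transcript
property sweeps, 100-seed generator/scanner cross-validation, 200-run
type-I-error calibration, and 4-replicate quantification tables. These
sizes are the package's own verification design; all scale linearly for
larger inputs.
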