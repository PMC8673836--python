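# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, including the places where the design was genuinely
open and a decision had to be made.

## Structure model

Structures are reduced to chains → residues → atoms with coordinates in
Angstrom; nothing downstream converts units. Chain roles are assigned from
residue-name composition: ≥ 90% standard deoxyribonucleotides (including
MD-style 5′/3′ terminal variants such as DA5/DT3) → `dna`, ≥ 90% standard
amino acids → `protein`, everything else → `other`. Waters, ions and
modified residues are therefore kept but routed out of contact analysis;
they are logged, never silently dropped.

Multi-model files keep one model per structure object; the default is model
1, the common convention for NMR ensembles used as modelling templates, and
an explicit `model_choice` overrides it. Altloc groups resolve to a single
conformer — highest occupancy, ties broken toward altloc "A". Hydrogens are
retained but flagged, and excluded from contact counting by default so that
X-ray templates (usually without hydrogens) and NMR or MD structures (with
them) are comparable.

## Contact frequency and ranking

A contact is a (protein heavy atom, DNA heavy atom) pair at Euclidean
distance d ≤ cutoff, with the boundary inclusive and the cutoff defaulting
to 4.0 Å — the standard interface threshold for this kind of analysis.
Contacts are binary per atom pair; no distance weighting.

Across an ensemble of N complexes the per-residue score is the
count-mean, `mean_count = Σ counts / N`, with `support` (fraction of
complexes with ≥ 1 contact) as a companion. Count-mean is the primary
ranking key because it preserves the size of each interface; support breaks
ties and can serve as a floor during nomination (`require_support`).
Remaining ties go to the lower residue number so output is deterministic.
Residues with zero mean count never appear in a ranking.

Homology models built from one query sequence carry query numbering, so
ensemble aggregation uses the author residue number as an identity map by
default; an explicit per-profile residue map is accepted for ensembles that
number differently, and an unmapped key is a hard error rather than a
silent drop.

DNA partner classes: phosphate = {P, OP1, OP2, OP3, O5′, O3′} (legacy
O1P/O2P spellings and `*`-for-prime conventions are normalized), sugar =
remaining primed names, base = all other heavy atoms. Unknown unprimed
names fall through to base with a logged warning, which is the conservative
choice for ring substituents of modified bases.

## Conservation

The default metric is normalized Shannon information, 1 − H/log₂20, over
the amino-acid frequencies of a column with gaps excluded; an all-gap
column scores 0 with coverage 0. Columns with coverage < 0.5 are flagged
low-confidence in output but not filtered — filtering is the caller's
decision. The metric is intentionally simple and order-free; phylogeny-
weighted rates (ConSurf-style) are out of scope, and no attempt is made to
reproduce any particular published conservation table.

## Nomination

A residue is nominated when it sits in its domain's top-k by mean contact
count (k = 4 by default, matching the per-domain shortlist size this
analysis is usually reported with) and its conservation score is ≥ τ.
"Relatively high conservation" is not a quantity; τ defaults to 0.5 and is
echoed into every report so the rule is always explicit. The combination is
a strict intersection — a judgment-call override belongs to the analyst,
not the code. Domains are processed independently and concatenated. A top-k
residue missing from the conservation track is reported as "unscored" and
excluded, not raised: a numbering mismatch should be visible, not fatal.
Nomination is monotone in τ by construction.

## Trajectory analysis

Trajectories are multi-model PDB files; every frame must share the
topology (atom count, ordering and residue identity), and the first
offending frame is named in the error. A frame counts toward persistence
iff the residue has ≥ 1 contact pair; persistence is exactly the mean of
the per-frame flags. The per-frame dominant partner class is the argmax of
class pair-counts with ties resolved phosphate > sugar > base — when a
residue bridges backbone and base equally, the backbone interaction is the
more persistent, load-bearing one to report.

### Simplified interaction energies

The per-residue molecular-mechanics score uses a screened Coulomb term with
distance-dependent dielectric ε(r) = 4r,

    dG_elec = Σ 332.0637 q_i q_j / (4 r²)   [kcal/mol, r in Å, q in e]

plus 12-6 Lennard-Jones with Lorentz–Berthelot combining, over heavy-atom
pairs within 12 Å. Charges and LJ parameters come from a user-supplied TSV
table. This is a ranking-style score for comparing residues within one
system: it is pairwise additive, has the right sign structure (opposite
charges attract; scaling charges by λ scales dG_elec by λ²), and its
absolute values are *not* claimed comparable to a full Poisson–Boltzmann
treatment.

### Free-energy bookkeeping

The end-state decomposition
ΔG_bind = ΔG_MM + ΔG_solv − TΔS, ΔG_MM = ΔG_elec + ΔG_VDW,
ΔG_solv = ΔG_polar + ΔG_nonpolar is implemented as exact arithmetic:
combined terms are derived properties of `EnergyDecomposition`, so the
identities hold to machine precision by construction. Polar/nonpolar
solvation and the entropy term are accepted as externally computed values
(default 0) — PB/GB solvers and normal-mode entropy are deliberately out of
scope, as they are run in dedicated MD packages.

### Ion arithmetic

Neutralizing counter-ions are the absolute solute charge in Na⁺ (negative
solute) or Cl⁻ (positive). Salt pairs use the naive convention
n = round(c · N_A · V_box), rounding half-away-from-zero, with V_box the
full cubic box volume; for a 78 Å box at 100 mM this gives 29 pairs.
Conventions that subtract solute/solvent-excluded volume or correct for
ionic strength (SLTCAP and relatives) give smaller counts and are not
implemented; published setups using such conventions will legitimately
differ from the naive number.

## Regulon integration

All interval logic is BED-convention: 0-based, half-open, overlap means
≥ 1 shared base, so abutting intervals do not overlap. Replicate consensus
is the base-level AND of the two replicates' coverage, merged (book-ended
runs join) and sorted — semantically identical to a per-base bitmap, which
is exactly how the tests validate it.

Promoter windows are symmetric and strand-ignorant: [tss − flank,
tss + flank + 1), the `+1` making both boundary bases inclusive, clipped at
zero and at the chromosome end when sizes are provided. One TSS per gene is
assumed; transcript-level deduplication happens upstream. The default flank
is 5000 bp (TSS ± 5 kb).

Enrichment of a k-gene overlap between sets of sizes n_A, n_B in a universe
of N genes is the upper tail P(X ≥ k), X ~ Hypergeometric(N, n_A, n_B)
(scipy's stable survival function). Multiple-testing control is
Benjamini–Hochberg over an explicitly declared family of tests — the family
is an input, never guessed. Display percentages round half-away-from-zero
to integers; machine output always keeps full precision.

The candidate filter is the three-way intersection bound ∩
down-on-knockdown ∩ down-in-reference-regulon, and the report also carries
the intermediate bound ∩ down stage, since that promoter list is a result
of interest in its own right.

## Synthetic data

The generators are constructive, not sampled: whenever a count or fraction
is planted, the realized data reproduces it exactly, and each generator
re-verifies its output with an independent brute-force check
(`ConstructionError` on any mismatch). Randomness enters only through
rigid-body transforms of structures and identifier shuffles of gene
universes — transformations the measured quantities are invariant to — so
recovery tests are exact while fixtures still vary with the seed.

The DNA model is an idealized straight B-form duplex (rise 3.38 Å, twist
36°/bp, antiparallel strands phased 140° apart) with five atoms per
nucleotide: P, OP1, OP2, C1′, N1, the 5′ ends lacking the phosphate group.
Radii are chosen so consecutive intra-strand P–P distances land at ~7.0 Å,
the canonical backbone spacing. Contact probes for a residue planted with
count c are placed 3.5–3.9 Å radially outward from a dedicated phosphorus
(each probe within the 4 Å cutoff of exactly that atom; several probes for
one residue need distinct radii), and zero-count residues sit ≥ 8 Å from
every DNA atom. Scheduled trajectory frames place a single probe 3.5 Å
from a P, C1′ or N1 atom, or far from the duplex.

What the generator does **not** emulate: real protein geometry or sequence-
specific readout, bent or breathing DNA, noisy peak boundaries, overlapping
promoters or multi-TSS genes (synthetic TSSs sit 12 kb apart so ±5 kb
windows never collide), and mapping artifacts. Passing recovery tests
therefore demonstrates correctness of the counting, classification and
set/interval machinery on well-posed inputs — not robustness to the
messiness of real structural or sequencing data, which the optional
real-data paths are for.

The default `RegulonSpec` realizes the study-scale universe this package
targets: 20 000 genes, 957 consensus peaks, 7690 knockdown DEGs (3969
down), 1849/678 overlaps with a 6000/3000-gene reference regulon, 258
bound-and-down promoters, 7 candidates, and 919/900 mark-co-occupied peaks
(96%/94% of 957). The reference-regulon totals (6000/3000) are not printed
quantities anywhere; they are plausible DEG counts for a double-knockout
contrast chosen once to make the planted overlaps realizable.

## Verification problem sizes

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen to exercise each code path exhaustively while finishing in seconds:
100 randomized ≤ 200-atom complexes × 3 cutoffs against the all-pairs
oracle; 50 seeded 12–20-complex ensembles for ranking/nomination recovery;
100–500-frame scheduled trajectories; 1000 random free-energy draws; all
hypergeometric margins for N ≤ 20 (19 480 tails) against direct summation;
100 randomized interval universes against a base-resolution bitmap. The
regulon stage runs at full published scale (20 000 genes, 957 peaks) since
it is cheap.

## Known limitations

- The contact score treats all atom pairs equally; hydrogen-bond geometry,
  water-mediated contacts and buried-surface measures are out of scope.
- The simplified MM score is not an MM/PBSA implementation; only the
  bookkeeping identity is exact, and per-residue decompositions from full
  pipelines will differ in absolute value.
- Conservation ignores phylogeny and alignment uncertainty.
- The interval engine assumes consistent chromosome naming between inputs;
  a chromosome present in peaks but absent from windows is logged and
  skipped, not reconciled.
- Binary trajectory formats (DCD/XTC) are not read; convert to multi-model
  PDB upstream.
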