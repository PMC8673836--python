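# resnominate

Tools for nominating DNA-binding residues of multi-homeodomain transcription
factors from structural ensembles, and for integrating ChIP-seq binding with
knockdown expression data into a short candidate-gene list.

## The problem

Many transcription factors — the ZHX family of zinc-finger/homeodomain
proteins is the motivating case — have no experimentally solved DNA-bound
structure. A practical way to predict which residues anchor such a factor to
DNA is to thread its homeodomain (HD) sequences onto the many solved
DNA-bound HD complexes, count protein–DNA atomic contacts per residue across
that ensemble, and keep the top-contacted residues that are also
evolutionarily conserved. On the genomics side, deciding which target genes
make that binding functionally relevant requires a chain of interval and
set operations over ChIP-seq peaks, promoter windows and differential
expression lists.

`resnominate` implements both tracks as a tested, reusable library with a
CLI, plus a constructive synthetic-data generator so every stage can be
validated against planted ground truth without downloading anything.

## Methods at a glance

**Contact frequency.** For residue *i* of a protein in complex *c*, the
contact count n_i(c) is the number of (protein heavy atom, DNA heavy atom)
pairs within d ≤ 4.0 Å (inclusive). Over an ensemble of N complexes the
normalized contact frequency is

    mean_count(i) = (1/N) Σ_c n_i(c),      support(i) = |{c : n_i(c) ≥ 1}| / N

Residues are ranked by mean_count (ties: higher support, then lower residue
number); the default report keeps the top 4 per domain.

**Conservation.** Per MSA column, 1 − H/log₂20 where H is the Shannon
entropy of the amino-acid frequencies (gaps excluded). A residue is
*nominated* when it is in a domain's top-k by contact frequency **and** its
conservation score is ≥ τ (default 0.5).

**Trajectory analysis.** Over a multi-model-PDB trajectory, contact
persistence of a residue is the fraction of frames with ≥ 1 contact pair;
each frame's contacts are classified by DNA partner — phosphate backbone
(P, OP1/OP2/OP3, O5′, O3′), sugar (other primed atoms) or nucleobase — and
the per-frame dominant class gives a partner timeline. Free-energy
bookkeeping follows the end-state decomposition
ΔG_bind = ΔG_MM + ΔG_solv − TΔS with ΔG_MM = ΔG_elec + ΔG_VDW and
ΔG_solv = ΔG_polar + ΔG_nonpolar; solvation and entropy terms are accepted
as externally computed inputs, while a simplified screened-Coulomb +
Lennard-Jones score (ε(r) = 4r, 12 Å cutoff) ranks per-residue interaction
strength.

**Regulon integration.** BED-convention (0-based half-open) throughout:
base-level replicate peak consensus → promoter windows (TSS ± 5 kb,
boundary-inclusive) → promoter-bound genes (≥ 1 bp overlap) → histone-mark
co-occupancy fractions → DEG Venn overlaps with upper-tail hypergeometric
enrichment (Benjamini–Hochberg across a declared family) → the final
bound ∩ down-on-knockdown ∩ down-in-reference candidate filter.

## Worked example

Build a 12-complex synthetic ensemble with a planted contact gradient over
six residues of a C-terminal helix, aggregate it, and nominate:

```python
from resnominate.synthetic_data import EnsembleSpec, make_ensemble, make_msa
from resnominate.contact_profiling import profile_complex, aggregate_ensemble
from resnominate.structure_io import ResidueSelection
from resnominate.nomination import NominationConfig, nominate

spec = EnsembleSpec(
    n_complexes=12,
    counts={
        488: [1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0],
        489: [1] * 12,
        491: [8, 7, 8, 9, 8, 8, 7, 8, 9, 8, 8, 8],
        492: [3] * 12,
        495: [5, 5, 4, 5, 6, 5, 5, 4, 5, 6, 5, 5],
        497: [0] * 12,
    },
    seed=42,
)
models = make_ensemble(spec)
members = [("A", r) for r in spec.counts]
profiles = [profile_complex(m, ResidueSelection(m.id, members)) for m in models]
table = aggregate_ensemble(profiles)
print(table.to_frame().to_string(index=False))
```

```
 residue  mean_count  support rank
     488         0.5      0.5    5
     489         1.0      1.0    4
     491         8.0      1.0    1
     492         3.0      1.0    3
     495         5.0      1.0    2
     497         0.0      0.0 <NA>
```

Residue 491 contacts DNA in every complex and dominates the ranking, the
way the most-contacted arginine of a homeodomain recognition helix does.
Combining the top 4 with a conservation track (here generated with planted
per-column tiers; 491 and 495 conserved, 489 and 492 not):

```python
result = nominate(table, track, NominationConfig(top_k=4, conservation_threshold=0.5))
print(result.to_frame().to_string(index=False))
```

```
domain  residue  mean_count  support  conservation
            491         8.0      1.0      0.933734
            495         5.0      1.0      0.796088
```

Only the conserved members of the top 4 survive: the nominated DNA-binding
candidates. The same pipeline runs from the shell
(`resnominate simulate ensemble`, `resnominate contacts aggregate`,
`resnominate nominate`, `resnominate run --config pipeline.yaml`), and the
genomic track via `resnominate regulon consensus|bind|cooccupancy|venn|
enrich|filter`.

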