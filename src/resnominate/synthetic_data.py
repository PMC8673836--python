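"""Constructive synthetic inputs with known ground truth.

Every generator here *plants* the quantity the corresponding analysis stage
is supposed to recover — per-residue contact counts, per-frame partner
classes, column conservation tiers, gene-set overlap counts — and verifies
the realized geometry/combinatorics against the plan before returning, so
recovery tests are exact rather than statistical.  Randomness only enters
through rigid-body transforms and identifier shuffles, which the measured
quantities are invariant to.

The DNA model is an idealized straight B-form double helix (rise 3.38 A,
twist 36 deg/bp) with a reduced atom set per nucleotide: P, OP1, OP2
(phosphate), C1' (sugar) and N1 (base).  Contact analysis depends only on
atom names, elements and coordinates, so this reduced representation is
sufficient; physical realism beyond that is a non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import Msa
from .errors import ConstructionError, ValidationError
from .regulon_integration import GeneSet, GenomicInterval, write_bed
from .structure_io import Atom, Chain, ComplexStructure, Residue
from .trajectory_analysis import Trajectory

# Idealized B-DNA helix parameters (Angstrom / degrees).
RISE = 3.38
TWIST_DEG = 36.0
R_PHOSPHATE = 9.9
R_SUGAR = 7.0
R_BASE = 4.0
P_O_BOND = 1.48
STRAND2_PHASE_DEG = 140.0

CONTACT_CUTOFF = 4.0  # planted geometry targets this cutoff
FAR_DISTANCE = 9.0  # "no contact" placements sit at least this far from DNA

_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def _cyl(radius: float, theta_deg: float, z: float) -> np.ndarray:
    t = math.radians(theta_deg)
    return np.array([radius * math.cos(t), radius * math.sin(t), z])


def _frame_vectors(theta_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(radial, tangential, axial) unit vectors at helix angle theta."""
    t = math.radians(theta_deg)
    u = np.array([math.cos(t), math.sin(t), 0.0])
    tang = np.array([-math.sin(t), math.cos(t), 0.0])
    return u, tang, np.array([0.0, 0.0, 1.0])


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform-ish random rotation matrix and a translation vector."""
    # QR of a Gaussian matrix gives a rotation after sign fixing.
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.uniform(-20.0, 20.0, size=3)
    return q, shift


def _apply_rigid(structure: ComplexStructure, rot: np.ndarray, shift: np.ndarray) -> None:
    for res in structure.iter_residues():
        for atom in res.atoms:
            atom.coords = rot @ atom.coords + shift


def _nucleotide_atoms(theta_deg: float, z: float, with_phosphate: bool) -> list[Atom]:
    u, tang, _ = _frame_vectors(theta_deg)
    atoms = []
    if with_phosphate:
        p = _cyl(R_PHOSPHATE, theta_deg, z)
        # OP1/OP2 tilted slightly inward and tangentially so that probes placed
        # radially outward from P at 3.5-3.9 A stay > 4 A from them.
        op_dir1 = -0.3 * u + 0.954 * tang
        op_dir2 = -0.3 * u - 0.954 * tang
        atoms += [
            Atom("P", "P", p),
            Atom("OP1", "O", p + P_O_BOND * op_dir1),
            Atom("OP2", "O", p + P_O_BOND * op_dir2),
        ]
    atoms += [
        Atom("C1'", "C", _cyl(R_SUGAR, theta_deg, z)),
        Atom("N1", "N", _cyl(R_BASE, theta_deg, z)),
    ]
    return atoms


def _bdna_chains(n_bp: int) -> list[Chain]:
    """Strand chains of an idealized duplex in helix-axis coordinates."""
    if n_bp < 1:
        raise ValidationError(f"n_bp must be >= 1, got {n_bp}")
    bases = ["DA", "DT"]
    strand1 = []
    for i in range(n_bp):
        theta, z = i * TWIST_DEG, i * RISE
        strand1.append(
            Residue(
                chain_id="D",
                seq_number=i + 1,
                name=bases[i % 2],
                atoms=_nucleotide_atoms(theta, z, with_phosphate=i > 0),
            )
        )
    strand2 = []
    for j in range(n_bp):
        i = n_bp - 1 - j  # base-paired partner on strand 1
        theta, z = i * TWIST_DEG + STRAND2_PHASE_DEG, i * RISE
        strand2.append(
            Residue(
                chain_id="E",
                seq_number=j + 1,
                name=bases[(i + 1) % 2],
                atoms=_nucleotide_atoms(theta, z, with_phosphate=j > 0),
            )
        )
    return [Chain("D", "dna", strand1), Chain("E", "dna", strand2)]


def make_bdna(n_bp: int, seed: int = 0) -> ComplexStructure:
    """Idealized double-stranded B-DNA with a reduced atom set.

    Two antiparallel strands (chains D and E); nucleotide i of strand 1 sits
    at angle i*36 deg and height i*3.38 A, its partner on strand 2 at the
    same height with a 140 deg azimuthal offset.  The 5' nucleotide of each
    strand carries no phosphate group, so the atom count is 2*(5*n_bp - 3).
    The seed only sets a rigid-body placement of the whole duplex.
    """
    dna = ComplexStructure(
        id=f"bdna{n_bp}",
        chains=_bdna_chains(n_bp),
        provenance=f"idealized B-DNA, {n_bp} bp, seed {seed}",
    )
    _apply_rigid(dna, *_random_rigid(np.random.default_rng(seed)))
    return dna


def bdna_atom_count(n_bp: int) -> int:
    """Closed-form atom count of :func:`make_bdna` output."""
    return 2 * (5 * n_bp - 3)


@dataclass(frozen=True)
class EnsembleSpec:
    """Planted per-residue contact counts for each complex of an ensemble.

    ``counts`` maps a protein residue number to one contact count per
    complex; all lists must have length ``n_complexes``.
    """

    n_complexes: int
    counts: Mapping[int, Sequence[int]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 1:
            raise ValidationError("n_complexes must be >= 1")
        if not self.counts:
            raise ValidationError("EnsembleSpec needs at least one residue")
        for res, per_complex in self.counts.items():
            if len(per_complex) != self.n_complexes:
                raise ValidationError(
                    f"residue {res}: {len(per_complex)} counts for {self.n_complexes} complexes"
                )
            if any(c < 0 for c in per_complex):
                raise ValidationError(f"residue {res}: planted counts must be >= 0")


def _dna_coordinates(structure: ComplexStructure) -> np.ndarray:
    return np.array(
        [
            atom.coords
            for chain in structure.dna_chains
            for res in chain.residues
            for atom in res.atoms
        ]
    )


def _verify_planted_counts(
    complex_: ComplexStructure, planted: Mapping[int, int], complex_id: str
) -> None:
    """Brute-force distance check that realized counts equal the plan."""
    dna_xyz = _dna_coordinates(complex_)
    for chain in complex_.protein_chains:
        for res in chain.residues:
            xyz = np.array([a.coords for a in res.atoms])
            d = np.linalg.norm(xyz[:, None, :] - dna_xyz[None, :, :], axis=2)
            realized = int(np.sum(d <= CONTACT_CUTOFF))
            if realized != planted[res.seq_number]:
                raise ConstructionError(
                    f"{complex_id}: residue {res.seq_number} realized {realized} contacts, "
                    f"planted {planted[res.seq_number]}"
                )


def make_complex(
    counts: Mapping[int, int], seed: int = 0, complex_id: str = "synthetic"
) -> ComplexStructure:
    """One protein-DNA complex realizing exact planted contact counts.

    Each protein pseudo-residue is anchored to its own phosphate group along
    the duplex; a residue planted with count c gets c probe atoms placed
    3.5-3.9 A radially outward from that phosphorus (each within the 4 A
    cutoff of exactly that one DNA atom), and residues planted at zero sit
    >= 8 A from every DNA atom.  The realized structure is re-checked by an
    exhaustive distance scan and a ConstructionError raised on any mismatch.
    """
    if not counts:
        raise ValidationError("make_complex needs at least one residue")
    resnums = sorted(counts)
    n_bp = 2 * len(resnums) + 2
    dna_chains = _bdna_chains(n_bp)  # probes placed in helix coordinates, transform last

    protein_residues = []
    for idx, resnum in enumerate(resnums):
        host = 2 * idx + 1  # strand-1 nucleotide index (1-based residues skip the 5' end)
        theta = host * TWIST_DEG
        z = host * RISE
        u, _, _ = _frame_vectors(theta)
        p_pos = _cyl(R_PHOSPHATE, theta, z)
        c = int(counts[resnum])
        atoms = []
        if c == 0:
            atoms.append(Atom("C1", "C", p_pos + FAR_DISTANCE * u))
        else:
            for k in range(c):
                dist = 3.5 + 0.4 * k / c  # all probes in [3.5, 3.9)
                atoms.append(Atom(f"C{k + 1}", "C", p_pos + dist * u))
        protein_residues.append(
            Residue(chain_id="A", seq_number=resnum, name="ALA", atoms=atoms)
        )

    complex_ = ComplexStructure(
        id=complex_id,
        chains=[Chain("A", "protein", protein_residues)] + dna_chains,
        provenance=f"constructive synthetic complex, seed {seed}",
    )
    _apply_rigid(complex_, *_random_rigid(np.random.default_rng(seed)))
    _verify_planted_counts(complex_, dict(counts), complex_id)
    return complex_


def make_ensemble(spec: EnsembleSpec) -> list[ComplexStructure]:
    """One complex per ensemble member, each realizing its planted counts."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for j in range(spec.n_complexes):
        counts_j = {res: int(spec.counts[res][j]) for res in spec.counts}
        out.append(
            make_complex(counts_j, seed=int(rng.integers(2**31)), complex_id=f"model{j + 1:03d}")
        )
    return out


@dataclass(frozen=True)
class TrajectorySpec:
    """Per-frame partner-class schedule for named residues.

    ``schedule`` maps a residue number to a sequence over frames with values
    in {"phosphate", "sugar", "base", "none"} (or None for no contact).
    """

    schedule: Mapping[int, Sequence[str | None]]
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.schedule.values()}
        if not self.schedule or len(lengths) != 1:
            raise ValidationError("schedule must be non-empty with equal-length frame series")
        valid = {"phosphate", "sugar", "base", "none", None}
        for res, series in self.schedule.items():
            bad = set(series) - valid
            if bad:
                raise ValidationError(f"residue {res}: unknown partner classes {bad}")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.schedule.values())))


_CLASS_OF_ATOM = {"P": "phosphate", "OP1": "phosphate", "OP2": "phosphate",
                  "C1'": "sugar", "N1": "base"}


def make_trajectory(spec: TrajectorySpec) -> Trajectory:
    """A trajectory whose per-frame contacts follow the schedule exactly.

    In every frame each scheduled residue's single probe atom is placed
    3.5 A from one DNA atom of the scheduled class (P, C1' or N1 of its host
    nucleotide) and > 4 A from all others, or far from the duplex for "none"
    frames.  Frame-wise realization is verified by an exhaustive distance
    scan against a local atom-class table.
    """
    resnums = sorted(spec.schedule)
    n_bp = 2 * len(resnums) + 2
    rng = np.random.default_rng(spec.seed)
    frames = []
    for f in range(spec.n_frames):
        dna_chains = _bdna_chains(n_bp)
        protein_residues = []
        for idx, resnum in enumerate(resnums):
            host = 2 * idx + 1
            theta, z = host * TWIST_DEG, host * RISE
            u, _, zhat = _frame_vectors(theta)
            cls = spec.schedule[resnum][f] or "none"
            if cls == "phosphate":
                pos = _cyl(R_PHOSPHATE, theta, z) + 3.7 * u
            elif cls == "sugar":
                pos = _cyl(R_SUGAR, theta, z) - 3.5 * zhat
            elif cls == "base":
                pos = _cyl(R_BASE - 3.5, theta, z)
            else:
                pos = _cyl(R_PHOSPHATE + 12.0, theta, z)
            protein_residues.append(
                Residue(chain_id="A", seq_number=resnum, name="ALA",
                        atoms=[Atom("CB", "C", pos)])
            )
        frame = ComplexStructure(
            id=f"frame{f + 1:05d}",
            chains=[Chain("A", "protein", protein_residues)] + dna_chains,
        )
        _apply_rigid(frame, *_random_rigid(rng))
        _verify_schedule_frame(frame, {r: spec.schedule[r][f] for r in resnums}, f)
        frames.append(frame)
    return Trajectory(frames=frames)


def _verify_schedule_frame(
    frame: ComplexStructure, planned: Mapping[int, str | None], frame_idx: int
) -> None:
    dna_atoms = [
        (atom.name, atom.coords)
        for chain in frame.dna_chains
        for res in chain.residues
        for atom in res.atoms
    ]
    dna_xyz = np.array([c for _, c in dna_atoms])
    for chain in frame.protein_chains:
        for res in chain.residues:
            want = planned[res.seq_number] or "none"
            xyz = np.array([a.coords for a in res.atoms])
            d = np.linalg.norm(xyz[:, None, :] - dna_xyz[None, :, :], axis=2)
            hit = np.nonzero(d.min(axis=0) <= CONTACT_CUTOFF)[0]
            classes = {_CLASS_OF_ATOM[dna_atoms[j][0]] for j in hit}
            ok = (classes == set()) if want == "none" else (classes == {want})
            if not ok:
                raise ConstructionError(
                    f"frame {frame_idx}, residue {res.seq_number}: planned {want}, "
                    f"realized contact classes {sorted(classes)}"
                )


def _composition_score(counts: Sequence[int]) -> float:
    freqs = np.array([c for c in counts if c > 0], dtype=float)
    freqs /= freqs.sum()
    entropy = float(-np.sum(freqs * np.log2(freqs)))
    return float(max(0.0, 1.0 - entropy / math.log2(20)))


def make_msa(
    conservation: Sequence[float],
    n_seqs: int,
    seed: int = 0,
    query_id: str = "query",
) -> tuple[Msa, list[float]]:
    """An ungapped MSA whose columns approximate target conservation scores.

    For each target the best achievable column composition over ``n_seqs``
    rows is selected from single-letter, two-letter and k-equal-letter
    candidates; the realized scores (computed in closed form from the chosen
    compositions) are returned alongside, and are exact for the tiers 1.0
    (unanimous column) and, when ``n_seqs`` is a multiple of 20, 0.0.  The
    query is the first row and carries each column's dominant letter.
    """
    if n_seqs < 2:
        raise ValidationError("make_msa needs n_seqs >= 2")
    if any(not 0.0 <= t <= 1.0 for t in conservation):
        raise ValidationError("conservation targets must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    candidates: list[list[int]] = []
    for k in range(1, 21):  # k letters as equal as possible
        base, extra = divmod(n_seqs, k)
        if base == 0:
            break
        candidates.append([base + (1 if i < extra else 0) for i in range(k)])
    for a in range(max(1, n_seqs // 2), n_seqs):  # dominant letter + one minor
        candidates.append([a, n_seqs - a])

    columns: list[list[str]] = []
    realized: list[float] = []
    for target in conservation:
        best = min(candidates, key=lambda c: abs(_composition_score(c) - target))
        realized.append(_composition_score(best))
        offset = int(rng.integers(20))
        letters = [_AA_LETTERS[(offset + i) % 20] for i in range(len(best))]
        col: list[str] = []
        for letter, count in zip(letters, sorted(best, reverse=True)):
            col.extend(letter * count)
        columns.append(col[:n_seqs])

    rows = ["".join(columns[c][s] for c in range(len(columns))) for s in range(n_seqs)]
    ids = [query_id] + [f"seq{i:03d}" for i in range(1, n_seqs)]
    return Msa(ids=ids, rows=rows), realized


# ---------------------------------------------------------------------------
# Regulon universe


@dataclass(frozen=True)
class RegulonSpec:
    """Planted gene/peak universe emulating a factor-knockdown integration.

    Defaults mirror the study scale this package targets: a 957-peak factor
    with high active-mark co-occupancy, 7690 knockdown DEGs of which 3969
    are positively regulated, 1849/678 overlaps with the reference
    (double-knockout) regulon, 258 promoter-bound positively regulated genes
    and 7 final candidates.
    """

    n_genes: int = 20000
    n_peaks: int = 957
    n_bound_genes: int = 658
    n_bound_down: int = 258
    n_candidates: int = 7
    n_deg_kd: int = 7690
    n_down_kd: int = 3969
    n_deg_ref: int = 6000
    n_down_ref: int = 3000
    overlap_all: int = 1849
    overlap_down: int = 678
    cooccupied: Mapping[str, int] = field(
        default_factory=lambda: {"H3K4me3": 919, "H3K27ac": 900}
    )
    flank: int = 5000
    seed: int = 0

    def cells(self) -> dict[str, int]:
        """Disjoint gene-category sizes implied by the planted counts."""
        c = {
            "candidate": self.n_candidates,
            "bound_down_only": self.n_bound_down - self.n_candidates,
            "down_both_unbound": self.overlap_down - self.n_candidates,
            "down_kd_only": self.n_down_kd
            - self.n_bound_down
            - (self.overlap_down - self.n_candidates),
            "down_ref_only": self.n_down_ref - self.overlap_down,
            "up_kd_ref_other": self.overlap_all - self.overlap_down,
            "up_kd_only": (self.n_deg_kd - self.n_down_kd)
            - (self.overlap_all - self.overlap_down),
            "ref_other_only": (self.n_deg_ref - self.n_down_ref)
            - (self.overlap_all - self.overlap_down),
            "bound_only": self.n_bound_genes - self.n_bound_down,
        }
        return c

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.cells().items() if v < 0}
        if bad:
            raise ConstructionError(f"unrealizable overlap structure; negative cells: {bad}")
        if sum(self.cells().values()) > self.n_genes:
            raise ConstructionError("gene universe too small for the planted sets")
        if self.n_peaks < self.n_bound_genes:
            raise ConstructionError("need n_peaks >= n_bound_genes (one promoter peak per bound gene)")
        if any(c > self.n_peaks or c < 0 for c in self.cooccupied.values()):
            raise ConstructionError("co-occupied counts must lie in [0, n_peaks]")


@dataclass
class RegulonData:
    """Realized regulon universe: interval files plus labelled gene sets."""

    spec: RegulonSpec
    tss_table: pd.DataFrame
    peaks_rep1: list[GenomicInterval]
    peaks_rep2: list[GenomicInterval]
    marks: dict[str, list[GenomicInterval]]
    deg_kd_all: GeneSet
    deg_ref_all: GeneSet
    down_kd: GeneSet
    down_ref: GeneSet
    bound_genes: GeneSet
    candidates: GeneSet
    chrom_sizes: dict[str, int]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_bed(self.peaks_rep1, out / "peaks_rep1.bed")
        write_bed(self.peaks_rep2, out / "peaks_rep2.bed")
        for mark, ivs in self.marks.items():
            write_bed(ivs, out / f"marks_{mark}.bed")
        self.tss_table.to_csv(out / "tss.tsv", sep="\t", index=False)
        for gs in (self.deg_kd_all, self.deg_ref_all, self.down_kd, self.down_ref):
            pd.Series(sorted(gs.genes), name="gene").to_csv(
                out / f"genes_{gs.label}.tsv", sep="\t", index=False
            )


def make_regulon(spec: RegulonSpec = RegulonSpec()) -> RegulonData:
    """Realize a :class:`RegulonSpec` as TSS/peak/mark/gene-set data.

    Genes live on one chromosome with TSSs 12 kb apart, so +/-5 kb promoter
    windows never touch.  Every planted bound gene gets a promoter peak;
    remaining peaks go to intergenic gaps outside all windows.  Replicates
    are the same peaks padded 50 bp left (rep1) or right (rep2), so their
    base-level consensus is exactly the planted peak set.  Marks overlap the
    planted number of consensus peaks and nothing else.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    shuffled = list(rng.permutation(gene_ids))

    assignment: dict[str, list[str]] = {}
    cursor = 0
    for cell, size in spec.cells().items():
        assignment[cell] = shuffled[cursor : cursor + size]
        cursor += size

    def union(*cells: str) -> list[str]:
        out: list[str] = []
        for c in cells:
            out.extend(assignment[c])
        return out

    down_kd = GeneSet(
        "down_kd", union("candidate", "bound_down_only", "down_both_unbound", "down_kd_only")
    )
    down_ref = GeneSet("down_ref", union("candidate", "down_both_unbound", "down_ref_only"))
    deg_kd_all = GeneSet("deg_kd_all", sorted(down_kd.genes | set(union("up_kd_ref_other", "up_kd_only"))))
    deg_ref_all = GeneSet(
        "deg_ref_all", sorted(down_ref.genes | set(union("up_kd_ref_other", "ref_other_only")))
    )
    bound = GeneSet("bound", union("candidate", "bound_down_only", "bound_only"))
    candidates = GeneSet("candidates", assignment["candidate"])

    tss_of = {g: 20000 + i * 12000 for i, g in enumerate(gene_ids)}
    tss_table = pd.DataFrame(
        {"gene": gene_ids, "chrom": "chr1", "tss": [tss_of[g] for g in gene_ids], "strand": "+"}
    )
    chrom_sizes = {"chr1": 20000 + spec.n_genes * 12000 + 20000}

    peaks = [
        GenomicInterval("chr1", tss_of[g] - 100, tss_of[g] + 100, name=g)
        for g in sorted(bound.genes)
    ]
    n_extra = spec.n_peaks - len(peaks)
    # Intergenic gap [tss+5001, tss+7000) of gene i is outside every window.
    peaks += [
        GenomicInterval("chr1", tss_of[gene_ids[i]] + 5600, tss_of[gene_ids[i]] + 5800)
        for i in range(n_extra)
    ]
    peaks.sort()
    peaks_rep1 = [GenomicInterval(p.chrom, p.start - 50, p.end, p.name) for p in peaks]
    peaks_rep2 = [GenomicInterval(p.chrom, p.start, p.end + 50, p.name) for p in peaks]

    marks: dict[str, list[GenomicInterval]] = {}
    for mark, count in spec.cooccupied.items():
        chosen = rng.choice(len(peaks), size=count, replace=False)
        marks[mark] = sorted(
            GenomicInterval("chr1", peaks[i].start - 10, peaks[i].start + 10) for i in chosen
        )

    data = RegulonData(
        spec=spec,
        tss_table=tss_table,
        peaks_rep1=peaks_rep1,
        peaks_rep2=peaks_rep2,
        marks=marks,
        deg_kd_all=deg_kd_all,
        deg_ref_all=deg_ref_all,
        down_kd=down_kd,
        down_ref=down_ref,
        bound_genes=bound,
        candidates=candidates,
        chrom_sizes=chrom_sizes,
    )
    _verify_regulon(data)
    return data


def _verify_regulon(data: RegulonData) -> None:
    """Re-check the planted counts by direct set arithmetic."""
    spec = data.spec
    checks = {
        "deg_kd": (len(data.deg_kd_all), spec.n_deg_kd),
        "deg_ref": (len(data.deg_ref_all), spec.n_deg_ref),
        "down_kd": (len(data.down_kd), spec.n_down_kd),
        "down_ref": (len(data.down_ref), spec.n_down_ref),
        "overlap_all": (len(data.deg_kd_all.genes & data.deg_ref_all.genes), spec.overlap_all),
        "overlap_down": (len(data.down_kd.genes & data.down_ref.genes), spec.overlap_down),
        "bound": (len(data.bound_genes), spec.n_bound_genes),
        "bound_down": (len(data.bound_genes.genes & data.down_kd.genes), spec.n_bound_down),
        "candidates": (
            len(data.bound_genes.genes & data.down_kd.genes & data.down_ref.genes),
            spec.n_candidates,
        ),
        "peaks": (len(data.peaks_rep1), spec.n_peaks),
    }
    bad = {k: v for k, v in checks.items() if v[0] != v[1]}
    if bad:
        raise ConstructionError(f"realized regulon deviates from spec: {bad}")
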