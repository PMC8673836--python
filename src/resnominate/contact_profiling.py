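"""Per-residue atomic protein-DNA contact counting and ensemble aggregation.

A contact is a (protein atom, DNA atom) pair within a distance cutoff
(default 4.0 A, boundary inclusive, heavy atoms only).  Counts from an
ensemble of complexes are averaged into a normalized contact frequency
(``mean_count``) with a companion ``support`` column (fraction of complexes
in which the residue touches DNA at all); ranking by mean_count with support
as tie-breaker drives downstream residue nomination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import MappingError, ValidationError
from .structure_io import (
    Atom,
    ComplexStructure,
    Residue,
    ResidueKey,
    ResidueSelection,
    normalize_key,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactParams:
    """Distance cutoff in Angstrom (inclusive boundary) and hydrogen policy."""

    cutoff: float = 4.0
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValidationError(f"cutoff must be > 0, got {self.cutoff}")


@dataclass
class ContactPair:
    protein_atom: str
    dna_atom: str
    dna_residue: ResidueKey
    distance: float


@dataclass
class ContactRecord:
    residue_key: ResidueKey
    pairs: list[ContactPair]

    @property
    def count(self) -> int:
        return len(self.pairs)


@dataclass
class ResidueContactProfile:
    """Contact counts of one complex over a residue selection (zeros kept)."""

    structure_id: str
    counts: dict[ResidueKey, int]


@dataclass
class EnsembleContactTable:
    """Normalized contact frequencies over an ensemble of complexes.

    ``mean_count`` is the per-residue atomic contact count summed over the
    ensemble and divided by the number of complexes; ``support`` is the
    fraction of complexes in which the residue makes at least one contact.
    """

    n_complexes: int
    mean_count: dict[int, float]
    support: dict[int, float]

    def __post_init__(self) -> None:
        if self.n_complexes < 1:
            raise ValidationError("ensemble table needs n_complexes >= 1")
        for res, mc in self.mean_count.items():
            sup = self.support[res]
            if mc < 0 or not (0.0 <= sup <= 1.0):
                raise ValidationError(f"residue {res}: invalid mean_count/support")
            if (mc == 0) != (sup == 0):
                raise ValidationError(f"residue {res}: mean_count=0 must coincide with support=0")

    @property
    def residues(self) -> list[int]:
        return sorted(self.mean_count)

    def to_frame(self) -> pd.DataFrame:
        ranked = rank_residues(self, k=len(self.mean_count) or 1)
        rank_of = {res: i + 1 for i, (res, _, _) in enumerate(ranked)}
        rows = [
            {
                "residue": res,
                "mean_count": self.mean_count[res],
                "support": self.support[res],
                "rank": rank_of.get(res, pd.NA),
            }
            for res in self.residues
        ]
        return pd.DataFrame(rows)


def _residue_atoms(res: Residue, params: ContactParams) -> list[Atom]:
    return list(res.atoms) if params.include_hydrogens else res.heavy_atoms()


def _dna_atom_arrays(complex: ComplexStructure, params: ContactParams):
    names, keys, coords = [], [], []
    for chain in complex.dna_chains:
        for res in chain.residues:
            for atom in _residue_atoms(res, params):
                names.append(atom.name)
                keys.append(res.key)
                coords.append(atom.coords)
    return names, keys, np.asarray(coords, dtype=float).reshape(-1, 3)


def atomic_contacts(
    complex: ComplexStructure,
    residue_key: Sequence,
    params: ContactParams = ContactParams(),
) -> ContactRecord:
    """List every (protein atom, DNA atom) pair within the cutoff.

    The residue must belong to a protein chain and the complex must contain a
    DNA chain.  Distances are Euclidean; the boundary is inclusive
    (d <= cutoff counts).
    """
    complex.require_complex()
    key = normalize_key(residue_key)
    residue = complex.get_residue(key)
    protein_keys = {r.key for ch in complex.protein_chains for r in ch.residues}
    if key not in protein_keys:
        raise KeyError(f"residue {key} is not part of a protein chain in {complex.id}")

    prot_atoms = _residue_atoms(residue, params)
    dna_names, dna_keys, dna_coords = _dna_atom_arrays(complex, params)
    if not prot_atoms or dna_coords.size == 0:
        return ContactRecord(residue_key=key, pairs=[])

    p_coords = np.asarray([a.coords for a in prot_atoms])
    dists = cdist(p_coords, dna_coords)
    pairs = []
    for i, j in zip(*np.nonzero(dists <= params.cutoff)):
        pairs.append(
            ContactPair(
                protein_atom=prot_atoms[i].name,
                dna_atom=dna_names[j],
                dna_residue=dna_keys[j],
                distance=float(dists[i, j]),
            )
        )
    return ContactRecord(residue_key=key, pairs=pairs)


def profile_complex(
    complex: ComplexStructure,
    selection: ResidueSelection,
    params: ContactParams = ContactParams(),
) -> ResidueContactProfile:
    """Contact counts for every residue of a selection (zeros included)."""
    residues = selection.resolve(complex)
    counts = {
        res.key: atomic_contacts(complex, res.key, params).count for res in residues
    }
    return ResidueContactProfile(structure_id=complex.id, counts=counts)


def aggregate_ensemble(
    profiles: Sequence[ResidueContactProfile],
    residue_map: Sequence[Mapping[ResidueKey, int]] | None = None,
) -> EnsembleContactTable:
    """Aggregate per-complex profiles into mean contact counts and support.

    ``residue_map`` (one mapping per profile) sends each profile's residue
    keys onto a shared query numbering; by default the author residue number
    is used (identity map), as homology models of one query share numbering.
    Residues absent from a profile contribute a zero count for that complex.
    """
    if not profiles:
        raise ValidationError("aggregate_ensemble: need at least one profile")
    if residue_map is not None and len(residue_map) != len(profiles):
        raise ValidationError("residue_map must have one entry per profile")

    n = len(profiles)
    totals: dict[int, float] = {}
    hits: dict[int, int] = {}
    for idx, prof in enumerate(profiles):
        for key, count in prof.counts.items():
            if residue_map is not None:
                try:
                    query_num = residue_map[idx][key]
                except KeyError:
                    raise MappingError(
                        f"profile {prof.structure_id!r}: residue key {key} missing from residue map"
                    ) from None
            else:
                query_num = key[1]
            totals[query_num] = totals.get(query_num, 0.0) + count
            hits[query_num] = hits.get(query_num, 0) + (1 if count >= 1 else 0)
    mean_count = {res: total / n for res, total in totals.items()}
    support = {res: hits[res] / n for res in totals}
    return EnsembleContactTable(n_complexes=n, mean_count=mean_count, support=support)


def rank_residues(table: EnsembleContactTable, k: int = 4) -> list[tuple[int, float, float]]:
    """Top-k residues by mean contact count.

    Descending mean_count; ties broken by higher support, then by lower
    residue number.  Residues with zero mean count never appear, so the
    result may be shorter than ``k``.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if not table.mean_count:
        raise ValidationError("rank_residues: empty table")
    entries = [
        (res, table.mean_count[res], table.support[res])
        for res in table.mean_count
        if table.mean_count[res] > 0
    ]
    entries.sort(key=lambda e: (-e[1], -e[2], e[0]))
    return entries[:k]


#: DNA backbone phosphate-group atom labels (PDB v3 plus legacy O1P-style).
PHOSPHATE_ATOMS = frozenset(["P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'", "O3'"])

_warned_names: set[str] = set()


def classify_partner(dna_atom_name: str) -> str:
    """Classify a DNA atom label as ``phosphate``, ``sugar`` or ``base``.

    Phosphate covers the phosphate group plus its bridging oxygens; the
    remaining primed names belong to the deoxyribose sugar; everything else
    (ring and exocyclic atoms) is nucleobase.  Unknown unprimed labels fall
    through to ``base`` with a logged warning.
    """
    name = dna_atom_name.strip().upper().replace("*", "'")
    if not name:
        raise ValidationError("classify_partner: empty atom name")
    if name in PHOSPHATE_ATOMS:
        return "phosphate"
    if "'" in name:
        return "sugar"
    known_base_prefix = name[0] in "NCOH"
    if not known_base_prefix and name not in _warned_names:
        _warned_names.add(name)
        logger.warning("unrecognized DNA atom label %r classified as base", dna_atom_name)
    return "base"
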