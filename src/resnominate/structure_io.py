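"""Read protein-DNA complex structures into a uniform atomic model.

Structures are reduced to a light-weight chain/residue/atom hierarchy with
chain roles (``protein`` / ``dna`` / ``other``) assigned from residue-name
composition.  Multi-model files (NMR ensembles, trajectory dumps) keep one
model per :class:`ComplexStructure`; the default is the first model, matching
the common convention for NMR templates.  Coordinates are in Angstrom
throughout; no unit conversion happens anywhere downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import FormatError, RoleError, ValidationError

logger = logging.getLogger(__name__)

#: Standard 3-letter amino-acid codes.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Standard deoxyribonucleotide codes, including 5'/3' terminal variants used
#: by MD packages.
STANDARD_DNA = frozenset(
    [
        "DA", "DT", "DG", "DC", "DU", "DI",
        "DA5", "DT5", "DG5", "DC5", "DU5",
        "DA3", "DT3", "DG3", "DC3", "DU3",
    ]
)

ResidueKey = tuple[str, int, str]  # (chain_id, seq_number, insertion_code)


@dataclass
class Atom:
    """One atom: label, element, Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValidationError(f"atom {self.name!r}: element must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom]
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError(
                f"residue {self.name} {self.chain_id}{self.seq_number}: at least one atom required"
            )

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    role: str  # protein | dna | other
    residues: list[Residue]


@dataclass
class ComplexStructure:
    """One protein-DNA complex: chains with roles, from one model of a file."""

    id: str
    chains: list[Chain]
    model_index: int = 1
    provenance: str = ""
    _index: dict[ResidueKey, Residue] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._index = {}
        for ch in self.chains:
            for res in ch.residues:
                if res.key in self._index:
                    raise ValidationError(f"duplicate residue key {res.key} in structure {self.id}")
                self._index[res.key] = res

    def chains_with_role(self, role: str) -> list[Chain]:
        return [c for c in self.chains if c.role == role]

    @property
    def protein_chains(self) -> list[Chain]:
        return self.chains_with_role("protein")

    @property
    def dna_chains(self) -> list[Chain]:
        return self.chains_with_role("dna")

    def get_residue(self, key: ResidueKey | tuple[str, int]) -> Residue:
        key = normalize_key(key)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"residue {key} not found in structure {self.id}") from None

    def iter_residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def require_complex(self) -> None:
        """Raise unless the structure has >=1 protein and >=1 DNA chain."""
        if not self.protein_chains or not self.dna_chains:
            roles = sorted({c.role for c in self.chains})
            raise RoleError(
                f"structure {self.id}: contact analysis needs >=1 protein and >=1 dna chain "
                f"(found roles: {roles})"
            )


@dataclass
class ResidueSelection:
    """A set of protein residues of one structure, e.g. a C-terminal helix."""

    structure_id: str
    members: list[tuple[str, int]]

    def resolve(self, structure: ComplexStructure) -> list[Residue]:
        protein_keys = {
            r.key for ch in structure.protein_chains for r in ch.residues
        }
        out = []
        for chain_id, num in self.members:
            key = (chain_id, num, "")
            if key not in protein_keys:
                raise ValidationError(
                    f"selection member {key} does not resolve to a protein residue of {structure.id}"
                )
            out.append(structure.get_residue(key))
        return out


def normalize_key(key: Sequence) -> ResidueKey:
    """Accept (chain, num) or (chain, num, icode); return the canonical triple."""
    if len(key) == 2:
        return (str(key[0]), int(key[1]), "")
    if len(key) == 3:
        return (str(key[0]), int(key[1]), str(key[2]))
    raise ValidationError(f"residue key must have 2 or 3 fields, got {key!r}")


def classify_chain(residue_names: Sequence[str]) -> str:
    """Classify a chain as protein/dna/other from residue-name composition.

    A chain is ``dna`` if >=90% of its residues are standard
    deoxyribonucleotides, ``protein`` if >=90% are standard amino acids,
    ``other`` otherwise (waters, ions, modified residues).
    """
    if not residue_names:
        raise ValidationError("classify_chain: empty residue list")
    names = [n.strip().upper() for n in residue_names]
    n = len(names)
    frac_dna = sum(nm in STANDARD_DNA for nm in names) / n
    frac_aa = sum(nm in STANDARD_AA for nm in names) / n
    if frac_dna >= 0.9:
        return "dna"
    if frac_aa >= 0.9:
        return "protein"
    return "other"


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom label: highest occupancy, ties -> altloc 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for name, group in by_name.items():
        if len(group) > 1:
            group = sorted(group, key=lambda a: (-a.occ, a.altloc if a.altloc != "\0" else "A"))
        kept.append(group[0])
    return kept


_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}


def read_structure(
    path: str | Path,
    format: str = "auto",
    model_choice: int = 1,
    structure_id: str | None = None,
) -> ComplexStructure:
    """Read one model of a PDB/mmCIF file into a :class:`ComplexStructure`.

    Parameters
    ----------
    path : file to read.
    format : ``pdb``, ``mmcif`` or ``auto`` (detect from contents/extension).
    model_choice : 1-based model index for multi-model files (default: first).

    Altloc groups are resolved to a single conformer (highest occupancy, ties
    broken toward altloc "A").  Hydrogens are retained but flagged.  Chain
    roles come from :func:`classify_chain`; nonstandard residues are kept and
    logged, never dropped.
    """
    path = Path(path)
    if format not in ("auto", *_FORMATS):
        raise ValidationError(f"unknown structure format {format!r}")
    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc

    n_models = len(st)
    if n_models == 0:
        raise FormatError(f"{path}: no coordinate models found")
    if not (1 <= model_choice <= n_models):
        raise ValidationError(
            f"{path}: model_choice {model_choice} out of range (file has {n_models} model(s))"
        )
    model = st[model_choice - 1]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = []
            for ga in _resolve_altlocs(gres):
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name or "X",
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        is_hydrogen=ga.is_hydrogen(),
                    )
                )
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_number=gres.seqid.num,
                    name=gres.name,
                    atoms=atoms,
                    insertion_code=icode,
                )
            )
        if not residues:
            continue
        role = classify_chain([r.name for r in residues])
        if role == "other":  # keep, but leave a trace for the user
            nonstd = sorted(
                {r.name for r in residues if r.name not in STANDARD_AA | STANDARD_DNA}
            )
            logger.info("chain %s classified as 'other' (residues: %s)", gchain.name, nonstd[:8])
        chains.append(Chain(chain_id=gchain.name, role=role, residues=residues))

    if not chains:
        raise FormatError(f"{path}: no atom records parsed; not a valid coordinate file")
    return ComplexStructure(
        id=structure_id or path.stem,
        chains=chains,
        model_index=model_choice,
        provenance=f"read from {path.name} (model {model_choice} of {n_models})",
    )


def count_models(path: str | Path, format: str = "auto") -> int:
    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return len(st)


def _pdb_atom_name(name: str) -> str:
    # Names shorter than 4 characters start in column 14 per PDB convention.
    return name.ljust(4) if len(name) >= 4 else (" " + name).ljust(4)


def _format_atom_record(serial: int, atom: Atom, res: Residue) -> str:
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:>5} {_pdb_atom_name(atom.name)} {res.name:<3} "
        f"{res.chain_id[:1]:>1}{res.seq_number:>4}{(res.insertion_code or ' ')[:1]}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element.upper():>2}"
    )


def _model_lines(structure: ComplexStructure, serial_start: int = 1) -> list[str]:
    lines = []
    serial = serial_start
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(_format_atom_record(serial, atom, res))
                serial = min(serial + 1, 99999)
        lines.append("TER")
    return lines


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write a single-model PDB file (ATOM/TER/END records only)."""
    lines = _model_lines(structure) + ["END", ""]
    Path(path).write_text("\n".join(lines))


def write_trajectory_pdb(frames: Sequence[ComplexStructure], path: str | Path) -> None:
    """Write frames as a multi-model PDB file (MODEL/ENDMDL blocks)."""
    if not frames:
        raise ValidationError("write_trajectory_pdb: no frames")
    lines: list[str] = []
    for i, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {i:>4}")
        lines.extend(_model_lines(frame))
        lines.append("ENDMDL")
    lines += ["END", ""]
    Path(path).write_text("\n".join(lines))


def inspect_structure(structure: ComplexStructure) -> pd.DataFrame:
    """Chain-level summary (role, residue range, atom count) as a table."""
    rows = []
    for ch in structure.chains:
        nums = [r.seq_number for r in ch.residues]
        rows.append(
            {
                "chain_id": ch.chain_id,
                "role": ch.role,
                "n_residues": len(ch.residues),
                "first_residue": min(nums),
                "last_residue": max(nums),
                "n_atoms": sum(len(r.atoms) for r in ch.residues),
            }
        )
    return pd.DataFrame(rows)
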