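"""MD-trajectory post-processing and free-energy bookkeeping.

Works on trajectories stored as multi-model PDB files (every frame shares a
topology).  Provides per-residue contact persistence and partner-class
timelines at the contact cutoff, a simplified per-residue molecular-mechanics
interaction energy (screened Coulomb with distance-dependent dielectric plus
Lennard-Jones), exact end-state free-energy bookkeeping

    dG_bind = dG_MM + dG_solv - TdS,   dG_MM = dG_elec + dG_vdw,
    dG_solv = dG_polar + dG_nonpolar,

and the ion arithmetic used when setting up a solvated box.  Solvation and
entropy terms are accepted as externally supplied values; running MD itself
is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .contact_profiling import ContactParams, atomic_contacts, classify_partner
from .errors import ParameterError, TrajectoryError, ValidationError
from .structure_io import ComplexStructure, count_models, normalize_key, read_structure

#: Coulomb constant in kcal*A/(mol*e^2).
COULOMB_K = 332.0637
#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23
#: Cubic Angstrom in liters.
A3_TO_LITER = 1e-27

PARTNER_CLASSES = ("phosphate", "sugar", "base")


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, plus optional frame spacing."""

    frames: list[ComplexStructure]
    time_per_frame_ps: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("trajectory needs at least one frame")
        ref = self._topology_signature(self.frames[0])
        for i, frame in enumerate(self.frames[1:], start=2):
            if self._topology_signature(frame) != ref:
                raise TrajectoryError(
                    f"frame {i} does not share the topology of frame 1 "
                    f"(atom count/order or residue identity differ)"
                )

    @staticmethod
    def _topology_signature(frame: ComplexStructure):
        return tuple(
            (res.chain_id, res.seq_number, res.name, atom.name)
            for res in frame.iter_residues()
            for atom in res.atoms
        )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def read_trajectory(path: str | Path, time_per_frame_ps: float | None = None) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (model i -> frame i)."""
    n = count_models(path)
    frames = [
        read_structure(path, format="pdb", model_choice=i, structure_id=f"frame{i:05d}")
        for i in range(1, n + 1)
    ]
    return Trajectory(frames=frames, time_per_frame_ps=time_per_frame_ps)


@dataclass
class PersistenceResult:
    """Fraction of frames in which a residue contacts DNA."""

    residue_key: tuple
    flags: list[bool]

    @property
    def n_frames(self) -> int:
        return len(self.flags)

    @property
    def n_contact_frames(self) -> int:
        return sum(self.flags)

    @property
    def persistence(self) -> float:
        return self.n_contact_frames / self.n_frames


@dataclass
class PartnerTimeline:
    """Per-frame dominant DNA partner class and per-class contact counts."""

    residue_key: tuple
    dominant: list[str]  # phosphate | sugar | base | none
    class_counts: list[dict[str, int]]

    def switches(self) -> list[tuple[int, str, str]]:
        """(frame index, previous class, new class) for each change point."""
        out = []
        for i in range(1, len(self.dominant)):
            if self.dominant[i] != self.dominant[i - 1]:
                out.append((i, self.dominant[i - 1], self.dominant[i]))
        return out


def contact_persistence(
    traj: Trajectory,
    residue_key: Sequence,
    params: ContactParams = ContactParams(),
) -> PersistenceResult:
    """A frame counts as contact iff the residue has >= 1 atom pair within cutoff."""
    key = normalize_key(residue_key)
    flags = [atomic_contacts(frame, key, params).count >= 1 for frame in traj.frames]
    return PersistenceResult(residue_key=key, flags=flags)


def partner_timeline(
    traj: Trajectory,
    residue_key: Sequence,
    params: ContactParams = ContactParams(),
) -> PartnerTimeline:
    """Classify each frame's contacts by DNA partner class.

    The dominant class is the argmax of per-class pair counts; ties resolve
    in the order phosphate > sugar > base.  Frames without any contact are
    labelled ``none``.
    """
    key = normalize_key(residue_key)
    dominant: list[str] = []
    counts_series: list[dict[str, int]] = []
    for frame in traj.frames:
        record = atomic_contacts(frame, key, params)
        counts = {cls: 0 for cls in PARTNER_CLASSES}
        for pair in record.pairs:
            counts[classify_partner(pair.dna_atom)] += 1
        counts_series.append(counts)
        if record.count == 0:
            dominant.append("none")
        else:
            dominant.append(max(PARTNER_CLASSES, key=lambda c: (counts[c], -PARTNER_CLASSES.index(c))))
    return PartnerTimeline(residue_key=key, dominant=dominant, class_counts=counts_series)


# ---------------------------------------------------------------------------
# Simplified molecular-mechanics interaction energies

AtomParams = Mapping[tuple[str, str], tuple[float, float, float]]  # (res, atom) -> (q, sigma, eps)


def load_param_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Read a TSV parameter table: residue, atom, charge(e), sigma(A), epsilon(kcal/mol)."""
    df = pd.read_csv(path, sep="\t")
    required = {"residue", "atom", "charge", "sigma", "epsilon"}
    if not required.issubset(df.columns):
        raise ValidationError(f"parameter table must have columns {sorted(required)}")
    return {
        (str(r.residue), str(r.atom)): (float(r.charge), float(r.sigma), float(r.epsilon))
        for r in df.itertuples()
    }


def _lookup(params: AtomParams, res_name: str, atom_name: str):
    for key in ((res_name, atom_name), ("*", atom_name)):
        if key in params:
            return params[key]
    raise ParameterError(f"no charge/LJ parameters for atom {atom_name!r} of residue {res_name!r}")


def residue_mm_energy(
    frame: ComplexStructure,
    residue_key: Sequence,
    param_table: AtomParams,
    energy_cutoff: float = 12.0,
) -> tuple[float, float]:
    """(dG_elec, dG_vdw) in kcal/mol between one residue and all DNA atoms.

    Electrostatics use a screened Coulomb term with distance-dependent
    dielectric eps(r) = 4r, i.e. k*q_i*q_j / (4 r^2); dispersion is 12-6
    Lennard-Jones with Lorentz-Berthelot combining.  Heavy-atom pairs within
    ``energy_cutoff`` Angstrom contribute.  This is a ranking-style score for
    per-residue contact energies, not a full MM/PBSA decomposition.
    """
    frame.require_complex()
    key = normalize_key(residue_key)
    residue = frame.get_residue(key)

    prot = [(residue.name, a) for a in residue.heavy_atoms()]
    dna = [
        (res.name, a)
        for chain in frame.dna_chains
        for res in chain.residues
        for a in res.heavy_atoms()
    ]
    if not prot or not dna:
        return 0.0, 0.0

    p_par = np.array([_lookup(param_table, rn, a.name) for rn, a in prot])
    d_par = np.array([_lookup(param_table, rn, a.name) for rn, a in dna])
    p_xyz = np.array([a.coords for _, a in prot])
    d_xyz = np.array([a.coords for _, a in dna])

    r = cdist(p_xyz, d_xyz)
    mask = r <= energy_cutoff
    if not mask.any():
        return 0.0, 0.0
    rr = r[mask]

    qq = np.outer(p_par[:, 0], d_par[:, 0])[mask]
    elec = float(np.sum(COULOMB_K * qq / (4.0 * rr**2)))

    sigma = (p_par[:, 1][:, None] + d_par[:, 1][None, :])[mask] / 2.0
    eps = np.sqrt(np.outer(p_par[:, 2], d_par[:, 2]))[mask]
    sr6 = (sigma / rr) ** 6
    vdw = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    return elec, vdw


# ---------------------------------------------------------------------------
# Free-energy bookkeeping


@dataclass(frozen=True)
class EnergyDecomposition:
    """End-state free-energy terms in kcal/mol.

    The combined quantities are derived properties, so the identities
    dG_MM = dG_elec + dG_vdw, dG_solv = dG_polar + dG_nonpolar and
    dG_bind = dG_MM + dG_solv - TdS hold exactly by construction.
    """

    dG_elec: float
    dG_vdw: float
    dG_polar: float = 0.0
    dG_nonpolar: float = 0.0
    TdS: float = 0.0

    @property
    def dG_MM(self) -> float:
        return self.dG_elec + self.dG_vdw

    @property
    def dG_solv(self) -> float:
        return self.dG_polar + self.dG_nonpolar

    @property
    def dG_bind(self) -> float:
        return combine_free_energy(self.dG_MM, self.dG_solv, self.TdS)

    def as_dict(self) -> dict[str, float]:
        return {
            "dG_elec": self.dG_elec,
            "dG_vdw": self.dG_vdw,
            "dG_MM": self.dG_MM,
            "dG_polar": self.dG_polar,
            "dG_nonpolar": self.dG_nonpolar,
            "dG_solv": self.dG_solv,
            "TdS": self.TdS,
            "dG_bind": self.dG_bind,
        }


def combine_free_energy(dG_MM: float, dG_solv: float, TdS: float) -> float:
    """Binding free energy: dG_bind = dG_MM + dG_solv - TdS (kcal/mol)."""
    return dG_MM + dG_solv - TdS


# ---------------------------------------------------------------------------
# System-setup ion arithmetic


@dataclass(frozen=True)
class SystemSetupSpec:
    """Solvated-box bookkeeping for an MD system (engine settings are provenance)."""

    box_edge: float = 78.0  # Angstrom, cubic box
    salt_concentration: float = 0.1  # mol/L
    temperature: float = 310.0  # K
    solute_net_charge: int = 0  # elementary charges
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.box_edge > 0:
            raise ValidationError("box_edge must be > 0")
        if self.salt_concentration < 0:
            raise ValidationError("salt_concentration must be >= 0")


def neutralizing_ions(solute_net_charge: int) -> tuple[str, int]:
    """Counter-ion species and count that neutralize the solute charge."""
    q = int(solute_net_charge)
    if q < 0:
        return ("Na+", -q)
    if q > 0:
        return ("Cl-", q)
    return ("none", 0)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def salt_ion_pairs(spec: SystemSetupSpec) -> int:
    """Na+/Cl- pair count for a target salt concentration in a cubic box.

    Naive convention: n = round(c * N_A * V_box) with V_box = edge^3 converted
    to liters and rounding half-away-from-zero.  Conventions that subtract
    solute volume or correct for ionic strength (e.g. SLTCAP) are not
    implemented.
    """
    volume_liters = spec.box_edge**3 * A3_TO_LITER
    return _round_half_away(spec.salt_concentration * N_AVOGADRO * volume_liters)
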