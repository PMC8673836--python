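import math

import numpy as np
import pytest

from resnominate.contact_profiling import ContactParams
from resnominate.errors import ParameterError, TrajectoryError, ValidationError
from resnominate.structure_io import Atom, Chain, ComplexStructure, Residue
from resnominate.synthetic_data import TrajectorySpec, make_trajectory
from resnominate.trajectory_analysis import (
    COULOMB_K,
    EnergyDecomposition,
    SystemSetupSpec,
    Trajectory,
    combine_free_energy,
    contact_persistence,
    neutralizing_ions,
    partner_timeline,
    read_trajectory,
    residue_mm_energy,
    salt_ion_pairs,
)


def simple_frame(p_dist, base_dist=50.0, frame_id="f"):
    """One CB probe near a phosphate P and (optionally) a base N1."""
    protein = [Residue("A", 5, "ALA", [Atom("CB", "C", [0.0, 0.0, 0.0])])]
    dna = [
        Residue(
            "D", 1, "DA",
            [Atom("P", "P", [p_dist, 0.0, 0.0]), Atom("N1", "N", [0.0, base_dist, 0.0])],
        )
    ]
    return ComplexStructure(
        id=frame_id, chains=[Chain("A", "protein", protein), Chain("D", "dna", dna)]
    )


class TestPersistence:
    def test_always_in_contact(self):
        traj = Trajectory(frames=[simple_frame(3.0) for _ in range(10)])
        assert contact_persistence(traj, ("A", 5)).persistence == 1.0

    def test_scheduled_fraction_recovered_exactly(self):
        schedule = (["phosphate"] * 50 + ["none"] * 50)
        traj = make_trajectory(TrajectorySpec(schedule={5: schedule}, seed=3))
        result = contact_persistence(traj, ("A", 5))
        assert result.persistence == 0.5
        assert result.flags == [True] * 50 + [False] * 50

    def test_random_schedule_matches_per_frame_scan(self, rng):
        flags = rng.random(40) < 0.6
        schedule = ["sugar" if f else "none" for f in flags]
        traj = make_trajectory(TrajectorySpec(schedule={5: schedule}, seed=9))
        result = contact_persistence(traj, ("A", 5))
        assert result.flags == list(flags)
        assert result.persistence == flags.mean()

    def test_reversal_preserves_persistence_reverses_timeline(self):
        schedule = ["base"] * 3 + ["phosphate"] * 7
        traj = make_trajectory(TrajectorySpec(schedule={5: schedule}, seed=1))
        rev = Trajectory(frames=traj.frames[::-1])
        assert contact_persistence(rev, ("A", 5)).persistence == contact_persistence(
            traj, ("A", 5)
        ).persistence
        assert partner_timeline(rev, ("A", 5)).dominant == partner_timeline(
            traj, ("A", 5)
        ).dominant[::-1]


class TestTimeline:
    def test_scheduled_switch_at_planted_frame(self):
        schedule = ["base"] * 10 + ["phosphate"] * 20
        traj = make_trajectory(TrajectorySpec(schedule={5: schedule}, seed=4))
        tl = partner_timeline(traj, ("A", 5))
        assert tl.dominant == schedule
        assert tl.switches() == [(10, "base", "phosphate")]

    def test_no_contacts_is_all_none(self):
        traj = make_trajectory(TrajectorySpec(schedule={5: ["none"] * 8}, seed=0))
        assert partner_timeline(traj, ("A", 5)).dominant == ["none"] * 8

    def test_single_phosphate_contact_every_frame(self):
        traj = Trajectory(frames=[simple_frame(3.5, frame_id="x") for _ in range(5)])
        assert partner_timeline(traj, ("A", 5)).dominant == ["phosphate"] * 5

    def test_tie_resolves_phosphate_over_base(self):
        # probe equidistant (3 A) from one P and one N1
        frame = simple_frame(3.0, base_dist=3.0)
        tl = partner_timeline(Trajectory(frames=[frame]), ("A", 5))
        assert tl.class_counts[0] == {"phosphate": 1, "sugar": 0, "base": 1}
        assert tl.dominant == ["phosphate"]


def test_topology_mismatch_names_offending_frame():
    good = simple_frame(3.0)
    bad = ComplexStructure(
        id="bad",
        chains=[
            Chain("A", "protein", [Residue("A", 5, "ALA", [Atom("CG", "C", [0, 0, 0])])]),
            good.chains[1],
        ],
    )
    with pytest.raises(TrajectoryError, match="frame 3"):
        Trajectory(frames=[good, simple_frame(3.1), bad])


def test_multi_model_round_trip(tmp_path):
    from resnominate.structure_io import write_trajectory_pdb

    schedule = ["base"] * 4 + ["phosphate"] * 6
    traj = make_trajectory(TrajectorySpec(schedule={5: schedule}, seed=2))
    path = tmp_path / "traj.pdb"
    write_trajectory_pdb(traj.frames, path)
    back = read_trajectory(path)
    assert back.n_frames == 10
    assert partner_timeline(back, ("A", 5)).dominant == schedule


PARAMS = {
    ("ALA", "CB"): (1.0, 3.4, 0.1),
    ("DA", "P"): (-1.0, 3.7, 0.2),
    ("DA", "N1"): (0.0, 3.3, 0.17),
}


class TestMMEnergy:
    def test_coulomb_closed_form(self):
        """Unit charges at 4 A with eps(r)=4r: -332.0637/(16*4) kcal/mol."""
        frame = simple_frame(4.0)
        elec, _ = residue_mm_energy(frame, ("A", 5), PARAMS)
        assert elec == pytest.approx(-COULOMB_K / (16 * 4), rel=1e-9)

    def test_zero_charges_zero_elec(self):
        params = {k: (0.0, s, e) for k, (q, s, e) in PARAMS.items()}
        elec, _ = residue_mm_energy(simple_frame(4.0), ("A", 5), params)
        assert elec == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        sigma_ij = (3.4 + 3.7) / 2
        eps_ij = math.sqrt(0.1 * 0.2)
        r_min = 2 ** (1 / 6) * sigma_ij
        _, vdw = residue_mm_energy(simple_frame(r_min), ("A", 5), PARAMS)
        assert vdw == pytest.approx(-eps_ij, rel=1e-9)

    def test_charge_scaling_is_quadratic(self):
        frame = simple_frame(5.0, base_dist=6.0)
        lam = 3.0
        scaled = {k: (lam * q, s, e) for k, (q, s, e) in PARAMS.items()}
        e1, _ = residue_mm_energy(frame, ("A", 5), PARAMS)
        e2, _ = residue_mm_energy(frame, ("A", 5), scaled)
        assert e2 == pytest.approx(lam**2 * e1, rel=1e-12)

    def test_opposite_charges_attract(self):
        elec, _ = residue_mm_energy(simple_frame(3.0), ("A", 5), PARAMS)
        assert elec < 0

    def test_pairwise_additive_over_dna_chains(self):
        protein = [Residue("A", 5, "ALA", [Atom("CB", "C", [0.0, 0.0, 0.0])])]
        d1 = [Residue("D", 1, "DA", [Atom("P", "P", [4.0, 0, 0])])]
        d2 = [Residue("E", 1, "DA", [Atom("P", "P", [0, 5.0, 0])])]
        both = ComplexStructure(
            id="b",
            chains=[Chain("A", "protein", protein), Chain("D", "dna", d1), Chain("E", "dna", d2)],
        )
        only1 = ComplexStructure(id="1", chains=[Chain("A", "protein", protein), Chain("D", "dna", d1)])
        only2 = ComplexStructure(id="2", chains=[Chain("A", "protein", protein), Chain("E", "dna", d2)])
        e_both = residue_mm_energy(both, ("A", 5), PARAMS)
        e_sum = np.add(residue_mm_energy(only1, ("A", 5), PARAMS), residue_mm_energy(only2, ("A", 5), PARAMS))
        assert np.allclose(e_both, e_sum, rtol=1e-12)

    def test_cutoff_excludes_far_pairs(self):
        elec, vdw = residue_mm_energy(simple_frame(13.0, base_dist=50.0), ("A", 5), PARAMS)
        assert (elec, vdw) == (0.0, 0.0)

    def test_missing_parameter_names_atom(self):
        with pytest.raises(ParameterError, match="CB"):
            residue_mm_energy(simple_frame(4.0), ("A", 5), {("DA", "P"): (-1, 3.7, 0.2)})


class TestFreeEnergy:
    def test_equation_arithmetic(self):
        assert combine_free_energy(-50.0, 10.0, -5.0) == -35.0
        assert combine_free_energy(0.0, 0.0, 0.0) == 0.0

    def test_mm_assembled_from_components(self):
        decomp = EnergyDecomposition(dG_elec=-30.0, dG_vdw=-20.0)
        assert decomp.dG_MM == -50.0
        assert decomp.dG_bind == -50.0  # solvation and entropy default to zero

    def test_identities_on_random_draws(self, rng):
        for _ in range(200):
            e, v, p, np_, tds = rng.normal(scale=40.0, size=5)
            d = EnergyDecomposition(e, v, p, np_, tds)
            assert d.dG_MM == pytest.approx(e + v, rel=1e-12, abs=1e-12)
            assert d.dG_solv == pytest.approx(p + np_, rel=1e-12, abs=1e-12)
            assert d.dG_bind == pytest.approx(d.dG_MM + d.dG_solv - tds, rel=1e-12, abs=1e-12)


class TestIons:
    @pytest.mark.parametrize("charge,expected", [(-24, ("Na+", 24)), (5, ("Cl-", 5)), (0, ("none", 0))])
    def test_neutralizing(self, charge, expected):
        assert neutralizing_ions(charge) == expected

    def test_salt_pairs_naive_formula(self):
        """0.1 M in a 78 A cube: round(c * N_A * V) = 29 pairs."""
        assert salt_ion_pairs(SystemSetupSpec(box_edge=78.0, salt_concentration=0.1)) == 29

    def test_zero_concentration(self):
        assert salt_ion_pairs(SystemSetupSpec(salt_concentration=0.0)) == 0

    def test_volume_linearity_before_rounding(self):
        from resnominate.trajectory_analysis import A3_TO_LITER, N_AVOGADRO

        v1 = 60.0**3 * A3_TO_LITER * N_AVOGADRO * 0.1
        v2 = (60.0 * 2 ** (1 / 3)) ** 3 * A3_TO_LITER * N_AVOGADRO * 0.1
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            SystemSetupSpec(box_edge=-1.0)
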