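"""Ligand detection, coordination numbers, geometry classification and the
multisite cation model."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_rotation
from poreblock.core_structures import AtomRecord, Structure
from poreblock.ion_coordination import (
    CoordinationShell,
    Ligand,
    build_dummy_ion,
    classify_geometry,
    coordination_shell,
    coordination_statistics,
    find_ligands,
    ideal_template,
)
from poreblock.synthetic_data import (
    CoordinationFixtureSpec,
    MUTANT_SITE_ROSTER,
    WILD_TYPE_SITE_ROSTER,
    build_coordination_fixture,
)


def ion_of(structure):
    return structure.atoms[0]


def make_site(positions, names_residues):
    """Ad-hoc binding-site structure: ion at origin plus given atoms."""
    atoms = [AtomRecord(1, "CA", "CA", "CAL", 1, "X", np.zeros(3))]
    for i, (pos, (name, element, resname, resnum, chain)) in enumerate(
        zip(positions, names_residues)
    ):
        atoms.append(
            AtomRecord(2 + i, name, element, resname, resnum, chain, np.asarray(pos))
        )
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# exhaustive brute-force oracle for geometry classification


def kabsch(P, Q):
    H = Q.T @ P
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def brute_force_classify(shell: CoordinationShell):
    """Try every vertex permutation of every template for the shell's CN and
    return (label, angular rmsd) at the global minimum."""
    cn = shell.CN
    labels = {6: ["octahedral"], 7: ["pentagonal_bipyramidal"]}.get(cn, [])
    vecs = np.array([l.atom.position - shell.ion.position for l in shell.ligands])
    obs = vecs / np.linalg.norm(vecs, axis=1)[:, None]
    best = (math.inf, "other")
    for label in labels:
        tmpl = ideal_template(label)
        for perm in itertools.permutations(range(cn)):
            t = tmpl[list(perm)]
            rot = kabsch(obs, t)
            cosines = np.clip(np.sum(obs * (t @ rot.T), axis=1), -1, 1)
            rmsd = float(np.sqrt(np.mean(np.degrees(np.arccos(cosines)) ** 2)))
            if rmsd < best[0]:
                best = (rmsd, label)
    return best[1], best[0]


class TestFindLigands:
    def test_distance_threshold(self):
        s = make_site(
            [(2.4, 0, 0), (3.4, 0, 0)],
            [("O", "O", "HOH", 101, "W"), ("O", "O", "HOH", 102, "W")],
        )
        ligands = find_ligands(s, ion_of(s), {"water_O": 3.0})
        assert [l.atom.residue_number for l in ligands] == [101]
        assert np.isclose(ligands[0].distance, 2.4)

    def test_bidentate_carboxylate_mutually_partnered(self):
        s = make_site(
            [(2.5, 0, 0), (0, 2.5, 0)],
            [("OD1", "O", "ASP", 433, "A"), ("OD2", "O", "ASP", 433, "A")],
        )
        ligands = find_ligands(s, ion_of(s))
        assert len(ligands) == 2
        assert ligands[0].denticity_partner is ligands[1].atom
        assert ligands[1].denticity_partner is ligands[0].atom

    def test_cysteine_thiolate_recognised(self):
        s = make_site([(2.8, 0, 0)], [("SG", "S", "CYS", 432, "A")])
        ligands = find_ligands(s, ion_of(s), {"thiolate_S": 3.2})
        assert ligands[0].chemistry == "thiolate_S"

    def test_unknown_oxygen_chemistry_warns(self):
        s = make_site([(2.4, 0, 0)], [("OG", "O", "SER", 100, "A")])
        with pytest.warns(UserWarning, match="other"):
            ligands = find_ligands(s, ion_of(s))
        assert ligands == []

    def test_cn_monotone_in_cutoff(self):
        rng = np.random.default_rng(13)
        pos = rng.normal(scale=2.5, size=(12, 3))
        s = make_site(
            pos, [("O", "O", "HOH", 200 + i, "W") for i in range(12)]
        )
        cuts = [1.5, 2.0, 2.5, 3.0, 3.5]
        cns = [
            coordination_shell(s, ion_of(s), {"water_O": c}).CN for c in cuts
        ]
        assert cns == sorted(cns)


class TestCoordinationShell:
    def test_mutant_fixture_has_cn7_with_bidentate(self, mutant_shell_structure):
        shell = coordination_shell(
            mutant_shell_structure, ion_of(mutant_shell_structure)
        )
        assert shell.CN == 7
        assert shell.n_waters == 2
        assert shell.n_bidentate == 1

    def test_wild_type_fixture_has_cn6_three_waters(self, wild_type_shell_structure):
        shell = coordination_shell(
            wild_type_shell_structure, ion_of(wild_type_shell_structure)
        )
        assert shell.CN == 6
        assert shell.n_waters == 3
        assert shell.n_bidentate == 0

    def test_isolated_ion_has_empty_shell(self):
        s = make_site([(9.0, 0, 0)], [("O", "O", "HOH", 101, "W")])
        shell = coordination_shell(s, ion_of(s))
        assert shell.CN == 0 and shell.ligands == []


class TestClassifyGeometry:
    def test_ideal_octahedron(self, wild_type_shell_structure):
        shell = coordination_shell(
            wild_type_shell_structure, ion_of(wild_type_shell_structure)
        )
        geo = classify_geometry(shell)
        assert geo.label == "octahedral"
        assert geo.angular_rmsd < 1e-6

    def test_ideal_pentagonal_bipyramid(self, mutant_shell_structure):
        shell = coordination_shell(
            mutant_shell_structure, ion_of(mutant_shell_structure)
        )
        geo = classify_geometry(shell)
        assert geo.label == "pentagonal_bipyramidal"
        assert geo.angular_rmsd < 1e-6

    @pytest.mark.parametrize("geometry,roster", [
        ("octahedral", WILD_TYPE_SITE_ROSTER),
        ("pentagonal_bipyramidal", MUTANT_SITE_ROSTER),
    ])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_shells_match_exhaustive_oracle(self, geometry, roster, seed):
        s = build_coordination_fixture(
            CoordinationFixtureSpec(geometry, roster, 2.4, angular_noise_sd=5.0,
                                    seed=seed)
        )
        shell = coordination_shell(s, ion_of(s))
        geo = classify_geometry(shell)
        oracle_label, oracle_rmsd = brute_force_classify(shell)
        assert geo.label == oracle_label == geometry
        assert np.isclose(geo.angular_rmsd, oracle_rmsd, atol=1e-6)
        assert 1.0 <= geo.angular_rmsd <= 10.0

    def test_rotation_leaves_label_and_rmsd_unchanged(self, mutant_shell_structure):
        shell = coordination_shell(
            mutant_shell_structure, ion_of(mutant_shell_structure)
        )
        ref = classify_geometry(shell)
        rng = np.random.default_rng(99)
        for _ in range(25):
            rot = random_rotation(rng)
            rotated = mutant_shell_structure.with_coordinates(
                mutant_shell_structure.coordinates() @ rot.T
            )
            geo = classify_geometry(
                coordination_shell(rotated, ion_of(rotated))
            )
            assert geo.label == ref.label
            assert abs(geo.angular_rmsd - ref.angular_rmsd) < 1e-6

    def test_unsupported_cn_is_other(self):
        s = make_site(
            [(2.4, 0, 0), (0, 2.4, 0)],
            [("O", "O", "HOH", 101, "W"), ("O", "O", "HOH", 102, "W")],
        )
        geo = classify_geometry(coordination_shell(s, ion_of(s)))
        assert geo.label == "other"

    def test_heavily_distorted_octahedron_is_other(self):
        # six ligands crammed into one hemisphere cannot match the template
        rng = np.random.default_rng(4)
        pos = np.abs(rng.normal(scale=1.0, size=(6, 3))) + 0.5
        pos = 2.4 * pos / np.linalg.norm(pos, axis=1)[:, None]
        s = make_site(pos, [("O", "O", "HOH", 300 + i, "W") for i in range(6)])
        geo = classify_geometry(coordination_shell(s, ion_of(s)))
        assert geo.label == "other"
        assert geo.angular_rmsd > 15.0


class TestCoordinationStatistics:
    def test_static_fixture_gives_zero_sd_and_unit_occupancy(
        self, wild_type_shell_structure
    ):
        from poreblock.core_structures import Frame, Trajectory

        coords = wild_type_shell_structure.coordinates()
        traj = Trajectory(
            topology=wild_type_shell_structure,
            frames=[Frame(coordinates=coords.copy(), time_index=i) for i in range(5)],
        )
        stats = coordination_statistics(traj)
        assert stats.geometry_occupancy == {"octahedral": 1.0}
        mean, sd = stats.bond_length_stats["water_O"]
        assert np.isclose(mean, 2.4, atol=1e-9) and sd < 1e-12
        mean_c, sd_c = stats.bond_length_stats["carboxylate_O"]
        assert np.isclose(mean_c, 2.4, atol=1e-9)

    def test_alternating_mixture_occupancy_half_half(self, mutant_shell_structure):
        from poreblock.core_structures import Frame, Trajectory
        from poreblock.ion_coordination import ideal_template

        # one topology (the 7-ligand mutant fixture); in alternate frames the
        # glutamate oxygen retreats out of the shell and the remaining six
        # donors rearrange onto octahedral vertices
        coords_pbp = mutant_shell_structure.coordinates()
        donor_idx = [
            i
            for i, a in enumerate(mutant_shell_structure.atoms)
            if i > 0 and a.element in ("O", "S") and a.name != "O?"
            and a.name not in ("CG", "CD")
        ]
        glu_idx = next(
            i
            for i, a in enumerate(mutant_shell_structure.atoms)
            if a.residue_name == "GLU" and a.element == "O"
        )
        coords_oct = coords_pbp.copy()
        oct_vertices = ideal_template("octahedral") * 2.4
        kept = [i for i in donor_idx if i != glu_idx]
        assert len(kept) == 6
        for v, i in zip(oct_vertices, kept):
            coords_oct[i] = v
        coords_oct[glu_idx] = np.array([8.0, 0.0, 0.0])  # out of the shell
        traj = Trajectory(
            topology=mutant_shell_structure,
            frames=[
                Frame(coordinates=(coords_pbp if i % 2 == 0 else coords_oct),
                      time_index=i)
                for i in range(10)
            ],
        )
        stats = coordination_statistics(traj)
        assert stats.geometry_occupancy == {
            "pentagonal_bipyramidal": 0.5,
            "octahedral": 0.5,
        }
        assert set(stats.cn_trace) == {6, 7}


class TestDummyIonModel:
    def test_charge_closure(self):
        m = build_dummy_ion(n_sites=6, site_charge=0.3)
        assert np.isclose(m.central_charge, 0.2, atol=1e-12)
        assert np.isclose(m.total_charge, 2.0, atol=1e-12)

    @pytest.mark.parametrize("site_charge", [-0.5, 0.0, 0.25, 1.0 / 3.0])
    def test_total_charge_exactly_two_for_any_parameterization(self, site_charge):
        m = build_dummy_ion(n_sites=6, site_charge=site_charge)
        assert abs(m.total_charge - 2.0) < 1e-12

    def test_six_sites_pairwise_orthogonal_axes(self):
        m = build_dummy_ion(n_sites=6, site_distance=0.9)
        s = m.to_structure()
        pos = np.array([a.position for a in s.atoms[1:]])
        np.testing.assert_allclose(np.linalg.norm(pos, axis=1), 0.9, atol=1e-12)
        unit = pos / 0.9
        dots = np.abs(unit @ unit.T - np.eye(6))
        # every pair is orthogonal or antipodal
        assert np.all((dots < 1e-9) | (np.abs(dots - 1) < 1e-9))

    def test_model_shell_classifies_as_octahedral(self):
        m = build_dummy_ion()
        s = m.to_structure()
        ion = s.atoms[0]
        ligands = [
            Ligand(atom=a, chemistry="other", distance=float(np.linalg.norm(a.position)))
            for a in s.atoms[1:]
        ]
        geo = classify_geometry(CoordinationShell(ion=ion, ligands=ligands))
        assert geo.label == "octahedral"
        assert geo.angular_rmsd < 1e-6

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_dummy_ion(site_distance=0.0)
        with pytest.raises(ValueError):
            build_dummy_ion(n_sites=1)
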