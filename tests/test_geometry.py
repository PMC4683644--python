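"""Superposition, probe distances, pocket sterics, interval arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pocketmod as pm
from pocketmod import synthdata
from pocketmod.geometry import GenomicInterval, ScissileBondDef, interval_length
from pocketmod.structio import Atom, Residue, SiteCatalog, Structure
from pocketmod.synthdata import SCISSILE, make_ligand

from conftest import rigid_transform


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        rot, trans, rmsd = pm.kabsch_superpose(pts, pts)
        assert rmsd < 1e-9
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, np.zeros(3), atol=1e-9)

    def test_planted_transform_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot_true, trans_true = rigid_transform(rng)
        moved = pts @ rot_true.T + trans_true
        rot, trans, rmsd = pm.kabsch_superpose(pts, moved)
        assert rmsd < 1e-6
        np.testing.assert_allclose(rot, rot_true, atol=1e-6)
        np.testing.assert_allclose(trans, trans_true, atol=1e-6)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_noisy_rmsd_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(scale=0.3, size=(10, 3))
        rot, trans, rmsd = pm.kabsch_superpose(a, b)
        fitted = a @ rot.T + trans
        direct = np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1)))
        assert rmsd == pytest.approx(direct)

    def test_superposed_rmsd_never_exceeds_raw(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=(7, 3))
            b = rng.normal(size=(7, 3))
            _, _, rmsd = pm.kabsch_superpose(a, b)
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert rmsd <= raw + 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pm.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            pm.kabsch_superpose(line, line)


def structure_with_ligand(lig_center):
    s = pm.make_toy_template(8, "helix", seed=0, sequence="AVDSTIDE")
    s.ligands.append(make_ligand(np.asarray(lig_center, float)))
    return s


class TestScissileDistance:
    def test_probe_at_midpoint_is_zero(self):
        s = structure_with_ligand([0.0, 0.0, 0.0])
        lig = s.get_ligand("VAD")
        mid = 0.5 * (lig.atom("C1").coord + lig.atom("O1").coord)
        s.residues[0].atom("CA").coord = mid
        assert pm.scissile_distance(s, ("A", 1), "CA", SCISSILE) == pytest.approx(0.0)

    def test_three_four_five(self):
        s = structure_with_ligand([30.0, 0.0, 0.0])
        lig = s.get_ligand("VAD")
        mid = 0.5 * (lig.atom("C1").coord + lig.atom("O1").coord)
        s.residues[0].atom("CA").coord = mid + np.array([3.0, 4.0, 0.0])
        assert pm.scissile_distance(s, ("A", 1), "CA", SCISSILE) == pytest.approx(5.0)

    def test_carboxyl_probe_on_aspartate(self):
        s = structure_with_ligand([8.0, 0.0, 0.0])
        d = pm.scissile_distance(s, ("A", 3), "carboxyl", SCISSILE)  # residue 3 is D
        lig = s.get_ligand("VAD")
        mid = 0.5 * (lig.atom("C1").coord + lig.atom("O1").coord)
        cg = s.get_residue("A", 3).atom("CG").coord
        assert d == pytest.approx(float(np.linalg.norm(cg - mid)))
        assert pm.scissile_distance(s, ("A", 3), "carboxyl_min", SCISSILE) <= d + 1e-12

    def test_carboxyl_probe_on_nonacid_raises(self):
        s = structure_with_ligand([8.0, 0.0, 0.0])
        with pytest.raises(KeyError):
            pm.scissile_distance(s, ("A", 1), "carboxyl", SCISSILE)  # alanine

    def test_invariant_under_rigid_motion(self):
        s = structure_with_ligand([7.0, 2.0, 1.0])
        base = pm.scissile_distance(s, ("A", 5), "CA", SCISSILE)
        rng = np.random.default_rng(5)
        for _ in range(3):
            rot, trans = rigid_transform(rng)
            moved = s.copy()
            moved.set_coords(moved.coords() @ rot.T + trans)
            assert pm.scissile_distance(moved, ("A", 5), "CA", SCISSILE) == pytest.approx(
                base, abs=1e-9
            )


class TestSiteDistance:
    def test_self_distance_zero(self, helix12):
        assert pm.site_distance(helix12, ("A", 4), ("A", 4)) == 0.0

    def test_constructed_ten_angstroms(self):
        res = [
            Residue("A", 1, "GLY", [Atom("CA", "C", np.zeros(3))]),
            Residue("A", 2, "GLY", [Atom("CA", "C", np.array([10.0, 0, 0]))]),
        ]
        s = Structure(residues=res)
        assert pm.site_distance(s, ("A", 1), ("A", 2)) == pytest.approx(10.0)

    def test_matches_hand_computation(self, helix12):
        d = pm.site_distance(helix12, ("A", 2), ("A", 9))
        hand = float(
            np.linalg.norm(
                helix12.get_residue("A", 2).atom("CA").coord
                - helix12.get_residue("A", 9).atom("CA").coord
            )
        )
        assert d == pytest.approx(hand)

    def test_missing_site_raises(self, helix12):
        with pytest.raises(KeyError):
            pm.site_distance(helix12, ("A", 1), ("A", 99))


class TestPocketClash:
    def test_distant_probe_no_clashes(self):
        scen = synthdata.make_scenario("pocket", seed=0)
        s = scen.structures["small"]
        sites = [tuple(x) for x in scen.ground_truth["pocket_sites"]]
        report = pm.pocket_clash(s, sites, "PRB")
        assert report.clash_count == scen.ground_truth["clash_count_small"] == 0

    def test_half_angstrom_overlap_counted_once(self):
        res = [Residue("A", 1, "GLY", [Atom("CA", "C", np.zeros(3))])]
        s = Structure(residues=res)
        s.ligands.append(
            Residue("P", 1, "PRB",
                    [Atom("C1", "C", np.array([2.9, 0, 0]), is_ligand_atom=True)])
        )
        report = pm.pocket_clash(s, [("A", 1)], "PRB")
        assert report.clash_count == 1
        assert report.overlaps[0][2] == pytest.approx(0.5)  # 1.7 + 1.7 - 2.9

    def test_bulky_pocket_more_clashes_less_volume(self):
        scen = synthdata.make_scenario("pocket", seed=0)
        sites = [tuple(x) for x in scen.ground_truth["pocket_sites"]]
        small = pm.pocket_clash(scen.structures["small"], sites, "PRB")
        bulky = pm.pocket_clash(scen.structures["bulky"], sites, "PRB")
        assert bulky.clash_count == scen.ground_truth["clash_count_bulky"]
        assert bulky.clash_count > small.clash_count
        assert bulky.free_volume < small.free_volume

    def test_free_volume_monotone_in_probe_radius(self):
        scen = synthdata.make_scenario("pocket", seed=0)
        sites = [tuple(x) for x in scen.ground_truth["pocket_sites"]]
        volumes = [
            pm.pocket_clash(
                scen.structures["small"], sites, "PRB", radius_scale=sc
            ).free_volume
            for sc in (0.8, 1.0, 1.5, 2.0)
        ]
        assert all(b <= a for a, b in zip(volumes, volumes[1:]))

    def test_empty_probe_raises(self, helix12):
        with pytest.raises(KeyError):
            pm.pocket_clash(helix12, [("A", 1)], "PRB")


class TestIntervalLength:
    @pytest.mark.parametrize("start,end,expected", [(1, 1, 1), (10, 19, 10)])
    def test_small_cases(self, start, end, expected):
        assert interval_length(GenomicInterval("I", start, end)) == expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("I", 5, 4)

    @given(st.integers(1, 10**6), st.integers(0, 999))
    def test_counting_oracle(self, start, span):
        iv = GenomicInterval("I", start, start + span)
        counted = sum(1 for _ in range(iv.start, iv.end + 1))
        assert interval_length(iv) == counted


class TestGeometryReport:
    def test_reference_against_itself_zero_deltas(self):
        s = structure_with_ligand([7.0, 1.0, 0.0])
        sites = SiteCatalog(entries={"bn2_site": ("A", 5)})
        reports = pm.geometry_report(
            {"wild_type": s, "other": s.copy()}, sites, [("bn2_site", "CA")], SCISSILE
        )
        assert reports["other"].deltas[("bn2_site", "CA")] == pytest.approx(0.0)

    def test_planted_shift_changes_distances_consistently(self):
        scen = synthdata.make_scenario("mutation_displacement", seed=3)
        sites = SiteCatalog(entries={"bn2_site": tuple(scen.ground_truth["site"])})
        reports = pm.geometry_report(
            {
                "wild_type": scen.structures["wild_type"],
                "shifted": scen.structures["shifted"],
            },
            sites,
            [("bn2_site", "CA")],
            SCISSILE,
        )
        key = ("bn2_site", "CA")
        assert reports["wild_type"].probe_distances[key] == pytest.approx(
            scen.ground_truth["wt_probe_distance"], abs=1e-9
        )
        assert reports["shifted"].probe_distances[key] == pytest.approx(
            scen.ground_truth["shifted_probe_distance"], abs=1e-9
        )
        delta = reports["shifted"].deltas[key]
        assert abs(delta) <= scen.ground_truth["planted_shift"] + 1e-9
        assert delta == pytest.approx(
            scen.ground_truth["shifted_probe_distance"]
            - scen.ground_truth["wt_probe_distance"]
        )

    def test_missing_reference_raises(self):
        s = structure_with_ligand([5.0, 0, 0])
        sites = SiteCatalog(entries={"bn2_site": ("A", 5)})
        with pytest.raises(KeyError):
            pm.geometry_report({"only": s}, sites, [("bn2_site", "CA")], SCISSILE)
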