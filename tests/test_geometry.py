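"""Coordination shells, distortion scoring and per-ligand descriptors."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from ionshell.fixtures import _GUA, OCTA, EX, EY, EZ, FixtureSpec, make_fixture
from ionshell.geometry import (
    GeometryParams,
    angle_deg,
    build_all_shells,
    build_shell,
    cis_trans,
    octahedral_distortion,
    outer_shell_contacts,
    phosphate_geometry,
    base_geometry,
)
from ionshell.classify import label_site

from conftest import make_atom, make_table


def brute_force_distortion(positions, ion=np.zeros(3)):
    """6!-assignment oracle: minimal mean |angle deviation| over vertex maps."""
    vecs = [np.asarray(p) - ion for p in positions]
    angles = {}
    for i, j in itertools.combinations(range(6), 2):
        c = np.dot(vecs[i], vecs[j]) / (np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j]))
        angles[(i, j)] = math.degrees(math.acos(max(-1, min(1, c))))
    # vertex k and k^1 are opposite (0-1, 2-3, 4-5)
    best = math.inf
    for perm in itertools.permutations(range(6)):
        total = 0.0
        for i, j in itertools.combinations(range(6), 2):
            ideal = 180.0 if perm[i] // 2 == perm[j] // 2 else 90.0
            total += abs(angles[(i, j)] - ideal)
        best = min(best, total / 15.0)
    return best


def shell_from_positions(positions, element="MG", categories=None):
    recs = [make_atom(element, element, (0, 0, 0), "metal", resname=element, chain="M")]
    categories = categories or ["Ow"] * len(positions)
    for i, (p, cat) in enumerate(zip(positions, categories), start=1):
        name = {"Ow": "O", "Oph": "OP1", "Or": "O2'", "Ob": "O6", "Nb": "N7"}[cat]
        res = "HOH" if cat == "Ow" else "G"
        recs.append(make_atom(name, name[0], p, cat, resname=res, chain="L", resnum=i))
    t = make_table(recs)
    return t, build_shell(t, t.atoms[0])


class TestBuildShell:
    def test_ideal_hexahydrate(self, octa_waters):
        t = octa_waters(2.07)
        shell = build_shell(t, t.atoms[0])
        assert shell.coordination_number == 6
        assert shell.exclusion_hits == []
        assert all(d == pytest.approx(2.07) for _, d in shell.ligands)

    def test_exclusion_zone_hit(self):
        positions = [2.07 * np.asarray(u) for u in OCTA[:5]] + [3.0 * np.asarray(OCTA[5])]
        _, shell = shell_from_positions(positions)
        assert shell.coordination_number == 5
        assert len(shell.exclusion_hits) == 1
        assert shell.exclusion_hits[0][1] == pytest.approx(3.0)

    def test_k_like_shell_relabelled_mg(self):
        """7 oxygens at 2.8 A: zero Mg ligands, all in the exclusion zone."""
        table, _ = make_fixture(FixtureSpec(motif="K_site", params={"element": "MG"}))
        shell = build_shell(table, table.metals()[0])
        assert shell.coordination_number == 0
        assert len(shell.exclusion_hits) == 7

    def test_k_window(self):
        table, _ = make_fixture(FixtureSpec(motif="K_site"))
        shell = build_shell(table, table.metals()[0])
        assert shell.ion.element == "K"
        assert shell.coordination_number == 7
        assert shell.exclusion_hits == []

    def test_low_occupancy_not_ligand(self):
        recs = [make_atom("MG", "MG", (0, 0, 0), "metal", resname="MG", chain="M")]
        recs.append(make_atom("O", "O", (2.07, 0, 0), "Ow", resname="HOH", chain="S", occ=0.3))
        t = make_table(recs)
        assert build_shell(t, t.atoms[0]).coordination_number == 0

    def test_carbon_phosphorus_never_ligands(self):
        recs = [make_atom("MG", "MG", (0, 0, 0), "metal", resname="MG", chain="M"),
                make_atom("C1'", "C", (2.0, 0, 0), "other"),
                make_atom("P", "P", (0, 2.0, 0), "other")]
        t = make_table(recs)
        shell = build_shell(t, t.atoms[0])
        assert shell.coordination_number == 0 and shell.exclusion_hits == []


class TestDistortion:
    def test_ideal_is_exactly_zero(self, octa_waters):
        t = octa_waters()
        shell = build_shell(t, t.atoms[0])
        assert shell.distortion == 0.0
        assert shell.distortion_sum == 0.0
        assert shell.distortion_category == "correct"

    def test_non_hexacoordinated(self):
        positions = [2.07 * np.asarray(u) for u in OCTA[:4]]
        _, shell = shell_from_positions(positions)
        val, cat = octahedral_distortion(shell)
        assert cat == "not_octahedral" and math.isnan(val)

    @pytest.mark.parametrize("rot_deg", [4.0, 12.0, 25.0])
    def test_matches_brute_force_oracle(self, rot_deg):
        """One ligand rotated in a coordination plane vs the 6! oracle."""
        th = math.radians(rot_deg)
        positions = [2.07 * np.array([math.cos(th), math.sin(th), 0.0])]
        positions += [2.07 * np.asarray(u) for u in OCTA[1:]]
        _, shell = shell_from_positions(positions)
        oracle = brute_force_distortion(positions)
        assert shell.distortion == pytest.approx(oracle, abs=1e-9)

    def test_category_thresholds(self):
        """Mean deviations of 4.9 / 5.1 / 10.1 deg land in the printed bands."""
        for target, expected in [(4.9, "correct"), (5.1, "slightly_distorted"),
                                 (10.1, "highly_distorted")]:
            positions = [2.07 * np.asarray(u) for u in OCTA]
            _, shell = shell_from_positions(positions)
            # perturb one cis angle slot by 15 * target degrees
            shell.angles[(0, 2)] = 90.0 + 15.0 * target
            val, cat = octahedral_distortion(shell)
            assert val == pytest.approx(target)
            assert cat == expected

    def test_monotone_in_single_perturbation(self):
        vals = []
        for rot in np.linspace(0.0, 30.0, 16):
            th = math.radians(rot)
            positions = [2.07 * np.array([math.cos(th), math.sin(th), 0.0])]
            positions += [2.07 * np.asarray(u) for u in OCTA[1:]]
            _, shell = shell_from_positions(positions)
            vals.append(shell.distortion)
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_random_shells_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            base = [2.07 * np.asarray(u) for u in OCTA]
            positions = [p + rng.normal(0, 0.04, 3) for p in base]
            _, shell = shell_from_positions(positions)
            assert shell.distortion == pytest.approx(
                brute_force_distortion(positions), abs=1e-9
            )


class TestCisTrans:
    def test_closed_forms(self, octa_waters):
        """cis O...O = sqrt(2) d = 2.93 A, trans O...O = 2 d = 4.14 A at d = 2.07."""
        t = octa_waters(2.07)
        shell = build_shell(t, t.atoms[0])
        cis_d, trans_d = set(), set()
        for (i, j), rel in shell.pairwise_cis_trans.items():
            d = float(np.linalg.norm(shell.ligands[i][0].xyz - shell.ligands[j][0].xyz))
            (cis_d if rel == "cis" else trans_d).add(round(d, 2))
        assert cis_d == {2.93}
        assert trans_d == {4.14}

    def test_angle_cut(self):
        positions = [2.07 * np.asarray(u) for u in OCTA]
        _, shell = shell_from_positions(positions)
        shell.angles[(0, 2)] = 135.0
        assert cis_trans(shell, 0, 2) == "cis"  # boundary inclusive
        shell.angles[(0, 2)] = 135.1
        assert cis_trans(shell, 0, 2) == "trans"
        shell.angles[(0, 2)] = 177.0
        assert cis_trans(shell, 0, 2) == "trans"


class TestRigidInvariance:
    def test_descriptors_invariant(self):
        table, _ = make_fixture(FixtureSpec(motif="Oph5Ow"))
        shells = build_all_shells(table)
        ref = next(iter(shells.values()))
        ref_pg = phosphate_geometry(table, ref)
        rng = np.random.default_rng(11)
        for _ in range(5):
            # random rotation (QR of a Gaussian matrix) + translation
            q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            shift = rng.uniform(-20, 20, 3)
            recs = []
            for a in table:
                recs.append(make_atom(a.name, a.element, q @ a.xyz + shift, a.category,
                                      resname=a.residue_name, chain=a.chain_id,
                                      resnum=a.residue_number))
            t2 = make_table(recs)
            sh2 = build_shell(t2, t2.metals()[0])
            assert sh2.distortion == pytest.approx(ref.distortion, abs=1e-6)
            assert label_site(sh2).text == label_site(ref).text
            pg2 = phosphate_geometry(t2, sh2)
            for (k1, v1), (k2, v2) in zip(sorted(ref_pg.items()), sorted(pg2.items())):
                assert v1.p_op_ion_angle == pytest.approx(v2.p_op_ion_angle, abs=1e-6)
                assert v1.plane_distance == pytest.approx(v2.plane_distance, abs=1e-6)


class TestPhosphateGeometry:
    def test_planted_angle_and_plane(self):
        """Fixture built with ion in the OP1-P-OP2 plane at P-OP...Mg = 148 deg."""
        table, _ = make_fixture(FixtureSpec(motif="Oph5Ow"))
        shell = build_all_shells(table)[table.metals()[0].atom_id]
        (desc,) = phosphate_geometry(table, shell).values()
        assert desc.p_op_ion_angle == pytest.approx(148.0, abs=1e-6)
        assert desc.plane_distance == pytest.approx(0.0, abs=1e-6)

    def test_out_of_plane_displacement(self):
        """Ion moved 0.7 A along the plane normal reads back 0.7."""
        p = np.array([0.0, 0.0, 0.0])
        op1 = p + 1.48 * np.array([1.0, 0.0, 0.0])
        op2 = p + 1.48 * np.array([math.cos(math.radians(119)), math.sin(math.radians(119)), 0.0])
        ion_inplane = op1 + 2.07 * np.array([1.0, 0.5, 0.0]) / np.linalg.norm([1.0, 0.5, 0.0])
        ion = ion_inplane + np.array([0.0, 0.0, 0.7])
        recs = [
            make_atom("MG", "MG", ion, "metal", resname="MG", chain="M"),
            make_atom("P", "P", p, "other"),
            make_atom("OP1", "O", op1, "Oph"),
            make_atom("OP2", "O", op2, "Oph"),
        ]
        t = make_table(recs)
        shell = build_shell(t, t.atoms[0])
        desc = phosphate_geometry(t, shell)[shell.ligands[0][0].atom_id]
        assert desc.plane_distance == pytest.approx(0.7, abs=1e-9)

    def test_against_independent_oracle(self):
        """Law-of-cosines angle + tetrahedron-height plane distance, 50 placements."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(-5, 5, 3)
            u1, u2 = rng.normal(size=3), rng.normal(size=3)
            op1 = p + 1.48 * u1 / np.linalg.norm(u1)
            op2 = p + 1.48 * u2 / np.linalg.norm(u2)
            if np.linalg.norm(np.cross(op1 - p, op2 - p)) < 0.3:
                continue  # nearly collinear phosphate, skip degenerate draw
            v = rng.normal(size=3)
            ion = op1 + 2.07 * v / np.linalg.norm(v)
            recs = [
                make_atom("MG", "MG", ion, "metal", resname="MG", chain="M"),
                make_atom("P", "P", p, "other"),
                make_atom("OP1", "O", op1, "Oph"),
                make_atom("OP2", "O", op2, "Oph"),
            ]
            t = make_table(recs)
            shell = build_shell(t, t.atoms[0])
            if not shell.ligands:
                continue
            op = shell.ligands[0][0]
            desc = phosphate_geometry(t, shell)[op.atom_id]
            # oracle 1: angle from the three side lengths
            a = np.linalg.norm(p - ion)
            b = np.linalg.norm(p - op.xyz)
            c = np.linalg.norm(ion - op.xyz)
            oracle_angle = math.degrees(math.acos((b * b + c * c - a * a) / (2 * b * c)))
            assert desc.p_op_ion_angle == pytest.approx(oracle_angle, abs=1e-6)
            # oracle 2: height of the ion over the (P, OP1, OP2) triangle
            vol6 = abs(np.linalg.det(np.vstack([op1 - p, op2 - p, ion - p])))
            area2 = np.linalg.norm(np.cross(op1 - p, op2 - p))
            assert desc.plane_distance == pytest.approx(vol6 / area2, abs=1e-6)


class TestBaseGeometry:
    def test_planted_carbonyl_angle(self):
        table, _ = make_fixture(FixtureSpec(motif="Ob5Ow"))
        shell = build_all_shells(table)[table.metals()[0].atom_id]
        descs = {k: v for k, v in base_geometry(table, shell).items()}
        (desc,) = descs.values()
        assert desc.alignment_angle == pytest.approx(144.0, abs=1e-6)
        assert desc.plane_distance == pytest.approx(0.0, abs=1e-6)

    def test_out_of_plane_ion(self):
        """Guanine in z = 0; ion 1.5 A above the plane reads 1.5."""
        o6 = _GUA["O6"]
        lateral = math.sqrt(2.07**2 - 1.5**2)
        ion = o6 + lateral * np.array([1.0, 0.0, 0.0]) + np.array([0.0, 0.0, 1.5])
        recs = [make_atom("MG", "MG", ion, "metal", resname="MG", chain="M")]
        for nm, pos in _GUA.items():
            cat = {"O6": "Ob", "N7": "Nb", "N3": "Nb"}.get(nm, "other")
            recs.append(make_atom(nm, nm[0], pos, cat))
        t = make_table(recs)
        shell = build_shell(t, t.atoms[0])
        desc = base_geometry(t, shell)[[a for a, _ in shell.ligands][0].atom_id]
        assert desc.plane_distance == pytest.approx(1.5, abs=1e-6)

    def test_plane_fit_matches_eigen_oracle(self):
        """SVD plane distances equal a covariance-eigenvector plane fit."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            ring = np.vstack([_GUA[nm] for nm in
                              ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")])
            ring = ring + rng.normal(0, 0.05, ring.shape)
            probe = rng.uniform(-3, 3, 3)
            centroid = ring.mean(axis=0)
            cov = (ring - centroid).T @ (ring - centroid)
            w, v = np.linalg.eigh(cov)
            normal = v[:, 0]
            oracle = abs(float(np.dot(probe - centroid, normal)))
            from ionshell.geometry import fit_plane, point_plane_distance

            c2, n2 = fit_plane(ring)
            assert point_plane_distance(probe, c2, n2) == pytest.approx(oracle, abs=1e-6)

    def test_nb_lone_pair_alignment(self):
        table, _ = make_fixture(FixtureSpec(motif="Nb5Ow"))
        shell = build_all_shells(table)[table.metals()[0].atom_id]
        (desc,) = base_geometry(table, shell).values()
        assert desc.alignment_angle == pytest.approx(0.0, abs=1e-6)
        assert desc.plane_distance == pytest.approx(0.0, abs=1e-6)


class TestOuterShell:
    def test_hoogsteen_edge_contacts(self):
        """A first-shell water 2.9 A from (G)O6 and (G)N7 gives two contacts."""
        table, _ = make_fixture(FixtureSpec(motif="outer_shell"))
        shell = build_all_shells(table)[table.metals()[0].atom_id]
        contacts = outer_shell_contacts(table, shell)
        names = sorted(acc.name for _, acc, _ in contacts)
        assert names == ["N7", "O6"]
        assert all(d == pytest.approx(2.9, abs=1e-6) for _, _, d in contacts)

    @pytest.mark.parametrize("d,expected", [(2.9, 1), (3.3, 0), (2.5, 0)])
    def test_window_edges(self, d, expected):
        recs = [make_atom("MG", "MG", (0, 0, 0), "metal", resname="MG", chain="M")]
        recs.append(make_atom("O", "O", (2.07, 0, 0), "Ow", resname="HOH", chain="S"))
        recs.append(make_atom("OP1", "O", (2.07 + d, 0, 0), "Oph", chain="A"))
        t = make_table(recs)
        shell = build_shell(t, t.atoms[0])
        assert len(outer_shell_contacts(t, shell)) == expected


class TestParams:
    def test_override_validation(self):
        p = GeometryParams().with_overrides({"clamp_dmax": "3.6"})
        assert p.clamp_dmax == 3.6
        p = GeometryParams().with_overrides({"mg_accept_window": "1.8,2.4"})
        assert p.mg_accept_window == (1.8, 2.4)
        with pytest.raises(KeyError):
            GeometryParams().with_overrides({"no_such_key": 1})

    def test_load_params_file(self, tmp_path):
        from ionshell.geometry import load_params

        f = tmp_path / "p.cfg"
        f.write_text("clamp_bmax = 50  # stricter B filter\nk_window = 2.5,3.3\n")
        p = load_params(f)
        assert p.clamp_bmax == 50.0 and p.k_window == (2.5, 3.3)
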