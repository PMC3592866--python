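"""Ensemble geometry: helices, angles, superposition, SASA, contacts."""

import numpy as np
import pytest

import oligostate as og
from oligostate.structure_geometry import (
    Atom,
    Chain,
    ContactKind,
    Model,
    Residue,
    StructureEnsemble,
    _sphere_points,
    ensemble_interface_report,
)


class TestIO:
    def test_roundtrip_preserves_topology_and_coords(self, hairpin_dimer, tmp_path):
        path = tmp_path / "dimer.pdb"
        og.write_structure(hairpin_dimer, path)
        back = og.read_structure(path)
        assert len(back) == len(hairpin_dimer)
        a = hairpin_dimer.models[0].atom_records()
        b = back.models[0].atom_records()
        assert a == b
        dev = np.abs(hairpin_dimer.models[0].coords() - back.models[0].coords())
        assert dev.max() < 1e-3 + 1e-9  # PDB format precision

    def test_multi_model_count(self, hairpin_dimer, tmp_path):
        ens = og.jitter_ensemble(hairpin_dimer, 0.2, 20, seed=3)
        path = tmp_path / "ens.pdb"
        og.write_structure(ens, path)
        assert len(og.read_structure(path)) == 20

    def test_unparseable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a coordinate file\n")
        with pytest.raises(ValueError):
            og.read_structure(bad)

    def test_topology_mismatch_names_atom(self, hairpin_dimer):
        m1 = hairpin_dimer.models[0]
        import copy

        m2 = copy.deepcopy(m1)
        del m2.chains[0].residues[0].atoms[-1]
        with pytest.raises(ValueError, match="topology"):
            StructureEnsemble([m1, m2])


class TestHelixAssignment:
    def test_ideal_helix_is_one_segment(self, hairpin_dimer):
        segs = og.assign_helices(hairpin_dimer.models[0], "A")
        assert len(segs) == 2  # the two hairpin helices
        for seg in segs:
            assert seg.n_residues >= 12

    def test_extended_chain_has_no_segments(self):
        # poly-alanine strand along x: phi/psi near 180
        residues = []
        for i in range(12):
            base = np.array([3.4 * i, 0.0, 0.0])
            residues.append(
                Residue(
                    i + 1,
                    "ALA",
                    [
                        Atom("N", "N", base),
                        Atom("CA", "C", base + [1.2, 0.7, 0.0]),
                        Atom("C", "C", base + [2.4, 0.0, 0.0]),
                        Atom("O", "O", base + [2.4, -1.2, 0.0]),
                    ],
                )
            )
        model = Model([Chain("A", residues)])
        assert og.assign_helices(model, "A") == []


class TestAxesAndAngles:
    def test_collinear_points_axis(self):
        pts = np.column_stack([np.zeros(8), np.zeros(8), np.arange(8.0)])
        axis, centroid, rms = og.fit_helix_axis(pts)
        assert axis @ np.array([0, 0, 1.0]) == pytest.approx(1.0)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            og.fit_helix_axis(np.zeros((4, 3)))

    def test_generated_helix_axis_and_radius(self):
        spec = og.HairpinGeometrySpec(interhelix_angle=0.0)
        ens = og.gen_hairpin_dimer(spec)
        segs = og.assign_helices(ens.models[0], "A")
        # parallel helices: crossing angle 0
        assert og.crossing_angle(segs[0].axis, segs[1].axis) == pytest.approx(0.0, abs=0.5)
        # rms from axis approximates the nominal helix radius
        assert segs[0].fit_rms == pytest.approx(2.3, rel=0.10)

    def test_crossing_angle_invariances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=3), rng.normal(size=3)
            a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
            th = og.crossing_angle(a, b)
            assert 0.0 <= th <= 90.0
            assert og.crossing_angle(b, a) == pytest.approx(th)
            assert og.crossing_angle(-a, b) == pytest.approx(th)

    def test_orthogonal_and_identical(self):
        assert og.crossing_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)
        assert og.crossing_angle([0, 0, 1], [0, 0, 1]) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            og.crossing_angle([0, 0, 0], [1, 0, 0])

    @pytest.mark.parametrize("inter,dock", [(0, 30), (15, 0), (31, 85), (45, 45), (60, 90), (90, 10)])
    def test_angle_recovery_grid(self, inter, dock):
        """Generated hairpins return their ground-truth angles within 1
        (inter-helix) and 2 (docking) degrees."""
        spec = og.HairpinGeometrySpec(interhelix_angle=inter, docking_angle=dock)
        model = og.gen_hairpin_dimer(spec).models[0]
        assert og.interhelix_angle(model, "A") == pytest.approx(inter, abs=1.0)
        assert og.interhelix_angle(model, "B") == pytest.approx(inter, abs=1.0)
        assert og.docking_angle(model) == pytest.approx(dock, abs=2.0)

    def test_docking_angle_requires_two_chains(self, hairpin_dimer):
        solo = Model([hairpin_dimer.models[0].chains[0]])
        with pytest.raises(ValueError):
            og.docking_angle(solo)

    def test_superposed_copies_dock_at_zero(self, hairpin_dimer):
        chain_a = hairpin_dimer.models[0].chains[0]
        import copy

        twin = copy.deepcopy(chain_a)
        twin.id = "B"
        model = Model([chain_a, twin])
        assert og.docking_angle(model) == pytest.approx(0.0, abs=1e-6)


class TestSuperposition:
    def test_self_superposition(self, hairpin_dimer):
        X = hairpin_dimer.models[0].coords()
        R, t, rmsd = og.superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert R == pytest.approx(np.eye(3), abs=1e-10)

    def test_rigid_rotation_recovered(self, hairpin_dimer):
        X = hairpin_dimer.models[0].coords()
        ang = np.deg2rad(40)
        Rz = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        Y = X @ Rz.T + np.array([5.0, -3.0, 2.0])
        _, _, rmsd = og.superpose(X, Y)
        assert rmsd < 1e-6

    def test_known_displacement_rmsd(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3)) * 10
        Y = X.copy()
        # displace one atom along the direction least coupled to rotation:
        # use a large cloud so the rigid-body re-fit is negligible
        Y[0] += np.array([0.9, 0.0, 0.0])
        _, _, rmsd = og.superpose(X, Y)
        assert rmsd == pytest.approx(0.9 / np.sqrt(50), rel=0.05)

    def test_degenerate_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            og.superpose(line, line)


class TestEnsembleRMSD:
    def test_identical_models_zero(self, hairpin_dimer):
        ens = og.jitter_ensemble(hairpin_dimer, 0.0, 5, seed=0)
        mean, sd = og.ensemble_rmsd(ens)
        assert mean == pytest.approx(0.0, abs=1e-10)
        assert sd == pytest.approx(0.0, abs=1e-10)

    def test_jittered_matches_analytic_scaling(self, hairpin_dimer):
        """iid per-coordinate jitter sigma gives per-model RMSD to the mean
        of sigma*sqrt(3)*sqrt(1-1/M) in expectation."""
        sigma, M = 0.5, 20
        ens = og.jitter_ensemble(hairpin_dimer, sigma, M, seed=11)
        mean, _ = og.ensemble_rmsd(ens, mode="backbone")
        expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 1.0 / M)
        assert mean == pytest.approx(expected, rel=0.05)

    def test_invariant_under_rigid_transform(self, hairpin_dimer):
        ens = og.jitter_ensemble(hairpin_dimer, 0.3, 6, seed=2)
        ref_mean, _ = og.ensemble_rmsd(ens)
        ang = np.deg2rad(70)
        R = np.array(
            [[1, 0, 0], [0, np.cos(ang), -np.sin(ang)], [0, np.sin(ang), np.cos(ang)]]
        )
        m0 = ens.models[0]
        for c in m0.chains:
            for r in c.residues:
                for a in r.atoms:
                    a.pos = R @ a.pos + np.array([10.0, 0.0, -4.0])
        moved_mean, _ = og.ensemble_rmsd(ens)
        assert moved_mean == pytest.approx(ref_mean, abs=1e-6)

    def test_empty_selection_raises(self, hairpin_dimer):
        ens = og.jitter_ensemble(hairpin_dimer, 0.1, 3, seed=0)
        with pytest.raises(ValueError):
            og.ensemble_rmsd(ens, residue_range=(900, 999))


class TestSASA:
    def test_isolated_atom_analytic(self):
        area = og.sasa([Atom("C", "C", np.zeros(3))])[0]
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_engulfed_atom_zero(self):
        # small sphere fully inside a very large one
        big = Atom("X", "SE", np.zeros(3))
        small = Atom("C", "C", np.array([0.2, 0.0, 0.0]))
        areas = og.sasa([big, small], radii={"SE": 6.0, "C": 1.7})
        assert areas[1] == 0.0

    def test_two_atom_toy_matches_dense_oracle(self):
        """Buried fraction of two overlapping spheres vs a 1e5-point run."""
        for d in (2.0, 3.0, 4.0):
            pair = [
                Atom("C", "C", np.zeros(3)),
                Atom("N", "N", np.array([d, 0.0, 0.0])),
            ]
            coarse = og.sasa(pair, sphere_points=960)
            dense = og.sasa(pair, sphere_points=100_000)
            assert coarse.sum() == pytest.approx(dense.sum(), rel=0.02)

    def test_additivity_bound_and_halving(self, hairpin_dimer):
        model = hairpin_dimer.models[0]
        total = og.buried_interface_area(model, "A", "B", per_protomer=False)
        half = og.buried_interface_area(model, "A", "B")
        assert total >= 0.0
        assert half == pytest.approx(total / 2.0)

    def test_distant_chains_bury_nothing(self, hairpin_dimer):
        import copy

        model = copy.deepcopy(hairpin_dimer.models[0])
        for r in model.chains[1].residues:
            for a in r.atoms:
                a.pos = a.pos + np.array([100.0, 0.0, 0.0])
        assert og.buried_interface_area(model, "A", "B") == 0.0

    def test_buried_area_decreases_with_gap(self):
        areas = []
        for gap in (3.0, 6.0, 9.0):
            model = og.gen_hairpin_dimer(
                og.HairpinGeometrySpec(inter_protomer_gap=gap)
            ).models[0]
            areas.append(og.buried_interface_area(model, "A", "B"))
        assert areas[0] > areas[1] > areas[2]

    def test_sphere_points_on_unit_sphere(self):
        pts = _sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.abs(pts.mean(axis=0)).max() < 0.01  # quasi-uniform

    def test_cross_check_against_biotite(self, hairpin_dimer):
        """Independent SASA engine agreement on the same radii set."""
        biotite_struc = pytest.importorskip("biotite.structure")
        model = hairpin_dimer.models[0]
        atoms = [a for c in model.chains for r in c.residues for a in r.atoms]
        arr = biotite_struc.AtomArray(len(atoms))
        arr.coord = np.array([a.pos for a in atoms], dtype=np.float32)
        for i, a in enumerate(atoms):
            arr.element[i] = a.element
            arr.atom_name[i] = a.name
            arr.res_name[i] = "ALA"
            arr.res_id[i] = i // 4 + 1
        vdw = np.array([og.structure_geometry.BONDI_RADII[a.element] for a in atoms])
        ours = og.sasa(atoms, sphere_points=960).sum()
        theirs = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=960, vdw_radii=vdw
        ).sum()
        assert ours == pytest.approx(theirs, rel=0.02)


class TestExposureAndContacts:
    def test_isolated_residue_fully_exposed(self):
        res = Residue(
            1,
            "ALA",
            [
                Atom("N", "N", np.array([0.0, 0.0, 0.0])),
                Atom("CA", "C", np.array([1.45, 0.0, 0.0])),
                Atom("C", "C", np.array([2.0, 1.4, 0.0])),
                Atom("O", "O", np.array([3.2, 1.5, 0.2])),
                Atom("CB", "C", np.array([1.9, -0.8, 1.2])),
            ],
        )
        model = Model([Chain("A", [res])])
        assert og.relative_exposure(model, "A", 1) == pytest.approx(1.0, abs=0.05)

    def test_buried_residue_in_dense_cluster(self):
        rng = np.random.default_rng(5)
        centre = Residue(1, "GLY", [Atom("CA", "C", np.zeros(3))])
        shell = []
        # tight cage of atoms on a sphere around the centre residue
        pts = _sphere_points(80) * 3.4
        cage = Residue(2, "GLY", [Atom("CA", "C", p) for p in pts])
        model = Model([Chain("A", [centre, cage])])
        assert og.relative_exposure(model, "A", 1) < 0.05

    def test_distant_glycines_no_contacts(self):
        g1 = Residue(1, "GLY", [Atom("N", "N", np.zeros(3)), Atom("CA", "C", [1.4, 0, 0]), Atom("C", "C", [2.1, 1.2, 0]), Atom("O", "O", [3.3, 1.2, 0])])
        g2 = Residue(2, "GLY", [Atom("N", "N", [20.0, 0, 0]), Atom("CA", "C", [21.4, 0, 0]), Atom("C", "C", [22.1, 1.2, 0]), Atom("O", "O", [23.3, 1.2, 0])])
        model = Model([Chain("A", [g1]), Chain("B", [g2])])
        assert og.find_contacts(model) == []

    def test_constructed_salt_bridge(self):
        asp = Residue(
            48,
            "ASP",
            [
                Atom("CB", "C", [0.0, 0.0, 0.0]),
                Atom("CG", "C", [1.5, 0.0, 0.0]),
                Atom("OD1", "O", [2.2, 1.05, 0.0]),
                Atom("OD2", "O", [2.1, -1.1, 0.0]),
            ],
        )
        arg = Residue(
            67,
            "ARG",
            [
                Atom("CD", "C", [6.4, 2.6, 0.0]),
                Atom("NE", "N", [5.2, 1.9, 0.0]),
                Atom("CZ", "C", [5.3, 3.2, 0.0]),
            ],
        )
        model = Model([Chain("A", [asp]), Chain("B", [arg])])
        contacts = og.find_contacts(model)
        assert any(
            c.kind is ContactKind.SALT_BRIDGE and c.inter_protomer for c in contacts
        )

    def test_contacts_match_bruteforce_distances(self, hairpin_dimer):
        """Every reported contact satisfies its distance cutoff, verified
        against a brute-force all-pairs scan."""
        model = hairpin_dimer.models[0]
        contacts = og.find_contacts(model)
        atoms = {}
        for c in model.chains:
            for r in c.residues:
                for a in r.atoms:
                    atoms[(c.id, r.seqid, a.name)] = a.pos
        cutoffs = {
            ContactKind.HBOND: 3.5,
            ContactKind.SALT_BRIDGE: 4.0,
            ContactKind.NONPOLAR: 4.5,
        }
        for c in contacts:
            pa = atoms[(c.partner_a[0], c.partner_a[1], c.partner_a[3])]
            pb = atoms[(c.partner_b[0], c.partner_b[1], c.partner_b[3])]
            d = np.linalg.norm(pa - pb)
            assert d == pytest.approx(c.distance, abs=1e-9)
            assert d <= cutoffs[c.kind]


def test_interface_report_fields(hairpin_dimer):
    rep = ensemble_interface_report(hairpin_dimer.models[0])
    assert rep.buried_area >= 0
    assert rep.buried_area_total == pytest.approx(2 * rep.buried_area)
    assert all(0.0 <= v <= 1.0 for v in rep.per_residue_burial.values())
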