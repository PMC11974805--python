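"""Interface contact geometry, SASA and buried surface area."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motifdms.structure import (
    PROBE_RADIUS,
    VDW_RADII,
    StructureUnit,
    assign_protomer_roles,
    buried_surface_area,
    donor_angle,
    find_hydrophobic_contacts,
    find_polar_contacts,
    residue_contact_table,
    shrake_rupley_sasa,
    sphere_points,
)


def unit(atoms, label=""):
    """Build a StructureUnit from (name, element, res_name, res_id, chain, xyz)."""
    return StructureUnit(
        atom_names=[a[0] for a in atoms],
        elements=[a[1] for a in atoms],
        coords=np.array([a[5] for a in atoms], dtype=float),
        res_names=[a[2] for a in atoms],
        res_ids=[a[3] for a in atoms],
        chains=[a[4] for a in atoms],
        label=label,
    )


def lysine_donor(chain="A", res_id=1, nz=(0.0, 0.0, 0.0), ce=(0.0, 0.0, 1.5)):
    return [
        ("NZ", "N", "LYS", res_id, chain, nz),
        ("CE", "C", "LYS", res_id, chain, ce),
    ]


def backbone_acceptor(chain="B", res_id=2, o=(0.0, 0.0, -3.0), c=(0.0, 1.2, -3.5)):
    return [
        ("O", "O", "GLY", res_id, chain, o),
        ("C", "C", "GLY", res_id, chain, c),
    ]


class TestPolarContacts:
    def test_pair_within_distance_and_angle(self):
        # NZ at origin, CE straight up: donor->acceptor at 3 A straight down
        # gives a 180-degree antecedent-donor-acceptor angle
        a = unit(lysine_donor())
        b = unit(backbone_acceptor())
        contacts = find_polar_contacts(a, b)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.0)
        assert 110 <= contacts[0].angle <= 180

    def test_too_far_apart(self):
        a = unit(lysine_donor())
        b = unit(backbone_acceptor(o=(0.0, 0.0, -4.5), c=(0.0, 1.2, -5.0)))
        assert find_polar_contacts(a, b) == []

    def test_bad_angle(self):
        # acceptor perpendicular to the CE-NZ bond: angle 90 degrees
        a = unit(lysine_donor())
        b = unit(backbone_acceptor(o=(3.0, 0.0, 0.0), c=(3.5, 1.2, 0.0)))
        assert find_polar_contacts(a, b) == []

    def test_angle_measured_at_donor_heavy_atom(self):
        assert donor_angle(
            np.array([0.0, 0, 0]), np.array([0.0, 0, 1]), np.array([0.0, 0, -3])
        ) == pytest.approx(180.0)
        assert donor_angle(
            np.array([0.0, 0, 0]), np.array([0.0, 0, 1]), np.array([3.0, 0, 0])
        ) == pytest.approx(90.0)

    def test_proline_backbone_nitrogen_is_not_a_donor(self):
        a = unit([("N", "N", "PRO", 1, "A", (0.0, 0, 0)), ("CA", "C", "PRO", 1, "A", (0.0, 0, 1.5))])
        b = unit(backbone_acceptor())
        assert find_polar_contacts(a, b) == []

    def test_unknown_residue_typed_by_element_with_warning(self):
        a = unit([("X1", "N", "LIG", 1, "A", (0.0, 0, 0)), ("X2", "C", "LIG", 1, "A", (0.0, 0, 1.5))])
        b = unit(backbone_acceptor())
        with pytest.warns(UserWarning, match="LIG"):
            contacts = find_polar_contacts(a, b)
        assert len(contacts) == 1

    def test_matches_all_pairs_oracle_on_toy_complex(self, rng):
        """Brute-force O(n^2) oracle over every inter-unit donor-acceptor pair."""
        from motifdms.structure import _polar_atoms

        def random_unit(chain, n_res):
            atoms = []
            for r in range(n_res):
                center = rng.uniform(-6, 6, 3)
                atoms += [
                    ("N", "N", "GLY", r + 1, chain, tuple(center)),
                    ("CA", "C", "GLY", r + 1, chain, tuple(center + [1.4, 0, 0])),
                    ("C", "C", "GLY", r + 1, chain, tuple(center + [2.0, 1.0, 0])),
                    ("O", "O", "GLY", r + 1, chain, tuple(center + [2.0, 2.2, 0])),
                ]
            return unit(atoms, label=chain)

        a = random_unit("A", 7)
        b = random_unit("B", 6)
        got = {(c.donor, c.acceptor) for c in find_polar_contacts(a, b)}
        expected = set()
        for dunit, aunit in ((a, b), (b, a)):
            donors, _ = _polar_atoms(dunit)
            _, acceptors = _polar_atoms(aunit)
            for di, anti in donors:
                for ai in acceptors:
                    d = np.linalg.norm(dunit.coords[di] - aunit.coords[ai])
                    if d >= 4.0:
                        continue
                    ang = donor_angle(dunit.coords[di], dunit.coords[anti], aunit.coords[ai])
                    if 110 <= ang <= 180:
                        expected.add((dunit.atom_label(di), aunit.atom_label(ai)))
        assert got == expected


class TestHydrophobicContacts:
    def leucines(self, chain, res_id, cd1):
        return [
            ("CD1", "C", "LEU", res_id, chain, cd1),
            ("CG", "C", "LEU", res_id, chain, (cd1[0], cd1[1], cd1[2] + 1.5)),
        ]

    def test_methyl_carbons_within_cutoff(self):
        a = unit(self.leucines("A", 1, (0.0, 0, 0)))
        b = unit(self.leucines("B", 2, (4.0, 0, 0)))
        contacts = find_hydrophobic_contacts(a, b)
        assert contacts and all(c.klass == "hydrophobic" for c in contacts)

    def test_beyond_cutoff(self):
        a = unit(self.leucines("A", 1, (0.0, 0, 0)))
        b = unit(self.leucines("B", 2, (5.0, 0, 4.0)))
        assert find_hydrophobic_contacts(a, b) == []

    def test_polar_carbons_excluded(self):
        # backbone carbonyl C and CA are not apolar carbons
        a = unit([("C", "C", "GLY", 1, "A", (0.0, 0, 0)), ("CA", "C", "GLY", 1, "A", (1.5, 0, 0))])
        b = unit(self.leucines("B", 2, (3.0, 0, 0)))
        assert find_hydrophobic_contacts(a, b) == []

    def test_matches_brute_force(self, rng):
        from motifdms.structure import _apolar_carbons

        def random_unit(chain):
            atoms = []
            for r in range(8):
                xyz = rng.uniform(-5, 5, 3)
                atoms += [
                    ("CB", "C", "ALA", r + 1, chain, tuple(xyz)),
                    ("CA", "C", "ALA", r + 1, chain, tuple(xyz + [1.5, 0, 0])),
                ]
            return unit(atoms, label=chain)

        a, b = random_unit("A"), random_unit("B")
        got = {(c.donor, c.acceptor) for c in find_hydrophobic_contacts(a, b)}
        expected = {
            (a.atom_label(i), b.atom_label(j))
            for i in _apolar_carbons(a)
            for j in _apolar_carbons(b)
            if np.linalg.norm(a.coords[i] - b.coords[j]) <= 4.5
        }
        assert got == expected

    def test_residue_table_deduplicates(self):
        a = unit(self.leucines("A", 1, (0.0, 0, 0)))
        b = unit(self.leucines("B", 2, (4.0, 0, 0)))
        records = find_hydrophobic_contacts(a, b)
        table = residue_contact_table(records)
        assert len(table) == 1
        assert table.iloc[0]["n_atom_pairs"] == len(records)


class TestSasa:
    def test_isolated_atom_is_an_exact_sphere(self):
        for element in ("C", "N", "O", "S"):
            u = unit([("X", element, "LIG", 1, "A", (0.0, 0, 0))])
            r = VDW_RADII[element] + PROBE_RADIUS
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert shrake_rupley_sasa(u) == pytest.approx(4 * math.pi * r**2, rel=1e-9)

    def test_two_overlapping_spheres_match_analytic_caps(self):
        """Closed-form oracle: each sphere loses a spherical cap of area
        2*pi*R*h where h = R - (d^2 + R1^2 - R2^2) / (2 d)."""
        d = 2.0
        u = unit(
            [("C1", "C", "LIG", 1, "A", (0.0, 0, 0)), ("C2", "C", "LIG", 1, "A", (d, 0, 0))]
        )
        r = VDW_RADII["C"] + PROBE_RADIUS
        h = r - d / 2  # equal radii
        analytic = 2 * (4 * math.pi * r**2 - 2 * math.pi * r * h)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = shrake_rupley_sasa(u)
        assert got == pytest.approx(analytic, rel=0.01)

    def test_sphere_points_are_unit_and_deterministic(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, sphere_points(960))

    def test_empty_unit_is_an_error(self):
        u = unit([("C1", "C", "LIG", 1, "A", (0.0, 0, 0))])
        with pytest.raises(ValueError):
            buried_surface_area(u, StructureUnit([], [], np.empty((0, 3)), [], [], []))


class TestBuriedSurfaceArea:
    def glycine(self, chain, res_id, offset):
        off = np.asarray(offset, dtype=float)
        return [
            ("N", "N", "GLY", res_id, chain, tuple(off + [0, 0, 0])),
            ("CA", "C", "GLY", res_id, chain, tuple(off + [1.5, 0, 0])),
            ("C", "C", "GLY", res_id, chain, tuple(off + [2.2, 1.3, 0])),
            ("O", "O", "GLY", res_id, chain, tuple(off + [2.0, 2.5, 0])),
        ]

    @pytest.fixture
    def complex_pair(self):
        a = unit(self.glycine("A", 1, (0, 0, 0)) + self.glycine("A", 2, (3, 0, 1)), "A")
        b = unit(self.glycine("B", 1, (1, 3, 2)) + self.glycine("B", 2, (4, 3, 1)), "B")
        return a, b

    def test_separated_units_bury_nothing(self):
        a = unit(self.glycine("A", 1, (0, 0, 0)))
        b = unit(self.glycine("B", 1, (50, 0, 0)))
        assert buried_surface_area(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_contacting_units_bury_area(self, complex_pair):
        assert buried_surface_area(*complex_pair) > 10.0

    def test_symmetry(self, complex_pair):
        a, b = complex_pair
        assert buried_surface_area(a, b) == pytest.approx(buried_surface_area(b, a), abs=1e-9)

    def test_translation_invariance(self, complex_pair):
        a, b = complex_pair
        t = np.array([13.0, -7.0, 4.0])
        eye = np.eye(3)
        assert buried_surface_area(a.transformed(eye, t), b.transformed(eye, t)) == pytest.approx(
            buried_surface_area(a, b), abs=1e-6
        )

    def test_rotation_invariance_within_sampling_resolution(self, complex_pair):
        # the point set is fixed in space, so rotating the complex changes the
        # sampled area only at the quadrature resolution
        a, b = complex_pair
        rot = Rotation.from_euler("xyz", [30, 45, 60], degrees=True).as_matrix()
        t = np.zeros(3)
        before = buried_surface_area(a, b)
        after = buried_surface_area(a.transformed(rot, t), b.transformed(rot, t))
        assert after == pytest.approx(before, rel=0.02)

    def test_contacts_invariant_under_rigid_motion(self, complex_pair):
        a, b = complex_pair
        rot = Rotation.from_euler("zyx", [12, 34, 56], degrees=True).as_matrix()
        t = np.array([5.0, 6.0, 7.0])
        before = find_polar_contacts(a, b)
        after = find_polar_contacts(a.transformed(rot, t), b.transformed(rot, t))
        assert [(c.donor, c.acceptor) for c in before] == [(c.donor, c.acceptor) for c in after]
        assert np.allclose(
            [c.distance for c in before], [c.distance for c in after], atol=1e-9
        )
        assert np.allclose([c.angle for c in before], [c.angle for c in after], atol=1e-6)


class TestProtomerRoles:
    def make_filament(self):
        dna = unit(
            [("P", "P", "DT", i + 1, "X", (0.0, 0.0, 3.0 * i)) for i in range(6)], "dna"
        )
        p1 = unit([("CA", "C", "GLY", 1, "C", (4.0, 0, 1.0))], "protC")
        p2 = unit([("CA", "C", "GLY", 1, "D", (4.0, 0, 13.0))], "protD")
        return dna, p1, p2

    def test_labels_follow_dna_polarity(self):
        dna, p1, p2 = self.make_filament()
        roles = assign_protomer_roles([p1, p2], dna)
        assert roles == [{"5prime_facing": "protC", "3prime_facing": "protD"}]

    def test_reversed_polarity_swaps_labels(self):
        dna, p1, p2 = self.make_filament()
        roles = assign_protomer_roles([p1, p2], dna, dna_runs_5_to_3=False)
        assert roles == [{"5prime_facing": "protD", "3prime_facing": "protC"}]

    def test_invariant_under_rigid_rotation(self):
        dna, p1, p2 = self.make_filament()
        rot = Rotation.from_euler("xyz", [110, 20, 65], degrees=True).as_matrix()
        t = np.array([-3.0, 9.0, 2.0])
        roles = assign_protomer_roles(
            [p1.transformed(rot, t), p2.transformed(rot, t)], dna.transformed(rot, t)
        )
        assert roles == [{"5prime_facing": "protC", "3prime_facing": "protD"}]

    def test_undeterminable_polarity_warns_and_unlabels(self):
        _, p1, p2 = self.make_filament()
        with pytest.warns(UserWarning):
            roles = assign_protomer_roles([p1, p2], None)
        assert roles == [{"5prime_facing": None, "3prime_facing": None}]


class TestStructureIO:
    def test_round_trip_through_pdb(self, tmp_path, complexes=None):
        import gemmi

        st = gemmi.Structure()
        st.name = "toy"
        model = gemmi.Model("1")
        for chain_name, x0 in (("A", 0.0), ("B", 6.0)):
            chain = gemmi.Chain(chain_name)
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(1, " ")
            for name, el, dx in (("N", "N", 0.0), ("CA", "C", 1.5)):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(x0 + dx, 0, 0)
                res.add_atom(atom)
            chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        path = tmp_path / "toy.pdb"
        st.write_pdb(str(path))

        a = StructureUnit.from_file(path, chains=["A"])
        b = StructureUnit.from_file(path, chains=["B"])
        assert len(a) == len(b) == 2
        assert a.res_names == ["GLY", "GLY"]
        assert buried_surface_area(a, b) >= 0.0
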