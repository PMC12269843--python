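"""BSA decomposition, contact classification, geometry and superposition."""

import numpy as np
import pytest

from tcrint.interface import (
    ContactCriteria,
    GeometryError,
    InterfaceError,
    compute_bsa,
    detect_contacts,
    docking_geometry,
    match_calpha,
    summarize_footprint,
    superpose,
)
from tcrint.sasa import SasaParams
from tcrint.structure import AnnotatedComplex, Atom, Residue
from tcrint.synthetic import (
    ToyComplexSpec,
    make_toy_complex,
    two_sphere_complex,
)


def _atom(name, element, xyz, r):
    return Atom(name, element, np.asarray(xyz, float), vdw_radius=r)


def _pair_complex(atom_a, atom_b, res_a=("ALA", 1), res_b=("ALA", 2)):
    ra = Residue(res_a[0], res_a[1], "", "D", atoms=[atom_a])
    rb = Residue(res_b[0], res_b[1], "", "C", atoms=[atom_b])
    return AnnotatedComplex(chains={"tcr_alpha": [ra], "peptide": [rb]})


def _rigid(coords, angle_deg, axis, shift):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
    return coords @ rot.T + np.asarray(shift, float)


class TestBsa:
    def test_disjoint_chains_bury_nothing(self):
        cx, _ = two_sphere_complex(d=100.0)
        assert compute_bsa(cx).total_bsa == pytest.approx(0.0, abs=1e-9)

    def test_tangent_spheres_bury_nothing(self):
        cx, expected = two_sphere_complex(d=6.2)  # exactly 2*(1.7+1.4)
        assert expected == 0.0
        assert compute_bsa(cx).total_bsa == pytest.approx(0.0, abs=1e-9)

    def test_two_sphere_interface_matches_cap_formula(self):
        cx, expected = two_sphere_complex(d=4.0)
        got = compute_bsa(cx).total_bsa
        assert got == pytest.approx(expected, rel=0.01)

    def test_symmetry_under_side_swap(self, toy_complex):
        params = SasaParams(n_points=480)
        fwd = compute_bsa(toy_complex, params)
        rev = compute_bsa(
            toy_complex, params,
            side_a=("mhc_alpha", "mhc_beta", "peptide"),
            side_b=("tcr_alpha", "tcr_beta"),
        )
        assert fwd.total_bsa == pytest.approx(rev.total_bsa, abs=1e-9)

    def test_single_side_rejected(self):
        r = Residue("ALA", 1, "", "A", atoms=[_atom("CA", "C", [0, 0, 0], 1.7)])
        cx = AnnotatedComplex(chains={"tcr_alpha": [r]})
        with pytest.raises(InterfaceError):
            compute_bsa(cx)

    def test_region_percentages_partition_tcr_burial(self, toy_complex):
        from tcrint.structure import assign_imgt_regions

        cx = toy_complex
        for role in ("tcr_alpha", "tcr_beta"):
            cx.regions[role] = assign_imgt_regions(cx.chains[role])
        bsa = compute_bsa(cx, SasaParams(n_points=480))
        assert bsa.total_bsa > 0
        assert sum(bsa.per_region_pct.values()) == pytest.approx(100.0, abs=0.1)
        assert sum(bsa.chain_share_pct.values()) == pytest.approx(100.0, abs=0.1)
        assert all(v >= 0 for v in bsa.per_residue.values())


class TestContacts:
    def test_backbone_pair_at_3p4_is_hbond_and_vdw(self):
        cx = _pair_complex(
            _atom("N", "N", [0, 0, 0], 1.55), _atom("O", "O", [3.4, 0, 0], 1.52)
        )
        (c,) = detect_contacts(cx).contacts
        assert c.kinds == ("hbond", "vdw")
        assert c.distance == pytest.approx(3.4)

    @pytest.mark.parametrize("d, expected", [(3.9, 1), (4.1, 0)])
    def test_carbon_pair_cutoff_boundary(self, d, expected):
        cx = _pair_complex(
            _atom("CB", "C", [0, 0, 0], 1.7), _atom("CB", "C", [d, 0, 0], 1.7)
        )
        cs = detect_contacts(cx)
        assert len(cs) == expected
        if expected:
            assert cs.contacts[0].kinds == ("vdw",)

    def test_salt_bridge_requires_charged_groups(self):
        cx = _pair_complex(
            _atom("NZ", "N", [0, 0, 0], 1.55), _atom("OE1", "O", [3.8, 0, 0], 1.52),
            res_a=("LYS", 1), res_b=("GLU", 2),
        )
        (c,) = detect_contacts(cx).contacts
        assert c.kinds == ("salt_bridge", "vdw")
        # citrulline is neutral: same geometry, no salt bridge
        cx2 = _pair_complex(
            _atom("NZ", "N", [0, 0, 0], 1.55), _atom("OE1", "O", [3.8, 0, 0], 1.52),
            res_a=("LYS", 1), res_b=("CIR", 2),
        )
        (c2,) = detect_contacts(cx2).contacts
        assert "salt_bridge" not in c2.kinds

    def test_disulfide_window(self):
        cx = _pair_complex(
            _atom("SG", "S", [0, 0, 0], 1.8), _atom("SG", "S", [4.4, 0, 0], 1.8),
            res_a=("CYS", 1), res_b=("CYS", 2),
        )
        (c,) = detect_contacts(cx).contacts
        assert c.kinds == ("disulfide",)  # 4.4 > vdw cutoff, S-S not an H-bond

    def test_hbond_always_vdw(self, toy_complex):
        cs = detect_contacts(toy_complex)
        for c in cs.of_kind("hbond"):
            assert "vdw" in c.kinds

    def test_planted_inventory_recovered_exactly(self, toy_complex, toy_truth):
        cs = detect_contacts(toy_complex)
        got = {(c.atom_a, c.atom_b, c.kinds) for c in cs}
        expected = {(a, b, kinds) for a, b, _, kinds in toy_truth.contacts}
        assert got == expected

    def test_displaced_tcr_has_no_contacts_and_no_bsa(self):
        cx, truth = make_toy_complex(ToyComplexSpec(displacement=50.0))
        assert truth.contacts == []
        assert len(detect_contacts(cx)) == 0
        assert compute_bsa(cx, SasaParams(n_points=480)).total_bsa == pytest.approx(
            0.0, abs=1e-9
        )

    def test_grid_equals_brute_force_on_random_atoms(self, rng):
        n = 250
        res_a = [
            Residue("ALA", i + 1, "", "D",
                    atoms=[_atom("CA", "C", c, 1.7)])
            for i, c in enumerate(rng.uniform(0, 25, size=(n, 3)))
        ]
        res_b = [
            Residue("SER", i + 1, "", "C",
                    atoms=[_atom("OG", "O", c, 1.52)])
            for i, c in enumerate(rng.uniform(0, 25, size=(n, 3)))
        ]
        cx = AnnotatedComplex(chains={"tcr_alpha": res_a, "peptide": res_b})
        grid = detect_contacts(cx, method="grid")
        brute = detect_contacts(cx, method="brute")
        assert len(grid) > 0
        assert grid.as_pair_set() == brute.as_pair_set()

    def test_empty_interface_is_empty_not_error(self):
        cx = AnnotatedComplex(chains={"tcr_alpha": [], "peptide": []})
        assert len(detect_contacts(cx)) == 0


class TestFootprint:
    @pytest.fixture()
    def annotated_toy(self, toy_complex, toy_truth):
        from tcrint.structure import assign_imgt_regions, assign_peptide_register

        cx = toy_complex
        for role in ("tcr_alpha", "tcr_beta"):
            cx.regions[role] = assign_imgt_regions(cx.chains[role])
        cx.register = assign_peptide_register(
            cx.chains["peptide"], toy_truth.p1_seq_id
        )
        return cx

    def test_all_region_rows_present(self, annotated_toy):
        table = summarize_footprint(detect_contacts(annotated_toy), annotated_toy)
        assert list(table.index) == [
            "CDR1a", "CDR2a", "CDR3a", "FWa", "CDR1b", "CDR2b", "CDR3b", "FWb",
        ]

    def test_planted_contacts_land_in_their_regions(self, annotated_toy):
        table = summarize_footprint(detect_contacts(annotated_toy), annotated_toy)
        # H-bond to P-1 citrulline comes from CDR3a (residue 113)
        assert table.loc["CDR3a", "n_hbond"] == 1
        assert table.loc["CDR3a", "pockets"] == "P-1"
        # vdW pair near P5 from CDR3b residue 107
        assert table.loc["CDR3b", "n_vdw"] == 1
        assert table.loc["CDR3b", "pockets"] == "P5"
        # salt bridge from CDR2b Lys57 goes to the HLA, not the peptide
        assert table.loc["CDR2b", "n_salt_bridge"] == 1
        assert table.loc["CDR2b", "n_to_hla"] == 1
        # disulfide from FWa
        assert table.loc["FWa", "n_disulfide"] == 1
        assert table["n_total"].sum() == 4

    def test_empty_contact_set_gives_zero_table(self, annotated_toy):
        from tcrint.interface import ContactSet

        table = summarize_footprint(ContactSet([]), annotated_toy)
        assert (table["n_total"] == 0).all()
        assert (table["pockets"] == "").all()


class TestDockingGeometry:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 70.0, 90.0])
    def test_constructed_angle_recovered(self, angle):
        cx, _ = make_toy_complex(ToyComplexSpec(docking_angle_deg=angle))
        geo = docking_geometry(cx)
        assert geo.docking_angle == pytest.approx(angle, abs=1e-6)

    def test_invariant_under_global_rigid_motion(self, toy_complex, rng):
        before = docking_geometry(toy_complex).docking_angle
        cx, _ = make_toy_complex(ToyComplexSpec())
        for role in cx.chains:
            for res in cx.chains[role]:
                for atom in res.atoms:
                    atom.coords = _rigid(
                        atom.coords[None, :], 53.0, [1, 2, 3], [5, -4, 9]
                    )[0]
        after = docking_geometry(cx).docking_angle
        assert after == pytest.approx(before, abs=1e-6)

    def test_short_peptide_rejected(self, toy_complex):
        cx = AnnotatedComplex(chains={
            "tcr_alpha": toy_complex.chains["tcr_alpha"],
            "tcr_beta": toy_complex.chains["tcr_beta"],
            "peptide": toy_complex.chains["peptide"][:4],
        })
        with pytest.raises(GeometryError):
            docking_geometry(cx)


class TestSuperposition:
    def test_identity(self, rng):
        coords = rng.normal(size=(20, 3))
        sup = superpose(coords, coords)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_exact_rigid_case_recovered(self, rng):
        a = rng.normal(size=(25, 3))
        b = _rigid(a, 37.0, [0, 0, 1], [1.0, -2.0, 3.0])
        sup = superpose(a, b)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.apply(b), a, atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_rmsd_invariant_under_premotion_of_either_set(self, rng):
        a = rng.normal(size=(15, 3))
        b = a + rng.normal(scale=0.5, size=a.shape)
        base = superpose(a, b).rmsd
        assert superpose(a, _rigid(b, 80, [1, 1, 0], [4, 4, 4])).rmsd == \
            pytest.approx(base, abs=1e-9)
        assert superpose(_rigid(a, 12, [0, 1, 1], [-3, 0, 7]), b).rmsd == \
            pytest.approx(base, abs=1e-9)

    def test_no_reflection(self, rng):
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored set: best proper rotation, not a reflection
        sup = superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
        assert sup.rmsd > 0

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_collinear_warns(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.warns(UserWarning, match="collinear"):
            superpose(line, line + [0.1, 0.2, 0.3])

    def test_match_calpha_pairs_shared_residues(self, toy_complex):
        res = toy_complex.chains["tcr_alpha"]
        a, b = match_calpha(res, res[2:])
        assert len(a) == len(res) - 2
        np.testing.assert_allclose(a, b)
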