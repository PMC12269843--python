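"""Structure parsing, chain roles, IMGT regions, register and SE motif."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrint.structure import (
    CoverageError,
    EmptyStructureError,
    ParseError,
    RegisterError,
    Residue,
    RoleError,
    assign_chain_roles,
    assign_imgt_regions,
    assign_peptide_register,
    chain_sequence,
    detect_shared_epitope,
    parse_structure,
    write_pdb,
)
from tcrint.synthetic import ToyComplexSpec, make_toy_complex

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.685   7.167  -4.934  1.00 10.00           C
ATOM      4  O   ALA A   1      13.601   7.325  -5.738  1.00 10.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.60 10.00           C
ATOM      3  CA BALA A   1      11.800   6.200  -5.000  0.40 10.00           C
ATOM      4  C   ALA A   1      12.685   7.167  -4.934  1.00 10.00           C
END
"""

CIR_PDB = """\
ATOM      1  N   ASP C1013       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ASP C1013       1.458   0.000   0.000  1.00 10.00           C
HETATM    3  N   CIR C1014       3.800   0.800   0.000  1.00 10.00           N
HETATM    4  CA  CIR C1014       5.000   0.000   0.000  1.00 10.00           C
ATOM      5  N   TYR C1015       7.600   0.800   0.000  1.00 10.00           N
ATOM      6  CA  TYR C1015       8.800   0.000   0.000  1.00 10.00           C
END
"""


class TestParsing:
    def test_minimal_pdb_identity(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(MINIMAL_PDB)
        polymer, hetero = parse_structure(p)
        assert list(polymer) == ["A"]
        (res,) = polymer["A"]
        assert res.name == "ALA" and res.seq_id == 1
        assert len(res.atoms) == 4
        np.testing.assert_allclose(res.atom("CA").coords, [11.639, 6.071, -5.147])
        assert not hetero

    def test_citrulline_retained_in_sequence(self, tmp_path):
        p = tmp_path / "cir.pdb"
        p.write_text(CIR_PDB)
        polymer, _ = parse_structure(p)
        names = [r.name for r in polymer["C"]]
        assert names == ["ASP", "CIR", "TYR"]
        assert polymer["C"][1].seq_id == 1014

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        polymer, _ = parse_structure(p)
        (res,) = polymer["A"]
        cas = [a for a in res.atoms if a.name == "CA"]
        assert len(cas) == 1
        np.testing.assert_allclose(cas[0].coords, [11.639, 6.071, -5.147])

    def test_unreadable_file_raises(self, tmp_path):
        p = tmp_path / "junk.pdb"
        p.write_text("this is not a structure\n")
        with pytest.raises((ParseError, EmptyStructureError)):
            parse_structure(p)

    def test_waters_flagged_separately(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(
            MINIMAL_PDB.replace("END\n", "")
            + "HETATM    5  O   HOH A 101       0.000   0.000   9.000"
              "  1.00 10.00           O\nEND\n"
        )
        polymer, hetero = parse_structure(p)
        assert len(polymer["A"]) == 1
        assert [r.name for r in hetero["A"]] == ["HOH"]

    def test_round_trip_preserves_inventory(self, tmp_path, toy_complex):
        chains = {res[0].chain_id: res for res in toy_complex.chains.values()}
        p = tmp_path / "toy.pdb"
        write_pdb(chains, p)
        polymer, _ = parse_structure(p)
        for cid, residues in chains.items():
            got = polymer[cid]
            assert [(r.name, r.seq_id) for r in got] == [
                (r.name, r.seq_id) for r in residues
            ]
            assert sum(len(r.atoms) for r in got) == sum(
                len(r.atoms) for r in residues
            )
            for r_in, r_out in zip(residues, got):
                for a_in, a_out in zip(r_in.atoms, r_out.atoms):
                    np.testing.assert_allclose(
                        a_in.coords, a_out.coords, atol=2e-3
                    )


def _fake_chain(chain_id, n):
    return [
        Residue("ALA", i + 1, "", chain_id,
                atoms=[])
        for i in range(n)
    ]


class TestChainRoles:
    def test_explicit_config(self):
        polymer = {c: _fake_chain(c, n) for c, n in
                   zip("ABCDE", (180, 190, 14, 110, 115))}
        cx = assign_chain_roles(polymer, {
            "A": "mhc_alpha", "B": "mhc_beta", "C": "peptide",
            "D": "tcr_alpha", "E": "tcr_beta",
        })
        assert set(cx.chains) == {"mhc_alpha", "mhc_beta", "peptide",
                                  "tcr_alpha", "tcr_beta"}
        assert len(cx.chains["peptide"]) == 14

    def test_peptide_autodetected_by_length(self):
        polymer = {c: _fake_chain(c, n) for c, n in
                   zip("ABCDE", (180, 190, 14, 110, 115))}
        cx = assign_chain_roles(polymer, {
            "A": "mhc_alpha", "B": "mhc_beta",
            "D": "tcr_alpha", "E": "tcr_beta",
        })
        assert cx.chains["peptide"][0].chain_id == "C"

    def test_apo_input_in_ternary_mode_fails(self):
        polymer = {c: _fake_chain(c, 110) for c in "DE"}
        with pytest.raises(RoleError):
            assign_chain_roles(
                polymer, {"D": "tcr_alpha", "E": "tcr_beta"}, mode="ternary"
            )

    def test_duplicate_role_rejected(self):
        polymer = {c: _fake_chain(c, 110) for c in "DE"}
        with pytest.raises(RoleError):
            assign_chain_roles(
                polymer, {"D": "tcr_alpha", "E": "tcr_alpha"}, mode="apo"
            )


class TestImgtRegions:
    @pytest.mark.parametrize(
        "seq_id, expected",
        [(109, "CDR3"), (113, "CDR3"), (57, "CDR2"), (58, "CDR2"),
         (55, "FW"), (27, "CDR1"), (38, "CDR1"), (39, "FW"), (104, "FW")],
    )
    def test_default_imgt_boundaries(self, seq_id, expected):
        chain = [Residue("ALA", seq_id, "", "D")]
        ann = assign_imgt_regions(chain)
        assert ann.label_of(seq_id) == expected

    def test_labels_partition_variable_domain(self):
        chain = [Residue("ALA", i, "", "D") for i in range(1, 130)]
        ann = assign_imgt_regions(chain)
        assert len(ann.labels) == 129
        assert all(v in ("CDR1", "CDR2", "CDR3", "FW")
                   for v in ann.labels.values())

    def test_constant_domain_unlabelled(self):
        chain = [Residue("ALA", i, "", "D") for i in (100, 150, 200)]
        ann = assign_imgt_regions(chain)
        assert ann.label_of(100) == "FW"
        assert ann.label_of(150) is None and ann.label_of(200) is None

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            assign_imgt_regions([], {"CDR1": (27, 60), "CDR2": (56, 65)})


class TestRegister:
    def test_epitope_register_anchored_at_p1(self, toy_complex, toy_truth):
        reg = assign_peptide_register(
            toy_complex.chains["peptide"], toy_truth.p1_seq_id
        )
        for seq_id, pocket in toy_truth.register.items():
            assert reg.pocket_of(seq_id) == pocket

    def test_p1_at_first_residue_of_9mer(self):
        chain = [Residue("ALA", i, "", "C") for i in range(1, 10)]
        reg = assign_peptide_register(chain, 1)
        assert [reg.pocket_of(i) for i in range(1, 10)] == [
            f"P{k}" for k in range(1, 10)
        ]

    def test_solubility_lysines_labelled_flank(self):
        cx, truth = make_toy_complex(ToyComplexSpec(flank_lysines=True))
        reg = assign_peptide_register(cx.chains["peptide"], truth.p1_seq_id)
        assert reg.pocket_of(1025) == "flank"
        assert reg.pocket_of(1026) == "flank"

    def test_missing_anchor_raises(self, toy_complex):
        with pytest.raises(RegisterError):
            assign_peptide_register(toy_complex.chains["peptide"], 9999)

    def test_pocket_order_strictly_increases(self, toy_complex, toy_truth):
        reg = assign_peptide_register(
            toy_complex.chains["peptide"], toy_truth.p1_seq_id
        )
        indices = []
        for res in toy_complex.chains["peptide"]:
            label = reg.pocket_of(res.seq_id)
            if label != "flank":
                indices.append(int(label[1:]))
        assert indices == sorted(indices)
        assert len(set(indices)) == len(indices)
        assert indices.count(1) == 1


class TestSharedEpitope:
    @pytest.mark.parametrize("motif", ["QKRAA", "QRRAA", "RRRAA"])
    def test_risk_motifs_positive(self, motif):
        seq = "A" * 69 + motif + "A" * 10
        res = detect_shared_epitope(seq)
        assert res.positive and res.motif == motif

    def test_protective_window_negative(self):
        seq = "A" * 69 + "DERAA" + "A" * 10
        res = detect_shared_epitope(seq)
        assert not res.positive and res.motif == "" and res.window == "DERAA"

    def test_case_insensitive(self):
        seq = "a" * 69 + "qkraa" + "a" * 10
        assert detect_shared_epitope(seq).positive

    def test_numbering_offset(self):
        # sequence starting at mature position 65
        seq = "AAAAA" + "QRRAA" + "AAAAA"
        assert detect_shared_epitope(seq, numbering_offset=65).positive

    def test_incomplete_window_raises(self):
        with pytest.raises(CoverageError):
            detect_shared_epitope("QKRAA")  # starts at position 1, window at 70

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=74, max_size=90))
    def test_result_depends_only_on_window(self, seq):
        res = detect_shared_epitope(seq)
        scrambled = seq[:69][::-1] + seq[69:74] + seq[74:][::-1]
        assert detect_shared_epitope(scrambled).positive == res.positive

    def test_toy_mhc_beta_carries_motif(self, toy_complex, toy_truth):
        beta = toy_complex.chains["mhc_beta"]
        res = detect_shared_epitope(chain_sequence(beta), beta[0].seq_id)
        assert res.positive and res.motif == toy_truth.se_motif
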