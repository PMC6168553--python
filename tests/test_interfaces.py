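import numpy as np
import pandas as pd
import pytest

from helifil.assembly import ATOM_COLUMNS, Structure, build_filament
from helifil.interfaces import (
    InterfaceAnnotation,
    classify_offsets,
    interface_report,
    load_default_annotations,
    mutation_burial,
    subunit_contacts,
)
from helifil.simulate import make_toy_monomer
from helifil.symmetry import HelicalSymmetry

SYM = HelicalSymmetry(-101.124, 4.848, "left")


def brute_force_contacts(assembly, cutoff, max_offset, ref_index=0):
    """All-pairs oracle over heavy atoms."""
    chains = assembly.chains()
    out = {}
    for k in range(1, max_offset + 1):
        ref = assembly.atoms[
            (assembly.atoms["chain"] == chains[ref_index])
            & ~assembly.atoms["element"].str.upper().eq("H")
        ]
        other = assembly.atoms[
            (assembly.atoms["chain"] == chains[ref_index + k])
            & ~assembly.atoms["element"].str.upper().eq("H")
        ]
        pairs = set()
        for ri in ref.itertuples():
            for rj in other.itertuples():
                d = np.sqrt((ri.x - rj.x) ** 2 + (ri.y - rj.y) ** 2 + (ri.z - rj.z) ** 2)
                if d <= cutoff:
                    pairs.add((ri.resnum, ri.name, rj.resnum, rj.name, round(d, 9)))
        out[k] = pairs
    return out


def contact_set(contacts):
    return {
        (c.resnum_i, c.atom_i, c.resnum_j, c.atom_j, round(c.distance, 9)) for c in contacts
    }


@pytest.fixture(scope="module")
def toy_assembly():
    monomer = Structure(make_toy_monomer(radius_ang=10.0))
    return build_filament(monomer, SYM, (0, 8))


class TestSubunitContacts:
    def test_far_apart_subunits_have_no_contacts(self):
        rows = [
            (1, "CA", "ALA", 1, "A", 0.0, 0.0, 0.0, "C"),
            (2, "CA", "ALA", 1, "B", 10.0, 0.0, 0.0, "C"),
        ]
        asm = Structure(pd.DataFrame(rows, columns=ATOM_COLUMNS))
        assert subunit_contacts(asm, 4.0, 1) == {1: []}

    def test_single_planted_pair(self):
        rows = [
            (1, "CA", "ALA", 1, "A", 0.0, 0.0, 0.0, "C"),
            (2, "CB", "ALA", 1, "A", 20.0, 0.0, 0.0, "C"),
            (3, "CA", "ALA", 2, "B", 3.5, 0.0, 0.0, "C"),
        ]
        asm = Structure(pd.DataFrame(rows, columns=ATOM_COLUMNS))
        contacts = subunit_contacts(asm, 4.0, 1)[1]
        assert len(contacts) == 1
        c = contacts[0]
        assert (c.resnum_i, c.atom_i, c.resnum_j) == (1, "CA", 2)
        assert c.distance == pytest.approx(3.5)

    def test_matches_brute_force_oracle(self, toy_assembly):
        got = subunit_contacts(toy_assembly, 4.0, 3)
        oracle = brute_force_contacts(toy_assembly, 4.0, 3)
        assert any(oracle[k] for k in oracle), "toy lattice must produce contacts"
        for k in (1, 2, 3):
            assert contact_set(got[k]) == oracle[k]

    def test_translational_symmetry(self, toy_assembly):
        """Contacts between subunits (m, m+k) match (0, k) in residues and
        distances."""
        base = subunit_contacts(toy_assembly, 4.0, 3, ref_index=0)
        shifted = subunit_contacts(toy_assembly, 4.0, 3, ref_index=3)
        assert any(base[k] for k in base)
        for k in (1, 2, 3):
            a = sorted((c.resnum_i, c.atom_i, c.resnum_j, c.atom_j) for c in base[k])
            b = sorted((c.resnum_i, c.atom_i, c.resnum_j, c.atom_j) for c in shifted[k])
            assert a == b
            da = sorted(c.distance for c in base[k])
            db = sorted(c.distance for c in shifted[k])
            assert np.allclose(da, db, atol=1e-6)

    def test_too_few_subunits_rejected(self, toy_assembly):
        with pytest.raises(ValueError, match="subunits"):
            subunit_contacts(toy_assembly, 4.0, 20)


class TestClassifyOffsets:
    def planted_annotations(self):
        return [
            InterfaceAnnotation("I", frozenset({444, 448}), frozenset({457, 461})),
            InterfaceAnnotation("II", frozenset({470}), frozenset({455})),
            InterfaceAnnotation("III", frozenset({472, 475}), frozenset({483, 488})),
        ]

    def make_contact(self, k, ri, rj):
        from helifil.interfaces import Contact

        return Contact(k, ri, "CB", rj, "CB", 3.5)

    def test_exact_annotation_match_scores_one(self):
        contacts = {1: [self.make_contact(1, 444, 461), self.make_contact(1, 448, 457)]}
        out = classify_offsets(contacts, self.planted_annotations())
        assert out[1] == ("I", pytest.approx(1.0))

    def test_empty_offset_is_other(self):
        out = classify_offsets({2: []}, self.planted_annotations())
        assert out[2] == ("other", 0.0)

    def test_planted_mapping_recovered(self):
        contacts = {
            1: [self.make_contact(1, 470, 455)],
            2: [self.make_contact(2, 472, 483), self.make_contact(2, 475, 488)],
            3: [self.make_contact(3, 461, 444)],  # reversed orientation
        }
        out = classify_offsets(contacts, self.planted_annotations())
        assert out[1][0] == "II"
        assert out[2][0] == "III"
        assert out[3][0] == "I"

    def test_scores_within_unit_interval_and_permutation_stable(self):
        contacts = {1: [self.make_contact(1, 470, 455), self.make_contact(1, 444, 461)]}
        out1 = classify_offsets(contacts, self.planted_annotations())
        contacts_rev = {1: list(reversed(contacts[1]))}
        out2 = classify_offsets(contacts_rev, self.planted_annotations())
        assert out1 == out2
        assert 0.0 <= out1[1][1] <= 1.0


class TestInterfaceReport:
    def salt_bridge_toy(self):
        rows = [
            (1, "NH1", "ARG", 444, "A", 0.0, 0.0, 0.0, "N"),
            (2, "CA", "ARG", 444, "A", 1.5, 0.0, 0.0, "C"),
            (3, "OE1", "GLU", 461, "B", 3.2, 0.0, 0.0, "O"),
            (4, "CA", "GLU", 461, "B", 4.5, 0.0, 0.0, "C"),
        ]
        return Structure(pd.DataFrame(rows, columns=ATOM_COLUMNS))

    def test_planted_salt_bridge_flagged(self):
        asm = self.salt_bridge_toy()
        ann = [InterfaceAnnotation("I", frozenset({444}), frozenset({461}), ((444, 461),))]
        rep = interface_report(asm, ann, cutoff=4.0, max_offset=1)
        row = rep.iloc[0]
        assert row["found"] and row["salt_bridge"]
        assert row["min_distance_ang"] == pytest.approx(1.7)  # CA(444)-OE1(461)

    def test_absent_pair_reports_distance(self):
        asm = self.salt_bridge_toy()
        ann = [InterfaceAnnotation("I", frozenset({444}), frozenset({461}), ((444, 461),))]
        rep = interface_report(asm, ann, cutoff=0.5, max_offset=1)
        assert not rep.iloc[0]["found"]
        assert np.isfinite(rep.iloc[0]["min_distance_ang"])

    def test_annotation_outside_model_range_rejected(self):
        asm = self.salt_bridge_toy()
        ann = [InterfaceAnnotation("I", frozenset({444, 999}), frozenset({461}))]
        with pytest.raises(ValueError, match="outside"):
            interface_report(asm, ann, max_offset=1)

    def test_default_annotations_cover_three_types(self):
        anns = load_default_annotations()
        assert {a.type_label for a in anns} == {"I", "II", "III"}
        pair_set = {p for a in anns for p in a.pairs}
        assert (444, 461) in pair_set and (448, 457) in pair_set
        assert (470, 455) in pair_set
        assert (472, 488) in pair_set and (475, 483) in pair_set


class TestMutationBurial:
    def test_counts_match_brute_force(self, toy_assembly):
        residues = sorted(set(toy_assembly.atoms["resnum"]))
        out = mutation_burial(toy_assembly, residues, 4.0, 3)
        oracle = brute_force_contacts(toy_assembly, 4.0, 3)
        for row in out.itertuples():
            expected = sum(
                1
                for k, pairs in oracle.items()
                for (ri, _, rj, _, _) in pairs
                if row.resnum in (ri, rj)
            )
            assert row.n_contacts == expected

    def test_isolated_residue_has_zero(self):
        rows = [
            (1, "CA", "ALA", 1, "A", 0.0, 0.0, 0.0, "C"),
            (2, "CA", "ALA", 2, "B", 50.0, 0.0, 0.0, "C"),
        ]
        asm = Structure(pd.DataFrame(rows, columns=ATOM_COLUMNS))
        out = mutation_burial(asm, [1], 4.0, 1)
        assert out.iloc[0]["n_contacts"] == 0

    def test_unknown_residue_rejected(self, toy_assembly):
        with pytest.raises(ValueError, match="residue"):
            mutation_burial(toy_assembly, [9999], 4.0, 1)

    def test_study_mutation_list_is_coverable(self):
        """The eight type-II surface positions all fall inside the modelled
        433-518 range used by the bundled annotations."""
        mutated = [470, 497, 450, 452, 453, 455, 458, 512]
        anns = load_default_annotations()
        type2 = next(a for a in anns if a.type_label == "II")
        assert set(mutated) <= (set(type2.surface_a) | set(type2.surface_b))
        assert all(433 <= r <= 518 for r in mutated)
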