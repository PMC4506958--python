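import numpy as np
import pytest

import bindmode as bm
from bindmode.interactions import InteractionRules, classify_pair, table_from_tsv
from bindmode.structure_io import Model
from conftest import toy_atom
from _oracles import random_rigid_transform

RULES = InteractionRules()


def _pair(p_name, p_res, l_name, l_element, d, p_element=None):
    """Protein atom at origin, ligand atom d Angstrom along +x."""
    p_el = p_element or p_name[0]
    prot = toy_atom(1, p_name, p_res, 100, (0, 0, 0), p_el)
    lig = toy_atom(2, l_name, "LIG", 701, (d, 0, 0), l_element, is_het=True)
    return prot, lig


class TestClassifyPair:
    def test_serine_hydroxyl_to_carboxylate_is_hb(self):
        prot, lig = _pair("OG", "SER", "OAC", "O", 2.74)
        ctx = {"protein_antecedent": np.array([-1.4, 0.0, 0.0])}  # angle 180
        assert classify_pair(prot, lig, 2.74, RULES, ctx) == "HB"

    def test_arginine_to_carboxylate_beyond_hb_range_is_es(self):
        prot, lig = _pair("NH1", "ARG", "OAA", "O", 3.51)
        assert classify_pair(prot, lig, 3.51, RULES) == "ES"

    def test_carbon_pair_beyond_contact_max_is_nothing(self):
        prot, lig = _pair("CB", "ALA", "CAT", "C", 3.50)
        assert classify_pair(prot, lig, 3.50, RULES) is None

    def test_carbon_pair_within_contact_max_is_np(self):
        prot, lig = _pair("CB", "ALA", "CAT", "C", 3.20)
        assert classify_pair(prot, lig, 3.20, RULES) == "NP"

    def test_failed_angle_downgrades_hb_to_np(self):
        prot, lig = _pair("OG", "SER", "OAC", "O", 3.0)
        ctx = {"protein_antecedent": np.array([1.4, 0.5, 0.0])}  # ~20 degrees
        assert classify_pair(prot, lig, 3.0, RULES, ctx) == "NP"

    def test_charged_pair_inside_hb_range_is_hb_not_es(self):
        prot, lig = _pair("NE", "ARG", "OAC", "O", 2.88)
        assert classify_pair(prot, lig, 2.88, RULES) == "HB"

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            InteractionRules(contact_max=4.5, es_max=4.0)


class TestBuildTable:
    def test_constructed_geometry_one_of_each(self):
        model = bm.make_interaction_fixture(1, 1, 1, 1)
        table = bm.build_interaction_table(model, bm.select(model, het=True, water=False))
        assert table.counts() == {"HB": 1, "NP": 1, "ES": 1, "water_HB": 1}

    def test_partition_property(self):
        model = bm.make_interaction_fixture(3, 4, 2, 2)
        table = bm.build_interaction_table(model, bm.select(model, het=True, water=False))
        s = bm.summarize_recognition(table)
        assert s.n_hb + s.n_np + s.n_es == len(table.contacts)
        assert s.n_water_hb == len(table.bridges)

    def test_distant_ligand_gives_empty_table(self):
        model = bm.make_interaction_fixture(1, 1, 1, 0)
        coords = model.coords()
        lig = bm.select(model, het=True, water=False)
        for i in lig:
            coords[i] += np.array([0.0, 500.0, 0.0])
        table = bm.build_interaction_table(model.with_coords(coords), lig)
        assert table.contacts == [] and table.bridges == []

    def test_empty_ligand_selection_is_an_error(self, receptor):
        with pytest.raises(ValueError, match="empty"):
            bm.build_interaction_table(receptor, bm.select(receptor, het=True))

    def test_contact_max_monotonicity(self):
        model = bm.make_interaction_fixture(2, 3, 1, 1)
        lig = bm.select(model, het=True, water=False)
        narrow = bm.build_interaction_table(model, lig, InteractionRules())
        wide = bm.build_interaction_table(
            model, lig, InteractionRules(contact_max=3.9, es_max=4.0))
        assert len(wide.contacts) >= len(narrow.contacts)

    def test_rigid_motion_invariance(self):
        model = bm.make_interaction_fixture(2, 2, 1, 1)
        lig = bm.select(model, het=True, water=False)
        table = bm.build_interaction_table(model, lig)
        R, t = random_rigid_transform(np.random.default_rng(7))
        moved = model.with_coords(model.coords() @ R.T + t)
        table2 = bm.build_interaction_table(moved, lig)
        assert [(c.protein_resseq, c.protein_atom, c.ligand_atom, c.itype)
                for c in table.contacts] == \
               [(c.protein_resseq, c.protein_atom, c.ligand_atom, c.itype)
                for c in table2.contacts]
        assert np.allclose([c.distance for c in table.contacts],
                           [c.distance for c in table2.contacts], atol=1e-9)

    def test_tsv_round_trip_and_determinism(self):
        model = bm.make_interaction_fixture(2, 3, 1, 2)
        lig = bm.select(model, het=True, water=False)
        table = bm.build_interaction_table(model, lig)
        tsv = bm.table_to_tsv(table)
        assert tsv == bm.table_to_tsv(table)  # byte-identical
        back = table_from_tsv(tsv)
        assert back.counts() == table.counts()
        assert len(back.bridges) == len(table.bridges)


class TestPublishedRecognitionTable:
    """Checks against the published Keap1-ligand recognition table."""

    def test_soaking_form_summary(self):
        s = bm.summarize_recognition(bm.datasets.keap1_ligand1_contact_table("soaking"))
        assert s.n_residues == 10
        assert (s.n_hb, s.n_water_hb, s.n_es, s.n_np) == (1, 1, 3, 19)
        assert [r for r in s.residues] == [
            ("TYR", 334), ("SER", 363), ("ARG", 380), ("ASN", 382), ("ASN", 414),
            ("ARG", 415), ("ARG", 483), ("SER", 508), ("ALA", 556), ("GLY", 603)]

    def test_cocrystallization_form_summary(self):
        s = bm.summarize_recognition(
            bm.datasets.keap1_ligand1_contact_table("cocrystallization"))
        assert s.n_residues == 7
        assert (s.n_hb, s.n_water_hb, s.n_np) == (5, 3, 11)

    def test_empty_table_summary(self):
        s = bm.summarize_recognition(bm.InteractionTable(contacts=[], bridges=[]))
        assert s.n_residues == 0
        assert (s.n_hb, s.n_water_hb, s.n_np, s.n_es) == (0, 0, 0, 0)

    def test_printed_distances_are_consistent_with_the_rules(self):
        """Every printed row respects its own type's distance bound, and every
        electrostatic row lies in the shell above hydrogen-bond range."""
        rules = InteractionRules()
        for form in ("soaking", "cocrystallization"):
            table = bm.datasets.keap1_ligand1_contact_table(form)
            for c in table.contacts:
                bound = rules.es_max if c.itype == "ES" else rules.contact_max
                assert c.distance <= bound
                if c.itype == "ES":
                    assert c.distance > rules.hb_max
            for b in table.bridges:
                assert b.d_protein_water <= rules.hb_max
                assert b.d_water_ligand <= rules.hb_max
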