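import re
from collections import defaultdict

import pytest

from cliffscape._chem import canonical_smiles, heavy_atom_count
from cliffscape.mmp_engine import (
    DataError,
    MMPTransformation,
    SizeRestrictedMMP,
    apply_size_restrictions,
    compare_with_sas,
    find_mmp_cliffs,
    fragment_molecule,
    index_mmps,
    passes_size_criteria,
)
from cliffscape.similarity import PairAssessment


def _t(id_i, id_j, fi, fj, const_heavy, frag_i="A", frag_j="B", n_cuts=1, const="K"):
    return MMPTransformation(
        id_i=id_i, id_j=id_j, constant_smiles=const,
        frag_i_smiles=frag_i, frag_j_smiles=frag_j,
        frag_i_heavy=fi, frag_j_heavy=fj, constant_heavy=const_heavy, n_cuts=n_cuts,
    )


class TestFragmentation:
    def test_ethylbenzene_single_cut(self):
        # hand enumeration: two acyclic C-C bonds -> four oriented splits
        frags = fragment_molecule("CCc1ccccc1", max_cuts=1, hydrogen_substitution=False)
        got = {(f.constant_smiles, f.variable_smiles) for f in frags}
        assert got == {
            ("c1ccc(C[*:1])cc1", "C[*:1]"),
            ("C[*:1]", "c1ccc(C[*:1])cc1"),
            ("c1ccc([*:1])cc1", "CC[*:1]"),
            ("CC[*:1]", "c1ccc([*:1])cc1"),
        }

    def test_benzene_only_hydrogen_substitution(self):
        assert fragment_molecule("c1ccccc1", hydrogen_substitution=False) == []
        frags = fragment_molecule("c1ccccc1", hydrogen_substitution=True)
        assert {f.variable_smiles for f in frags} == {"[H][*:1]"}
        assert all(f.variable_heavy == 0 for f in frags)
        # all H positions equivalent -> one record
        assert len(frags) == 1

    def test_methane_no_heavy_variable(self):
        frags = fragment_molecule("C")
        assert all(f.variable_heavy == 0 for f in frags)

    def test_invalid(self):
        with pytest.raises(ValueError):
            fragment_molecule("C1CC")

    def test_multicomponent_rejected(self):
        with pytest.raises(ValueError):
            fragment_molecule("CC.CC")

    def test_heavy_atom_conservation(self, small_curated):
        records, _, _ = small_curated
        for rec in records[:8]:
            parent = heavy_atom_count(rec.canonical_smiles)
            for f in fragment_molecule(rec.canonical_smiles, max_cuts=3, parent_id=rec.chem_id):
                assert f.constant_heavy + f.variable_heavy == parent
                assert f.n_cuts in (1, 2, 3)

    def test_attachment_labels_pair_off(self):
        for f in fragment_molecule("CCc1ccc(CNC(C)=O)cc1", max_cuts=3):
            c_labels = sorted(map(int, re.findall(r"\[\*:(\d+)\]", f.constant_smiles)))
            v_labels = sorted(map(int, re.findall(r"\[\*:(\d+)\]", f.variable_smiles)))
            assert c_labels == v_labels == list(range(1, f.n_cuts + 1))


class TestIndexing:
    def test_toluene_chlorobenzene(self):
        frags = {
            "toluene": fragment_molecule("Cc1ccccc1", parent_id="toluene", hydrogen_substitution=False),
            "chloro": fragment_molecule("Clc1ccccc1", parent_id="chloro", hydrogen_substitution=False),
        }
        (t,) = index_mmps(frags)
        assert t.pair == ("chloro", "toluene")
        assert t.constant_smiles == "c1ccc([*:1])cc1"
        assert {t.frag_i_smiles, t.frag_j_smiles} == {"C[*:1]", "Cl[*:1]"}

    def test_hydrogen_for_fragment_exchange(self):
        # vinyl H replaced by a nitro group: found only via H-substitution
        frags = {
            "styrene": fragment_molecule("C=Cc1ccccc1", parent_id="styrene"),
            "nitrostyrene": fragment_molecule("O=[N+]([O-])C=Cc1ccccc1", parent_id="nitrostyrene"),
        }
        pairs = {t.pair for t in index_mmps(frags)}
        assert ("nitrostyrene", "styrene") in pairs

    def test_identical_molecules_no_mmp(self):
        frags = {
            "a": fragment_molecule("Cc1ccccc1", parent_id="a"),
            "b": fragment_molecule("Cc1ccccc1", parent_id="b"),
        }
        assert index_mmps(frags) == []

    def test_order_invariance(self, fixtures):
        mols = fixtures["mmp_basic"].molecules
        frags = {n: fragment_molecule(s, parent_id=n) for n, s in mols.items()}
        rev = dict(reversed(list(frags.items())))
        assert index_mmps(frags) == index_mmps(rev)

    def test_micro_fixture_pairs(self, fixtures):
        fx = fixtures["mmp_basic"]
        no_h = {n: fragment_molecule(s, parent_id=n, hydrogen_substitution=False)
                for n, s in fx.molecules.items()}
        pairs_no_h = {t.pair for t in index_mmps(no_h)}
        assert pairs_no_h == fx.expected["pairs_no_h"]
        with_h = {n: fragment_molecule(s, parent_id=n) for n, s in fx.molecules.items()}
        pairs_h = {t.pair for t in index_mmps(with_h)}
        assert pairs_h == fx.expected["pairs_no_h"] | fx.expected["extra_pairs_with_h"]
        shared = fx.expected["shared_constant"]
        assert any(t.constant_smiles == shared for t in index_mmps(with_h))

    def test_planted_mmp_recovery(self, small_curated):
        records, _, truth = small_curated
        frags = {
            r.chem_id: fragment_molecule(r.canonical_smiles, parent_id=r.chem_id)
            for r in records
        }
        by_pair = defaultdict(set)
        for t in index_mmps(frags):
            by_pair[t.pair].add(t.constant_smiles)
        for pair, const in truth.planted_mmp_pairs.items():
            assert const in by_pair.get(pair, set()), pair


class TestSizeRestrictions:
    def test_boundary_kept(self):
        assert passes_size_criteria(_t("a", "b", 13, 5, 26))

    def test_criterion_iii(self):
        assert not passes_size_criteria(_t("a", "b", 14, 6, 40))

    def test_criterion_i(self):
        assert not passes_size_criteria(_t("a", "b", 12, 3, 40))

    def test_criterion_ii_both_sides(self):
        assert not passes_size_criteria(_t("a", "b", 10, 5, 19))
        assert not passes_size_criteria(_t("a", "b", 5, 10, 19))
        assert passes_size_criteria(_t("a", "b", 10, 5, 20))

    def test_hydrogen_fragment_vacuous(self):
        assert passes_size_criteria(_t("a", "b", 0, 8, 16))

    def test_criterion_iv_least_difference(self):
        survivors = apply_size_restrictions(
            [_t("a", "b", 5, 2, 30, const="K1"), _t("a", "b", 4, 3, 30, const="K2")]
        )
        (s,) = survivors
        assert s.transformation.constant_smiles == "K2"
        assert abs(s.transformation.frag_i_heavy - s.transformation.frag_j_heavy) == 1

    def test_one_per_pair(self, small_curated):
        records, _, _ = small_curated
        frags = {
            r.chem_id: fragment_molecule(r.canonical_smiles, parent_id=r.chem_id)
            for r in records
        }
        mmps = index_mmps(frags)
        restricted = apply_size_restrictions(mmps)
        pairs = [m.pair for m in restricted]
        assert len(pairs) == len(set(pairs))
        for m in restricted:
            assert passes_size_criteria(m.transformation)
        # monotone chain: restricted pairs are indexed pairs
        assert set(pairs) <= {t.pair for t in mmps}


class TestCliffs:
    def test_threshold(self):
        restricted = [
            SizeRestrictedMMP(_t("a", "b", 1, 2, 10)),
            SizeRestrictedMMP(_t("c", "d", 1, 2, 10)),
        ]
        pac50 = {"a": 6.09, "b": 4.0, "c": 5.99, "d": 4.0}
        cliffs = find_mmp_cliffs(restricted, pac50)
        assert [m.pair for m in cliffs] == [("a", "b")]
        assert restricted[0].activity_diff == pytest.approx(2.09)
        assert not restricted[1].is_cliff

    def test_missing_pac50(self):
        with pytest.raises(DataError, match="b"):
            find_mmp_cliffs([SizeRestrictedMMP(_t("a", "b", 1, 2, 10))], {"a": 5.0})

    def test_planted_jump(self, small_curated):
        records, _, truth = small_curated
        frags = {
            r.chem_id: fragment_molecule(r.canonical_smiles, parent_id=r.chem_id)
            for r in records
        }
        restricted = apply_size_restrictions(index_mmps(frags))
        cliffs = find_mmp_cliffs(restricted, {r.chem_id: r.pac50 for r in records})
        assert {m.pair for m in cliffs} <= truth.planted_cliff_pairs
        assert all(m.activity_diff >= 2.0 for m in cliffs)


class TestCompareWithSAS:
    def test_disjoint(self):
        report = compare_with_sas(
            [SizeRestrictedMMP(_t("a", "b", 1, 1, 10))],
            [PairAssessment("c", "d", 0.9, 2.5)],
        )
        assert report["n_intersection"] == 0
        assert not report["mmp_subset_of_sas"]

    def test_identical(self):
        mmps = [SizeRestrictedMMP(_t("a", "b", 1, 1, 10))]
        sas = [PairAssessment("a", "b", 0.9, 2.5)]
        report = compare_with_sas(mmps, sas)
        assert report["n_intersection"] == report["n_mmp_cliff_pairs"] == report["n_sas_cliffs"] == 1
        assert report["mmp_subset_of_sas"]
        assert report["n_mmp_directed"] == 2

    def test_mmp_subset_on_synthetic(self, small_curated):
        from cliffscape.sas_landscape import SASThresholds, find_activity_cliffs
        from cliffscape.similarity import pairwise_table

        records, _, _ = small_curated
        sas_cliffs, _ = find_activity_cliffs(pairwise_table(records), SASThresholds())
        frags = {
            r.chem_id: fragment_molecule(r.canonical_smiles, parent_id=r.chem_id)
            for r in records
        }
        restricted = apply_size_restrictions(index_mmps(frags))
        mmp_cliffs = find_mmp_cliffs(restricted, {r.chem_id: r.pac50 for r in records})
        report = compare_with_sas(mmp_cliffs, sas_cliffs)
        assert report["mmp_subset_of_sas"]
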