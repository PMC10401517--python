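from itertools import product

import pytest

from cliffscape._chem import canonical_smiles
from cliffscape.cliff_classifier import (
    LABELS,
    classify_cliffs,
    classify_pair,
    compute_cyclic_skeleton,
    compute_scaffold,
    decompose_rgroups,
    label_from_comparisons,
)


def _dec(smiles, chem_id=""):
    return decompose_rgroups(canonical_smiles(smiles), chem_id=chem_id)


class TestScaffold:
    def test_toluene(self):
        assert compute_scaffold("Cc1ccccc1") == canonical_smiles("c1ccccc1")

    def test_bibenzyl_linker_retained(self):
        assert compute_scaffold("c1ccccc1CCc1ccccc1") == canonical_smiles("c1ccc(CCc2ccccc2)cc1")

    def test_acyclic_raises(self):
        with pytest.raises(ValueError):
            compute_scaffold("CCCCCC")

    def test_catechol_series_share_scaffold(self):
        # ring-hydroxyls are side chains: both collapse to the same core
        a = compute_scaffold("CC(C)NCC(O)c1ccc(O)c(O)c1")  # isoproterenol
        b = compute_scaffold("CNCC(O)c1ccc(O)c(O)c1")      # epinephrine-like analog
        assert a == b


class TestSkeleton:
    def test_pyridine_equals_benzene(self, fixtures):
        fx = fixtures["skeleton"]
        sk = {compute_cyclic_skeleton(compute_scaffold(s)) for s in fx.molecules.values()}
        assert (len(sk) == 1) is fx.expected["same_skeleton"]

    def test_biphenyl(self):
        sk_biphenyl = compute_cyclic_skeleton(canonical_smiles("c1ccc(-c2ccccc2)cc1"))
        sk_bicyclohexyl = compute_cyclic_skeleton(canonical_smiles("C1CCC(C2CCCCC2)CC1"))
        assert sk_biphenyl == sk_bicyclohexyl

    def test_depends_only_on_topology(self):
        assert compute_cyclic_skeleton("c1ccncc1") == compute_cyclic_skeleton("C1CCOCC1")

    def test_pentavalent_center(self):
        # skeletonization must survive centres whose carbon valence exceeds 4
        scaffold = compute_scaffold("O=P(Oc1ccccc1)(Oc1ccccc1)Oc1ccccc1")
        assert compute_cyclic_skeleton(scaffold)


class TestRGroupDecomposition:
    def test_para_cresol(self):
        dec = _dec("Cc1ccc(O)cc1")
        assert sorted(dec.rgroup_multiset.elements()) == ["*C", "*O"]

    def test_unsubstituted_benzene(self):
        assert _dec("c1ccccc1").attachments == ()

    def test_cresol_isomers_same_rgroups_different_sites(self, fixtures):
        fx = fixtures["topology"]
        do = _dec(fx.molecules["ortho_cresol"])
        dp = _dec(fx.molecules["para_cresol"])
        assert do.rgroup_multiset == dp.rgroup_multiset
        assert do.attachments != dp.attachments

    def test_scaffold_mismatch(self):
        from cliffscape.cliff_classifier import DecompositionError

        with pytest.raises(DecompositionError):
            decompose_rgroups("Cc1ccccc1", scaffold_smiles=canonical_smiles("c1ccncc1"))


class TestDecisionTree:
    def test_totality_and_exclusivity(self):
        seen = set()
        for combo in product([True, False], repeat=4):
            label = label_from_comparisons(*combo)
            assert label in LABELS
            seen.add(label)
        assert seen == set(LABELS)

    @pytest.mark.parametrize(
        "combo,label",
        [
            ((True, True, True, True), "chirality"),
            ((True, True, True, False), "topology"),
            ((True, True, False, True), "r_group"),
            ((False, True, True, True), "scaffold"),
            ((False, True, True, False), "scaffold_topology"),
            ((False, True, False, True), "scaffold_r_group"),
            ((False, False, True, True), "unclassified"),
        ],
    )
    def test_branch_mapping(self, combo, label):
        assert label_from_comparisons(*combo) == label


class TestClassifyPair:
    def test_topology_cresols(self, fixtures):
        fx = fixtures["topology"]
        do = _dec(fx.molecules["ortho_cresol"])
        dp = _dec(fx.molecules["para_cresol"])
        assert classify_pair(do, dp).label == fx.expected["label"]

    def test_r_group(self):
        assert classify_pair(_dec("Cc1ccccc1"), _dec("Oc1ccccc1")).label == "r_group"

    def test_isoproterenol_like_pair_is_r_group(self):
        a = _dec("CC(C)NCC(O)c1ccc(O)c(O)c1")
        b = _dec("CNCC(O)c1ccc(O)c(O)c1")
        assert classify_pair(a, b).label == "r_group"

    def test_scaffold(self):
        # benzene vs pyridine core, same methyl at an equivalent skeleton site
        assert classify_pair(_dec("Cc1ccccc1"), _dec("Cc1ccccn1")).label == "scaffold"

    def test_scaffold_topology(self):
        # ortho-dimethylbenzene vs para-ish dimethylpyridine: scaffolds differ,
        # skeletons equal, methyl pair not mappable by a ring automorphism
        assert classify_pair(_dec("Cc1ccccc1C"), _dec("Cc1ccc(C)nc1")).label == "scaffold_topology"

    def test_scaffold_r_group(self):
        assert classify_pair(_dec("Cc1ccccc1"), _dec("Clc1ccccn1")).label == "scaffold_r_group"

    def test_unclassified(self):
        assert classify_pair(_dec("Cc1ccccc1"), _dec("Cc1ccc2ccccc2c1")).label == "unclassified"

    def test_chirality_for_stereo_pair(self):
        a = _dec("C[C@H](O)c1ccccc1")
        b = _dec("C[C@@H](O)c1ccccc1")
        assert classify_pair(a, b).label == "chirality"

    def test_triphenyl_series(self):
        # hand-derived: hydroxide vs chloride share the triphenyl-metal
        # scaffold and differ only in the single substituent
        tin_oh = _dec("O[Sn](c1ccccc1)(c1ccccc1)c1ccccc1")
        tin_cl = _dec("Cl[Sn](c1ccccc1)(c1ccccc1)c1ccccc1")
        assert classify_pair(tin_oh, tin_cl).label == "r_group"
        # phosphate triester adds O linkers: different skeleton entirely
        phosphate = _dec("O=P(Oc1ccccc1)(Oc1ccccc1)Oc1ccccc1")
        assert classify_pair(tin_oh, phosphate).label == "unclassified"

    def test_symmetry(self):
        mols = [
            "Cc1ccccc1", "Oc1ccccc1", "Cc1ccccn1", "Cc1ccccc1C",
            "Cc1ccc(C)nc1", "Cc1ccc2ccccc2c1", "Cc1ccc(O)cc1", "Cc1ccccc1O",
        ]
        decs = [_dec(m, f"m{i}") for i, m in enumerate(mols)]
        for i in range(len(decs)):
            for j in range(i + 1, len(decs)):
                assert classify_pair(decs[i], decs[j]).label == classify_pair(decs[j], decs[i]).label

    def test_scaffold_equality_implies_skeleton_equality(self, small_curated):
        records, _, _ = small_curated
        decs = [_dec(r.canonical_smiles, r.chem_id) for r in records]
        for i in range(len(decs)):
            for j in range(i + 1, len(decs)):
                if decs[i].scaffold_smiles == decs[j].scaffold_smiles:
                    assert decs[i].skeleton_smiles == decs[j].skeleton_smiles


class TestClassifyCliffs:
    def test_batch(self, small_curated):
        records, _, truth = small_curated
        smiles = {r.chem_id: r.canonical_smiles for r in records}
        classified = classify_cliffs(sorted(truth.planted_cliff_pairs), smiles)
        assert len(classified) == len(truth.planted_cliff_pairs)
        # same-family substituent swaps share the scaffold: r_group cliffs
        assert {c.label for c in classified.values()} <= {"r_group", "topology", "chirality"}
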