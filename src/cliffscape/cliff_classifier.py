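"""Seven-type structural classification of activity cliffs.

Each chemical is decomposed into a Bemis-Murcko scaffold, its cyclic skeleton
(every heavy atom -> carbon, every bond -> single: ring topology only), and
R-groups with their attachment sites.  A cliff pair is then labelled by a
fixed decision tree:

    scaffolds equal?
      yes: R-groups equal?  yes: topology equal? yes -> chirality
                                                 no  -> topology
                            no -> r_group
      no:  skeletons equal? no -> unclassified
           yes: R-groups equal? no -> scaffold_r_group
                yes: topology equal? yes -> scaffold
                                     no  -> scaffold_topology

Topology equality compares attachment-site patterns (labelled by R-group) up
to graph automorphism of the shared scaffold or skeleton.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from cliffscape._chem import mol_from_smiles

LABELS = (
    "chirality",
    "topology",
    "r_group",
    "scaffold",
    "scaffold_topology",
    "scaffold_r_group",
    "unclassified",
)


@dataclass(frozen=True)
class ScaffoldDecomposition:
    chem_id: str
    scaffold_smiles: str
    skeleton_smiles: str
    #: sorted tuple of (scaffold_atom_idx, rgroup_smiles); atom indices refer
    #: to the mol parsed from the canonical scaffold_smiles, which also equal
    #: the skeleton atom indices (skeletonization preserves atom order).
    attachments: tuple[tuple[int, str], ...]

    @property
    def rgroup_multiset(self) -> Counter:
        return Counter(smi for _, smi in self.attachments)


@dataclass(frozen=True)
class CliffClassification:
    label: str
    evidence: dict = field(default_factory=dict, compare=False)


def compute_scaffold(canonical_smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold (ring systems + linkers)."""
    mol = mol_from_smiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {canonical_smiles!r}")
    if mol.GetRingInfo().NumRings() == 0:
        raise ValueError(f"acyclic molecule has no scaffold: {canonical_smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def _skeleton_mol(scaffold: Chem.Mol) -> Chem.Mol:
    """Scaffold graph with every heavy atom as carbon and every bond single.

    Built atom-for-atom so that skeleton atom i corresponds to scaffold atom i;
    valence sanitization is relaxed because e.g. pentacoordinate centres map to
    carbon with five single bonds.
    """
    rw = Chem.RWMol()
    for _ in range(scaffold.GetNumAtoms()):
        atom = Chem.Atom(6)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for bond in scaffold.GetBonds():
        rw.AddBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(
        mol,
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
    )
    return mol


def compute_cyclic_skeleton(scaffold_smiles: str) -> str:
    """Canonical cyclic skeleton: depends only on the scaffold's graph topology."""
    scaffold = mol_from_smiles(scaffold_smiles)
    if scaffold is None:
        raise ValueError(f"invalid scaffold: {scaffold_smiles!r}")
    return Chem.MolToSmiles(_skeleton_mol(scaffold))


class DecompositionError(ValueError):
    pass


def _rgroup_smiles(mol: Chem.Mol, component: list[int], attach_mol_idx: int, stereo_aware: bool) -> str:
    """Canonical SMILES of one R-group with a wildcard at the attachment bond."""
    rw = Chem.RWMol(mol)
    if not stereo_aware:
        Chem.RemoveStereochemistry(rw)
    keep = set(component)
    dummy = Chem.Atom(0)
    di = rw.AddAtom(dummy)
    # bond dummy to the component atom(s) bonded to the scaffold attachment atom
    bond_type = None
    for nb in mol.GetAtomWithIdx(attach_mol_idx).GetNeighbors():
        if nb.GetIdx() in keep:
            bond_type = mol.GetBondBetweenAtoms(attach_mol_idx, nb.GetIdx()).GetBondType()
            rw.AddBond(nb.GetIdx(), di, bond_type)
    keep.add(di)
    remove = [a.GetIdx() for a in rw.GetAtoms() if a.GetIdx() not in keep]
    for idx in sorted(remove, reverse=True):
        rw.RemoveAtom(idx)
    sub = rw.GetMol()
    try:
        Chem.SanitizeMol(sub)
    except Exception:
        Chem.SanitizeMol(
            sub,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        )
    return Chem.MolToSmiles(sub)


def decompose_rgroups(
    canonical_smiles: str,
    scaffold_smiles: str | None = None,
    chem_id: str = "",
    stereo_aware: bool = False,
) -> ScaffoldDecomposition:
    """Split a molecule into scaffold + R-groups with attachment sites.

    Multiple scaffold embeddings are resolved by taking, over all substructure
    matches, the lexicographically smallest sorted attachment list.
    """
    mol = mol_from_smiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {canonical_smiles!r}")
    if scaffold_smiles is None:
        scaffold_smiles = compute_scaffold(canonical_smiles)
    scaffold = mol_from_smiles(scaffold_smiles)
    if scaffold is None:
        raise ValueError(f"invalid scaffold: {scaffold_smiles!r}")
    matches = mol.GetSubstructMatches(scaffold, uniquify=True, maxMatches=5000)
    if not matches:
        raise DecompositionError(
            f"scaffold {scaffold_smiles!r} not found in {canonical_smiles!r}"
        )
    skeleton_smiles = compute_cyclic_skeleton(scaffold_smiles)

    best: tuple[tuple[int, str], ...] | None = None
    for match in matches:
        mol_to_scaf = {mi: si for si, mi in enumerate(match)}
        in_scaffold = set(match)
        # connected components of the non-scaffold atoms
        seen: set[int] = set()
        attachments: list[tuple[int, str]] = []
        ok = True
        for atom in mol.GetAtoms():
            idx = atom.GetIdx()
            if idx in in_scaffold or idx in seen:
                continue
            component = [idx]
            seen.add(idx)
            stack = [idx]
            attach_atoms: set[int] = set()
            while stack:
                cur = stack.pop()
                for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
                    ni = nb.GetIdx()
                    if ni in in_scaffold:
                        attach_atoms.add(ni)
                    elif ni not in seen:
                        seen.add(ni)
                        component.append(ni)
                        stack.append(ni)
            if len(attach_atoms) != 1:
                ok = False  # side chain bridging two scaffold atoms: bad embedding
                break
            attach_mol_idx = attach_atoms.pop()
            smi = _rgroup_smiles(mol, component, attach_mol_idx, stereo_aware)
            attachments.append((mol_to_scaf[attach_mol_idx], smi))
        if not ok:
            continue
        cand = tuple(sorted(attachments))
        if best is None or cand < best:
            best = cand
    if best is None:
        raise DecompositionError(
            f"no valid scaffold embedding for {canonical_smiles!r} with {scaffold_smiles!r}"
        )
    return ScaffoldDecomposition(
        chem_id=chem_id,
        scaffold_smiles=scaffold_smiles,
        skeleton_smiles=skeleton_smiles,
        attachments=best,
    )


def _isomorphism_respects_attachments(
    graph_i: Chem.Mol,
    graph_j: Chem.Mol,
    sites_i: Sequence[tuple[int, str]],
    sites_j: Sequence[tuple[int, str]],
) -> bool:
    """True if some graph isomorphism maps the labelled attachment multiset of
    i onto that of j."""
    target = Counter(sites_j)
    for mapping in graph_j.GetSubstructMatches(graph_i, uniquify=False, maxMatches=100000):
        mapped = Counter((mapping[idx], label) for idx, label in sites_i)
        if mapped == target:
            return True
    return False


def label_from_comparisons(
    scaffold_equal: bool,
    skeleton_equal: bool,
    rgroups_equal: bool,
    topology_equal: bool,
) -> str:
    """Pure decision tree over the four structural comparisons.

    Note scaffold equality implies skeleton equality in practice; the tree is
    still total over all 16 boolean combinations (the impossible ones resolve
    through the scaffold branch, which never consults the skeleton).
    """
    if scaffold_equal:
        if rgroups_equal:
            return "chirality" if topology_equal else "topology"
        return "r_group"
    if not skeleton_equal:
        return "unclassified"
    if not rgroups_equal:
        return "scaffold_r_group"
    return "scaffold" if topology_equal else "scaffold_topology"


def classify_pair(dec_i: ScaffoldDecomposition, dec_j: ScaffoldDecomposition) -> CliffClassification:
    """Apply the seven-type decision tree to two decompositions."""
    scaffold_equal = dec_i.scaffold_smiles == dec_j.scaffold_smiles
    skeleton_equal = dec_i.skeleton_smiles == dec_j.skeleton_smiles
    rgroups_equal = dec_i.rgroup_multiset == dec_j.rgroup_multiset

    evidence = {
        "scaffold_equal": scaffold_equal,
        "skeleton_equal": skeleton_equal,
        "rgroups_equal": rgroups_equal,
        "topology_equal": None,
    }

    def topology_equal(on_skeleton: bool) -> bool:
        smi = dec_i.skeleton_smiles if on_skeleton else dec_i.scaffold_smiles
        graph_i = mol_from_smiles(smi)
        graph_j = mol_from_smiles(dec_j.skeleton_smiles if on_skeleton else dec_j.scaffold_smiles)
        eq = _isomorphism_respects_attachments(
            graph_i, graph_j, dec_i.attachments, dec_j.attachments
        )
        evidence["topology_equal"] = eq
        return eq

    if scaffold_equal and rgroups_equal:
        topo = topology_equal(on_skeleton=False)
    elif not scaffold_equal and skeleton_equal and rgroups_equal:
        topo = topology_equal(on_skeleton=True)
    else:
        topo = True  # not consulted by the tree on these branches
    label = label_from_comparisons(scaffold_equal, skeleton_equal, rgroups_equal, topo)
    return CliffClassification(label=label, evidence=evidence)


def classify_cliffs(
    cliff_pairs: Sequence[tuple[str, str]],
    smiles_by_id: dict[str, str],
    stereo_aware: bool = False,
) -> dict[tuple[str, str], CliffClassification]:
    """Decompose once per chemical, classify every cliff pair."""
    cache: dict[str, ScaffoldDecomposition] = {}

    def dec(cid: str) -> ScaffoldDecomposition:
        if cid not in cache:
            cache[cid] = decompose_rgroups(
                smiles_by_id[cid], chem_id=cid, stereo_aware=stereo_aware
            )
        return cache[cid]

    return {(i, j): classify_pair(dec(i), dec(j)) for i, j in cliff_pairs}


def write_classification_csv(
    classified: dict[tuple[str, str], CliffClassification], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id_i", "id_j", "label", "scaffold_equal", "skeleton_equal", "rgroups_equal", "topology_equal"]
        )
        for (i, j), c in sorted(classified.items()):
            e = c.evidence
            writer.writerow(
                [i, j, c.label, e.get("scaffold_equal"), e.get("skeleton_equal"),
                 e.get("rgroups_equal"), e.get("topology_equal")]
            )
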