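"""Matched-molecular-pair generation by fragmentation/indexing, size
restriction and MMP-cliff calling.

A fragmentation splits a molecule into a *variable* fragment (touching every
cut bond) and a *constant* part (the remaining pieces, one attachment point
each).  Molecules sharing a canonical constant part but differing in the
variable fragment form an MMP.  Cut bonds are acyclic single bonds matched by
the Hussain-Rea cut pattern (the definition used by the standard MMP
platforms); stereochemistry is stripped before fragmenting, consistent with
the stereo-insensitive fingerprints used elsewhere in the pipeline.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from cliffscape._chem import mol_from_smiles
from cliffscape.activity_metrics import activity_difference
from cliffscape.similarity import PairAssessment

#: Default cut-bond definition: acyclic single bond from a neutral carbon (not
#: multiply bonded to a heteroatom) to any heavy atom.
CUT_SMARTS = "[#6+0;!$(*=,#[!#6])]!@!=!#[*]"


class DataError(KeyError):
    """A chemical referenced by an MMP has no activity value."""


@dataclass(frozen=True)
class Fragmentation:
    parent_id: str
    constant_smiles: str
    variable_smiles: str
    n_cuts: int
    constant_heavy: int
    variable_heavy: int


@dataclass(frozen=True)
class MMPTransformation:
    id_i: str
    id_j: str
    constant_smiles: str
    frag_i_smiles: str
    frag_j_smiles: str
    frag_i_heavy: int
    frag_j_heavy: int
    constant_heavy: int
    n_cuts: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_i, self.id_j)

    @property
    def transform(self) -> str:
        return f"{self.frag_i_smiles}>>{self.frag_j_smiles}"


@dataclass
class SizeRestrictedMMP:
    transformation: MMPTransformation
    activity_diff: float | None = None
    is_cliff: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return self.transformation.pair


def _strip_stereo(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    return mol


def _heavy_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _relabel(mol: Chem.Mol, perm: Mapping[int, int]) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum():
            atom.SetAtomMapNum(perm[atom.GetAtomMapNum()])
    return out


def _canonical_split(constant: Chem.Mol, variable: Chem.Mol, n_cuts: int) -> tuple[str, str]:
    """Canonical (constant, variable) SMILES pair, minimized over attachment-label
    permutations.  Minimizing the variable among label assignments that fix the
    minimal constant string makes matching robust to constant-part symmetry."""
    if n_cuts == 1:
        return Chem.MolToSmiles(constant), Chem.MolToSmiles(variable)
    labels = list(range(1, n_cuts + 1))
    best: tuple[str, str] | None = None
    for perm_t in permutations(labels):
        perm = dict(zip(labels, perm_t))
        cand = (
            Chem.MolToSmiles(_relabel(constant, perm)),
            Chem.MolToSmiles(_relabel(variable, perm)),
        )
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best


def _pieces_with_labels(frag_mol: Chem.Mol) -> list[tuple[Chem.Mol, set[int]]]:
    pieces = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False)
    out = []
    for piece in pieces:
        labels = {
            a.GetAtomMapNum()
            for a in piece.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum()
        }
        out.append((piece, labels))
    return out


def fragment_molecule(
    canonical_smiles: str,
    max_cuts: int = 3,
    parent_id: str = "",
    hydrogen_substitution: bool = True,
    cut_smarts: str = CUT_SMARTS,
) -> list[Fragmentation]:
    """Enumerate all 1..max_cuts fragmentations of a single-component molecule.

    Every combination of cuttable bonds whose removal leaves one piece adjacent
    to all cuts yields a fragmentation (that piece is the variable part).  For
    single cuts both orientations are emitted.  With ``hydrogen_substitution``,
    each distinct heavy atom carrying hydrogen additionally yields a
    fragmentation whose variable part is a single labelled hydrogen.
    """
    mol = mol_from_smiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {canonical_smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(f"expected a single-component structure: {canonical_smiles!r}")
    mol = _strip_stereo(mol)
    parent_heavy = _heavy_count(mol)

    pattern = Chem.MolFromSmarts(cut_smarts)
    cut_bonds = sorted(
        {
            mol.GetBondBetweenAtoms(i, j).GetIdx()
            for i, j in mol.GetSubstructMatches(pattern)
        }
    )

    found: set[tuple[str, str, int]] = set()
    results: list[Fragmentation] = []

    def emit(const_smi: str, var_smi: str, n_cuts: int, var_heavy: int) -> None:
        key = (const_smi, var_smi, n_cuts)
        if key in found:
            return
        found.add(key)
        results.append(
            Fragmentation(
                parent_id=parent_id,
                constant_smiles=const_smi,
                variable_smiles=var_smi,
                n_cuts=n_cuts,
                constant_heavy=parent_heavy - var_heavy,
                variable_heavy=var_heavy,
            )
        )

    for k in range(1, max_cuts + 1):
        if len(cut_bonds) < k:
            break
        for bond_set in combinations(cut_bonds, k):
            frag_mol = Chem.FragmentOnBonds(
                mol, list(bond_set), addDummies=True,
                dummyLabels=[(i + 1, i + 1) for i in range(k)],
            )
            # FragmentOnBonds marks dummies via isotope; move to atom maps.
            for atom in frag_mol.GetAtoms():
                if atom.GetAtomicNum() == 0 and atom.GetIsotope():
                    atom.SetAtomMapNum(atom.GetIsotope())
                    atom.SetIsotope(0)
            pieces = _pieces_with_labels(frag_mol)
            if len(pieces) != k + 1:
                continue  # a cut bond was shared; cannot happen for distinct bonds
            if k == 1:
                (p0, _), (p1, _) = pieces
                for var, const in ((p0, p1), (p1, p0)):
                    c, v = Chem.MolToSmiles(const), Chem.MolToSmiles(var)
                    emit(c, v, 1, _heavy_count(var))
            else:
                centers = [i for i, (_, labels) in enumerate(pieces) if len(labels) == k]
                if not centers:
                    continue  # no piece touches every cut: invalid cut set
                (ci,) = centers
                variable = pieces[ci][0]
                const_pieces = [p for i, (p, _) in enumerate(pieces) if i != ci]
                constant = const_pieces[0]
                for extra in const_pieces[1:]:
                    constant = Chem.CombineMols(constant, extra)
                c, v = _canonical_split(constant, variable, k)
                emit(c, v, k, _heavy_count(variable))

    if hydrogen_substitution:
        var_smi = "[H][*:1]"
        seen_const: set[str] = set()
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() < 1:
                continue
            rw = Chem.RWMol(mol)
            dummy = Chem.Atom(0)
            dummy.SetAtomMapNum(1)
            di = rw.AddAtom(dummy)
            rw.AddBond(atom.GetIdx(), di, Chem.BondType.SINGLE)
            ratom = rw.GetAtomWithIdx(atom.GetIdx())
            if ratom.GetNumExplicitHs() > 0:
                ratom.SetNumExplicitHs(ratom.GetNumExplicitHs() - 1)
            try:
                hmol = rw.GetMol()
                Chem.SanitizeMol(hmol)
            except Exception:
                continue
            c = Chem.MolToSmiles(hmol)
            if c in seen_const:
                continue
            seen_const.add(c)
            emit(c, var_smi, 1, 0)

    return results


def index_mmps(
    fragmentations: Mapping[str, Sequence[Fragmentation]],
    _records: object = None,
) -> list[MMPTransformation]:
    """Group fragmentations by constant part; cross-chemical pairs within a
    group whose variable parts differ become transformations.

    Output is invariant to input ordering: one record per unordered chemical
    pair per (constant, exchange), oriented with id_i < id_j and sorted.
    """
    groups: dict[str, dict[tuple[str, str], Fragmentation]] = defaultdict(dict)
    for pid, frags in fragmentations.items():
        for f in frags:
            groups[f.constant_smiles].setdefault((pid, f.variable_smiles), f)

    out: dict[tuple, MMPTransformation] = {}
    for const_smi, members in groups.items():
        entries = sorted(members.items())  # deterministic
        for (pid_a, var_a), frag_a in entries:
            for (pid_b, var_b), frag_b in entries:
                if pid_a >= pid_b or var_a == var_b:
                    continue
                t = MMPTransformation(
                    id_i=pid_a,
                    id_j=pid_b,
                    constant_smiles=const_smi,
                    frag_i_smiles=var_a,
                    frag_j_smiles=var_b,
                    frag_i_heavy=frag_a.variable_heavy,
                    frag_j_heavy=frag_b.variable_heavy,
                    constant_heavy=frag_a.constant_heavy,
                    n_cuts=frag_a.n_cuts,
                )
                out.setdefault((pid_a, pid_b, const_smi, var_a, var_b), t)
    return sorted(
        out.values(),
        key=lambda t: (t.id_i, t.id_j, t.constant_smiles, t.frag_i_smiles, t.frag_j_smiles),
    )


MAX_FRAG_DIFF = 8      # (i)  heavy-atom difference between exchanged fragments
MAX_FRAG_HEAVY = 13    # (iii) heavy atoms per exchanged fragment
CONST_RATIO = 2        # (ii)  constant >= 2x each fragment


def passes_size_criteria(t: MMPTransformation) -> bool:
    if abs(t.frag_i_heavy - t.frag_j_heavy) > MAX_FRAG_DIFF:
        return False
    if max(t.frag_i_heavy, t.frag_j_heavy) > MAX_FRAG_HEAVY:
        return False
    if t.constant_heavy < CONST_RATIO * t.frag_i_heavy:
        return False
    if t.constant_heavy < CONST_RATIO * t.frag_j_heavy:
        return False
    return True


def apply_size_restrictions(mmps: Iterable[MMPTransformation]) -> list[SizeRestrictedMMP]:
    """Filter by criteria (i)-(iii) and keep, per unordered pair, the single
    transformation with the least fragment heavy-atom difference (criterion iv;
    ties: smaller total fragment size, then transformation string)."""
    best: dict[tuple[str, str], MMPTransformation] = {}

    def rank(t: MMPTransformation) -> tuple:
        return (
            abs(t.frag_i_heavy - t.frag_j_heavy),
            t.frag_i_heavy + t.frag_j_heavy,
            t.transform,
            t.constant_smiles,
        )

    for t in mmps:
        if not passes_size_criteria(t):
            continue
        cur = best.get(t.pair)
        if cur is None or rank(t) < rank(cur):
            best[t.pair] = t
    return [SizeRestrictedMMP(transformation=best[p]) for p in sorted(best)]


def find_mmp_cliffs(
    restricted: Sequence[SizeRestrictedMMP],
    pac50: Mapping[str, float],
    act_threshold: float = 2.0,
) -> list[SizeRestrictedMMP]:
    """Set activity differences / cliff flags in place; return the cliffs."""
    cliffs = []
    for m in restricted:
        for cid in m.pair:
            if cid not in pac50:
                raise DataError(f"no pAC50 for chemical {cid!r}")
        m.activity_diff = activity_difference(pac50[m.transformation.id_i], pac50[m.transformation.id_j])
        m.is_cliff = m.activity_diff >= act_threshold
        if m.is_cliff:
            cliffs.append(m)
    return cliffs


def compare_with_sas(
    cliff_mmps: Sequence[SizeRestrictedMMP],
    sas_cliffs: Sequence[PairAssessment],
) -> dict:
    """Overlap report between MMP-cliff pairs and SAS region-III pairs.

    The subset relation is reported, never assumed.  ``n_mmp_directed`` gives
    the doubled (A->B plus B->A) count some tools print.
    """
    mmp_pairs = {m.pair for m in cliff_mmps}
    sas_pairs = {p.key for p in sas_cliffs}
    inter = mmp_pairs & sas_pairs
    return {
        "n_mmp_cliff_pairs": len(mmp_pairs),
        "n_mmp_directed": 2 * len(mmp_pairs),
        "n_sas_cliffs": len(sas_pairs),
        "n_intersection": len(inter),
        "mmp_only": sorted(mmp_pairs - sas_pairs),
        "sas_only": sorted(sas_pairs - mmp_pairs),
        "mmp_subset_of_sas": mmp_pairs <= sas_pairs,
    }


def write_mmps_csv(mmps: Sequence[SizeRestrictedMMP], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id_i", "id_j", "constant_smiles", "transform", "n_cuts",
             "frag_i_heavy", "frag_j_heavy", "constant_heavy", "activity_diff", "is_cliff"]
        )
        for m in mmps:
            t = m.transformation
            writer.writerow(
                [t.id_i, t.id_j, t.constant_smiles, t.transform, t.n_cuts,
                 t.frag_i_heavy, t.frag_j_heavy, t.constant_heavy,
                 "" if m.activity_diff is None else repr(m.activity_diff), m.is_cliff]
            )
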