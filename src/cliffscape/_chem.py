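"""Shared RDKit helpers: one canonicalization convention for the whole package.

Canonical SMILES from :func:`canonical_smiles` is the package-wide key used for
deduplication, scaffold comparison and MMP constant-part grouping.  Stereo is
retained in record SMILES but stripped for keys (see :func:`dedup_key`).
"""

from __future__ import annotations

from rdkit import Chem, RDLogger

# RDKit parse warnings are noise for deliberately-invalid test inputs.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse SMILES, returning None on failure instead of raising."""
    if not smiles or not isinstance(smiles, str):
        return None
    return Chem.MolFromSmiles(smiles)


def canonical_smiles(smiles_or_mol: str | Chem.Mol) -> str:
    """Package-wide canonical SMILES. Raises ValueError on unparseable input."""
    if isinstance(smiles_or_mol, Chem.Mol):
        return Chem.MolToSmiles(smiles_or_mol)
    mol = mol_from_smiles(smiles_or_mol)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles_or_mol!r}")
    return Chem.MolToSmiles(mol)


def dedup_key(smiles_or_mol: str | Chem.Mol) -> str:
    """Stereo-stripped canonical SMILES: two inputs differing only by stereo
    flags collapse to the same key."""
    if isinstance(smiles_or_mol, Chem.Mol):
        mol = Chem.Mol(smiles_or_mol)
    else:
        mol = mol_from_smiles(smiles_or_mol)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles_or_mol!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles_or_mol: str | Chem.Mol, ignore_dummies: bool = True) -> int:
    """Number of heavy atoms; wildcard/dummy atoms ([*]) excluded by default."""
    if isinstance(smiles_or_mol, Chem.Mol):
        mol = smiles_or_mol
    else:
        mol = mol_from_smiles(smiles_or_mol)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles_or_mol!r}")
    n = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and ignore_dummies:
            continue
        if atom.GetAtomicNum() > 1:
            n += 1
    return n


def has_ring(mol: Chem.Mol) -> bool:
    return mol.GetRingInfo().NumRings() > 0
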