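"""ECFP4 fingerprints, Tanimoto similarity and the pairwise assessment table."""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

from cliffscape._chem import mol_from_smiles
from cliffscape.activity_metrics import activity_difference
from cliffscape.dataset_io import ChemicalRecord

DEFAULT_N_BITS = 2048

_GENERATORS: dict[int, object] = {}


def _generator(n_bits: int):
    # Morgan radius 2 == diameter-4 circular fingerprint (ECFP4).
    if n_bits not in _GENERATORS:
        _GENERATORS[n_bits] = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return _GENERATORS[n_bits]


@dataclass(frozen=True)
class Fingerprint:
    bits: DataStructs.ExplicitBitVect
    n_bits: int


@dataclass
class PairAssessment:
    """One unordered chemical pair: similarity, activity gap, SAS region."""

    id_i: str
    id_j: str
    tanimoto: float
    activity_diff: float
    region: str | None = None  # "I".."IV", assigned by sas_landscape

    def __post_init__(self) -> None:
        if self.id_i > self.id_j:
            self.id_i, self.id_j = self.id_j, self.id_i

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_i, self.id_j)


def compute_ecfp4(canonical_smiles: str, n_bits: int = DEFAULT_N_BITS) -> Fingerprint:
    """Folded circular fingerprint of diameter 4 (Morgan radius 2), chirality off."""
    mol = mol_from_smiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {canonical_smiles!r}")
    return Fingerprint(bits=_generator(n_bits).GetFingerprint(mol), n_bits=n_bits)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """|a AND b| / |a OR b| on the folded bit vectors."""
    if fp_a.n_bits != fp_b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {fp_a.n_bits} vs {fp_b.n_bits}")
    return DataStructs.TanimotoSimilarity(fp_a.bits, fp_b.bits)


def pairwise_table(
    records: Sequence[ChemicalRecord], n_bits: int = DEFAULT_N_BITS
) -> list[PairAssessment]:
    """All n(n-1)/2 unordered pairs with Tanimoto and |dpAC50| filled in.

    Row-at-a-time bulk similarity keeps memory linear in n aside from the
    output list itself.
    """
    if len(records) < 2:
        return []
    fps = [compute_ecfp4(r.canonical_smiles, n_bits).bits for r in records]
    out: list[PairAssessment] = []
    for i in range(len(records) - 1):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        ri = records[i]
        for off, sim in enumerate(sims):
            rj = records[i + 1 + off]
            out.append(
                PairAssessment(
                    id_i=ri.chem_id,
                    id_j=rj.chem_id,
                    tanimoto=sim,
                    activity_diff=activity_difference(ri.pac50, rj.pac50),
                )
            )
    return out


def suggest_similarity_threshold(pairs: Iterable[PairAssessment | float]) -> float:
    """Diagnostic threshold: median(Tanimoto) + 3 x sample SD (about the mean).

    The pipeline default stays 0.35 unless explicitly overridden; this mirrors
    how that default was justified.
    """
    values = [p.tanimoto if isinstance(p, PairAssessment) else float(p) for p in pairs]
    if len(values) < 2:
        raise ValueError("need >= 2 pairs")
    med = statistics.median(values)
    sd = statistics.stdev(values)  # sample SD, ddof=1
    return med + 3.0 * sd


def write_pairs_csv(pairs: Sequence[PairAssessment], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_i", "id_j", "tanimoto", "activity_diff", "region"])
        for p in pairs:
            writer.writerow([p.id_i, p.id_j, repr(p.tanimoto), repr(p.activity_diff), p.region or ""])


def read_pairs_csv(path: str | Path) -> list[PairAssessment]:
    out: list[PairAssessment] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PairAssessment(
                    id_i=row["id_i"],
                    id_j=row["id_j"],
                    tanimoto=float(row["tanimoto"]),
                    activity_diff=float(row["activity_diff"]),
                    region=row.get("region") or None,
                )
            )
    return out
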