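"""Mechanism-of-action (MOA) pair classification for dual-endpoint chemicals.

Chemicals present in both the agonist and antagonist datasets carry a hit
tuple (agonist_hit, antagonist_hit).  After dropping chemicals inactive in
both assays, structurally similar pairs (Tanimoto > threshold) are labelled:

    strong_moa_cliff  the two tuples are element-wise opposite
    same_moa          the two tuples are equal
    weak_moa_cliff    anything else
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from rdkit import DataStructs

from cliffscape._chem import dedup_key
from cliffscape.dataset_io import ChemicalRecord, Endpoint, HitCall
from cliffscape.similarity import DEFAULT_N_BITS, compute_ecfp4


@dataclass(frozen=True)
class DualEndpointRecord:
    chem_id: str
    canonical_smiles: str
    agonist_hit: HitCall
    antagonist_hit: HitCall

    @property
    def hit_tuple(self) -> tuple[HitCall, HitCall]:
        return (self.agonist_hit, self.antagonist_hit)


@dataclass(frozen=True)
class MOAPairClass:
    id_i: str
    id_j: str
    tanimoto: float
    tuple_i: tuple[HitCall, HitCall]
    tuple_j: tuple[HitCall, HitCall]
    label: str


def intersect_datasets(
    agonists: Sequence[ChemicalRecord], antagonists: Sequence[ChemicalRecord]
) -> list[DualEndpointRecord]:
    """Chemicals present in both curated datasets, keyed by stereo-stripped
    canonical structure (falling back to chem_id when no structure)."""

    def key(rec: ChemicalRecord) -> str:
        try:
            return dedup_key(rec.canonical_smiles)
        except ValueError:
            return f"id:{rec.chem_id}"

    ago = {}
    for rec in agonists:
        if rec.endpoint is not Endpoint.AGONIST:
            raise ValueError(f"record {rec.chem_id} is not an agonist record")
        ago.setdefault(key(rec), rec)
    out: list[DualEndpointRecord] = []
    seen: set[str] = set()
    for rec in antagonists:
        if rec.endpoint is not Endpoint.ANTAGONIST:
            raise ValueError(f"record {rec.chem_id} is not an antagonist record")
        k = key(rec)
        if k in ago and k not in seen:
            seen.add(k)
            a = ago[k]
            out.append(
                DualEndpointRecord(
                    chem_id=a.chem_id,
                    canonical_smiles=a.canonical_smiles,
                    agonist_hit=a.hit_call,
                    antagonist_hit=rec.hit_call,
                )
            )
    return out


def filter_active_any(records: Sequence[DualEndpointRecord]) -> list[DualEndpointRecord]:
    """Drop chemicals inactive in both assays."""
    return [
        r
        for r in records
        if not (r.agonist_hit is HitCall.INACTIVE and r.antagonist_hit is HitCall.INACTIVE)
    ]


def similar_pairs(
    records: Sequence[DualEndpointRecord],
    sim_threshold: float = 0.35,
    n_bits: int = DEFAULT_N_BITS,
) -> list[tuple[DualEndpointRecord, DualEndpointRecord, float]]:
    """All unordered pairs with ECFP4 Tanimoto strictly above the threshold."""
    fps = [compute_ecfp4(r.canonical_smiles, n_bits).bits for r in records]
    out = []
    for i in range(len(records) - 1):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        for off, sim in enumerate(sims):
            if sim > sim_threshold:
                out.append((records[i], records[i + 1 + off], sim))
    return out


def classify_moa_pair(
    rec_i: DualEndpointRecord, rec_j: DualEndpointRecord, tanimoto: float = 1.0
) -> MOAPairClass:
    ti, tj = rec_i.hit_tuple, rec_j.hit_tuple
    opposite = {HitCall.ACTIVE: HitCall.INACTIVE, HitCall.INACTIVE: HitCall.ACTIVE}
    if ti == tj:
        label = "same_moa"
    elif tj == (opposite[ti[0]], opposite[ti[1]]):
        label = "strong_moa_cliff"
    else:
        label = "weak_moa_cliff"
    id_i, id_j = sorted((rec_i.chem_id, rec_j.chem_id))
    return MOAPairClass(
        id_i=id_i, id_j=id_j, tanimoto=tanimoto, tuple_i=ti, tuple_j=tj, label=label
    )


def classify_all(
    agonists: Sequence[ChemicalRecord],
    antagonists: Sequence[ChemicalRecord],
    sim_threshold: float = 0.35,
    n_bits: int = DEFAULT_N_BITS,
) -> tuple[list[MOAPairClass], dict]:
    """Full MOA stage; returns labelled pairs plus per-step counts."""
    common = intersect_datasets(agonists, antagonists)
    shortlisted = filter_active_any(common)
    pairs = similar_pairs(shortlisted, sim_threshold=sim_threshold, n_bits=n_bits)
    labelled = [classify_moa_pair(ri, rj, sim) for ri, rj, sim in pairs]
    counts = {
        "n_common": len(common),
        "n_shortlisted": len(shortlisted),
        "n_similar_pairs": len(labelled),
        "strong_moa_cliff": sum(1 for p in labelled if p.label == "strong_moa_cliff"),
        "same_moa": sum(1 for p in labelled if p.label == "same_moa"),
        "weak_moa_cliff": sum(1 for p in labelled if p.label == "weak_moa_cliff"),
    }
    return labelled, counts


def write_moa_csv(pairs: Sequence[MOAPairClass], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_i", "id_j", "tanimoto", "tuple_i", "tuple_j", "label"])
        for p in pairs:
            writer.writerow(
                [p.id_i, p.id_j, repr(p.tanimoto),
                 f"{p.tuple_i[0].value}/{p.tuple_i[1].value}",
                 f"{p.tuple_j[0].value}/{p.tuple_j[1].value}", p.label]
            )
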