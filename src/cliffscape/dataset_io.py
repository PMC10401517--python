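"""Reading activity tables and applying the dataset curation filters.

Curation order: drop records without a reported activity value, standardize
structures (salt stripping; reject mixtures and invalid structures), compute
pAC50, deduplicate per endpoint on stereo-stripped canonical structure, and
remove linear (ring-free) chemicals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from rdkit import Chem

from cliffscape._chem import canonical_smiles, dedup_key, has_ring, heavy_atom_count, mol_from_smiles
from cliffscape.activity_metrics import modl_ga_to_pac50


class HitCall(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    MISSING = "missing"


class Endpoint(str, Enum):
    AGONIST = "agonist"
    ANTAGONIST = "antagonist"


class SchemaError(ValueError):
    """Input table header lacks a mapped column."""


@dataclass(frozen=True)
class RawRecord:
    """One row of an activity table, as supplied."""

    chem_id: str
    name: str
    smiles: str
    modl_ga: float | None
    hit_call: HitCall
    endpoint: Endpoint
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chem_id:
            raise ValueError("chem_id must be non-empty")


@dataclass(frozen=True)
class ChemicalRecord:
    """One curated chemical: canonical single-component structure + activity."""

    chem_id: str
    canonical_smiles: str
    modl_ga: float
    pac50: float
    hit_call: HitCall
    endpoint: Endpoint
    name: str = ""
    metadata: dict[str, str] = field(default_factory=dict)


#: Fragments recognized as counter-ions/solvents during salt stripping.
#: Canonical SMILES keys.  Deliberately excludes organic acids (acetate,
#: oxalate, ...) so that e.g. a sodium-acetate input keeps its acid fragment.
SALT_FRAGMENTS: frozenset[str] = frozenset(
    canonical_smiles(s)
    for s in [
        "[Na+]", "[K+]", "[Li+]", "[Cs+]",
        "[Ca+2]", "[Mg+2]", "[Zn+2]", "[Ba+2]", "[Sr+2]", "[Al+3]", "[Fe+2]", "[Fe+3]",
        "[NH4+]",
        "[Cl-]", "[Br-]", "[I-]", "[F-]",
        "Cl", "Br", "I", "F",          # hydrohalic acids
        "O",                            # water of crystallization
        "[OH-]", "[O-2]",
        "OS(=O)(=O)O", "[O-]S(=O)(=O)[O-]", "[O-]S(=O)(=O)O",       # sulfate
        "O[N+](=O)[O-]", "[O-][N+](=O)[O-]",                        # nitrate
        "OP(=O)(O)O", "[O-]P(=O)([O-])[O-]",                        # phosphate
        "OC(=O)O", "[O-]C(=O)[O-]",                                 # carbonate
        "CS(=O)(=O)O", "CS(=O)(=O)[O-]",                            # mesylate
        "Cc1ccc(S(=O)(=O)O)cc1", "Cc1ccc(S(=O)(=O)[O-])cc1",        # tosylate
        "[N-]=[N+]=[N-]",
    ]
)


class Rejection(str, Enum):
    INVALID = "invalid"
    MIXTURE = "mixture"


def standardize_structure(smiles: str) -> str | Rejection:
    """Canonicalize a SMILES, stripping recognized salt/solvent fragments.

    Returns the canonical SMILES of the remaining single organic fragment, or a
    :class:`Rejection` (``invalid`` for unparseable/empty structures,
    ``mixture`` when >= 2 distinct non-salt fragments remain).
    """
    mol = mol_from_smiles(smiles)
    if mol is None:
        return Rejection.INVALID
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    non_salt: dict[str, Chem.Mol] = {}
    for frag in frags:
        smi = canonical_smiles(frag)
        if smi in SALT_FRAGMENTS:
            continue
        non_salt.setdefault(smi, frag)  # duplicate fragments collapse
    if len(non_salt) == 0:
        return Rejection.INVALID
    if len(non_salt) > 1:
        return Rejection.MIXTURE
    smi, frag = next(iter(non_salt.items()))
    if heavy_atom_count(frag) == 0:
        return Rejection.INVALID
    return smi


def parse_activity_table(
    path: str | Path,
    fmt: str = "csv",
    column_map: dict[str, str] | None = None,
) -> list[RawRecord]:
    """Parse a CSV/TSV activity table into :class:`RawRecord` rows.

    ``column_map`` maps field names (``chem_id``, ``name``, ``smiles``,
    ``modl_ga``, ``hit_call``, ``endpoint``) to table columns; defaults assume
    the columns are named ``chem_id, name, smiles, modl_ga, hit_c, endpoint``.
    Unmapped columns are carried through in ``metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}")
    cmap = {
        "chem_id": "chem_id",
        "name": "name",
        "smiles": "smiles",
        "modl_ga": "modl_ga",
        "hit_call": "hit_c",
        "endpoint": "endpoint",
    }
    if column_map:
        cmap.update(column_map)

    delim = "\t" if fmt == "tsv" else ","
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        # name is optional; everything else must be present
        for field_name, col in cmap.items():
            if field_name == "name":
                continue
            if col not in header:
                raise SchemaError(f"column {col!r} (field {field_name!r}) missing from header {header}")
        mapped_cols = set(cmap.values())
        records: list[RawRecord] = []
        for row in reader:
            raw_ga = (row.get(cmap["modl_ga"]) or "").strip()
            try:
                modl_ga: float | None = float(raw_ga)
            except ValueError:
                modl_ga = None
            hit_raw = (row.get(cmap["hit_call"]) or "").strip().lower()
            if hit_raw in ("1", "active", "true"):
                hit = HitCall.ACTIVE
            elif hit_raw in ("0", "inactive", "false"):
                hit = HitCall.INACTIVE
            else:
                hit = HitCall.MISSING
            records.append(
                RawRecord(
                    chem_id=(row.get(cmap["chem_id"]) or "").strip(),
                    name=(row.get(cmap["name"]) or "").strip(),
                    smiles=(row.get(cmap["smiles"]) or "").strip(),
                    modl_ga=modl_ga,
                    hit_call=hit,
                    endpoint=Endpoint((row.get(cmap["endpoint"]) or "").strip().lower()),
                    metadata={k: v for k, v in row.items() if k not in mapped_cols and k is not None},
                )
            )
    return records


def deduplicate(
    records: list[ChemicalRecord], log: list[tuple[str, str]] | None = None
) -> list[ChemicalRecord]:
    """Keep at most one record per (stereo-stripped structure, endpoint).

    First occurrence in input order wins; removals are appended to ``log`` as
    (kept_chem_id, dropped_chem_id) tuples.
    """
    seen: dict[tuple[str, Endpoint], str] = {}
    out: list[ChemicalRecord] = []
    for rec in records:
        key = (dedup_key(rec.canonical_smiles), rec.endpoint)
        if key in seen:
            if log is not None:
                log.append((seen[key], rec.chem_id))
            continue
        seen[key] = rec.chem_id
        out.append(rec)
    return out


def remove_linear(
    records: list[ChemicalRecord], log: list[str] | None = None
) -> list[ChemicalRecord]:
    """Drop chemicals with no ring system (empty Bemis-Murcko scaffold)."""
    out = []
    for rec in records:
        mol = mol_from_smiles(rec.canonical_smiles)
        if mol is not None and has_ring(mol):
            out.append(rec)
        elif log is not None:
            log.append(rec.chem_id)
    return out


@dataclass
class CurationReport:
    n_input: int = 0
    missing_activity: int = 0
    invalid: int = 0
    mixture: int = 0
    duplicate: int = 0
    linear: int = 0
    n_curated: int = 0
    duplicate_log: list[tuple[str, str]] = field(default_factory=list)
    linear_log: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "missing_activity": self.missing_activity,
            "invalid": self.invalid,
            "mixture": self.mixture,
            "duplicate": self.duplicate,
            "linear": self.linear,
            "n_curated": self.n_curated,
            "duplicate_log": [list(t) for t in self.duplicate_log],
            "linear_log": list(self.linear_log),
        }


def curate(raw: list[RawRecord]) -> tuple[list[ChemicalRecord], CurationReport]:
    """Apply the full curation cascade and report per-step drop counts."""
    report = CurationReport(n_input=len(raw))

    staged: list[ChemicalRecord] = []
    for rec in raw:
        if rec.modl_ga is None:
            report.missing_activity += 1
            continue
        std = standardize_structure(rec.smiles)
        if std is Rejection.INVALID:
            report.invalid += 1
            continue
        if std is Rejection.MIXTURE:
            report.mixture += 1
            continue
        hit = rec.hit_call if rec.hit_call is not HitCall.MISSING else HitCall.INACTIVE
        staged.append(
            ChemicalRecord(
                chem_id=rec.chem_id,
                canonical_smiles=std,
                modl_ga=rec.modl_ga,
                pac50=modl_ga_to_pac50(rec.modl_ga),
                hit_call=hit,
                endpoint=rec.endpoint,
                name=rec.name,
                metadata=dict(rec.metadata),
            )
        )

    deduped = deduplicate(staged, log=report.duplicate_log)
    report.duplicate = len(staged) - len(deduped)

    curated = remove_linear(deduped, log=report.linear_log)
    report.linear = len(deduped) - len(curated)
    report.n_curated = len(curated)
    return curated, report


def records_as_raw(records: list[ChemicalRecord]) -> list[RawRecord]:
    """Re-wrap curated records as raw rows (for idempotence checks / re-runs)."""
    return [
        RawRecord(
            chem_id=r.chem_id,
            name=r.name,
            smiles=r.canonical_smiles,
            modl_ga=r.modl_ga,
            hit_call=r.hit_call,
            endpoint=r.endpoint,
            metadata=dict(r.metadata),
        )
        for r in records
    ]


def write_curated_csv(records: list[ChemicalRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chem_id", "name", "canonical_smiles", "modl_ga", "pac50", "hit_call", "endpoint"])
        for r in records:
            writer.writerow(
                [r.chem_id, r.name, r.canonical_smiles, repr(r.modl_ga), repr(r.pac50), r.hit_call.value, r.endpoint.value]
            )


def read_curated_csv(path: str | Path) -> list[ChemicalRecord]:
    path = Path(path)
    out: list[ChemicalRecord] = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ChemicalRecord(
                    chem_id=row["chem_id"],
                    name=row.get("name", ""),
                    canonical_smiles=row["canonical_smiles"],
                    modl_ga=float(row["modl_ga"]),
                    pac50=float(row["pac50"]),
                    hit_call=HitCall(row["hit_call"]),
                    endpoint=Endpoint(row["endpoint"]),
                )
            )
    return out


def write_report_json(report: CurationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2))
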