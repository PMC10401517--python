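"""Synthetic activity datasets with known ground truth.

Scaffold families (large shared cores, so within-family pairs stay structurally
similar) are enumerated with single- and double-substituted analogs from a
substituent library.  Activities are additive on the pAC50 scale: family base
+ per-substituent effect + clipped Gaussian noise.  Planting a cliff adds
``cliff_jump`` to one member of a family, which turns every structurally
similar family pair involving it into an activity cliff.

Ground truth is *derived*, not asserted: planted cliff pairs are the pairs
whose noiseless activity gap clears the 2 log-unit threshold by the noise
margin AND whose actual ECFP4 Tanimoto exceeds 0.35; the generator raises if
any pair lands in the ambiguous band.  Noise is clipped at +/-3 sigma so the
margin is a hard guarantee rather than a probabilistic one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import DataStructs

from cliffscape._chem import canonical_smiles
from cliffscape.similarity import DEFAULT_N_BITS, compute_ecfp4


class ConfigError(ValueError):
    pass


#: Family templates: one "{}" slot (mono) and a symmetric two-slot variant (di).
#: Cores are large and mutually diverse so within-family similarity is high and
#: cross-family similarity is low.
FAMILY_TEMPLATES: list[tuple[str, str]] = [
    ("O=C(Nc1ccccc1)c1ccc({})cc1", "O=C(Nc1ccc({})cc1)c1ccc({})cc1"),
    ("O=S(=O)(N1CCCCC1)c1ccc({})cc1", "O=S(=O)(N1CCC({})CC1)c1ccc({})cc1"),
    ("O=C(OCc1ccncc1)C1CCC({})CC1", "O=C(OCc1ccnc({})c1)C1CCC({})CC1"),
    ("c1ccc(-n2cnc3ccc({})cc32)cc1", "c1cc({})ccc1-n1cnc2ccc({})cc21"),
    ("O=C(Cc1ccsc1)N1CCN(c2ccc({})cc2)CC1", "O=C(Cc1cc({})sc1)N1CCN(c2ccc({})cc2)CC1"),
    ("C(=Cc1ccc({})cc1)c1ccc2ccccc2c1", "C(=Cc1ccc({})cc1)c1ccc2cc({})ccc2c1"),
    ("CCCC1CCC(CNC(=O)C2CC2c2ccc({})cc2)CC1", "CCCC1CCC(CNC(=O)C2CC2c2ccc({})c({})c2)CC1"),
    ("c1ccc(COc2ccc({})cc2C2CC2)cc1", "c1cc({})ccc1COc1ccc({})cc1C1CC1"),
]

DEFAULT_SUBSTITUENTS = ["F", "Cl", "Br", "C", "CC", "OC", "N", "C#N"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_scaffold_families: int = 4
    substituent_library: tuple[str, ...] = tuple(DEFAULT_SUBSTITUENTS)
    base_pac50_range: tuple[float, float] = (4.5, 5.2)
    cliff_jump: float = 4.5
    noise_sd: float = 0.1
    effect_max: float = 0.15
    planted_cliff_fraction: float = 0.5
    include_disubstituted: bool = True
    sim_threshold: float = 0.35
    act_threshold: float = 2.0
    n_bits: int = DEFAULT_N_BITS
    seed: int = 0
    assert_recovery: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.n_scaffold_families <= len(FAMILY_TEMPLATES):
            raise ConfigError(
                f"n_scaffold_families must be in [1, {len(FAMILY_TEMPLATES)}]"
            )
        if not 0.0 <= self.planted_cliff_fraction <= 1.0:
            raise ConfigError("planted_cliff_fraction must lie in [0, 1]")
        if self.assert_recovery:
            # Worst-case noiseless gap between any two unjumped chemicals:
            # base-range width + up to two substituent effects per chemical.
            width = self.base_pac50_range[1] - self.base_pac50_range[0]
            spread = width + 4 * self.effect_max
            band = 2 * (3 * self.noise_sd)  # noise clipped at 3 sigma
            if spread + band >= self.act_threshold:
                raise ConfigError(
                    "margin invariant violated: unjumped pairs may reach the "
                    f"activity threshold (spread {spread:.3f} + noise band "
                    f"{band:.3f} >= {self.act_threshold})"
                )
            if self.cliff_jump - spread - band < self.act_threshold:
                raise ConfigError(
                    "margin invariant violated: cliff_jump too small for exact "
                    f"planted-cliff recovery (jump {self.cliff_jump} - spread "
                    f"{spread:.3f} - noise band {band:.3f} < {self.act_threshold})"
                )


@dataclass
class GroundTruth:
    planted_cliff_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_acg_ids: set[str] = field(default_factory=set)
    #: unordered pair -> expected canonical constant part of the MMP exchange
    planted_mmp_pairs: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_moa_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    true_pac50: dict[str, float] = field(default_factory=dict)
    hit_tuples: dict[str, tuple[str, str]] = field(default_factory=dict)
    jumped_ids: set[str] = field(default_factory=set)


def _clipped_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    return np.clip(rng.normal(0.0, sd, size=size), -3 * sd, 3 * sd)


def _build_family_members(
    config: SyntheticConfig, family: int
) -> list[tuple[str, str, tuple[str, ...]]]:
    """(chem_id, canonical_smiles, substituents) for one family, deduplicated."""
    mono_t, di_t = FAMILY_TEMPLATES[family]
    members: list[tuple[str, str, tuple[str, ...]]] = []
    seen: set[str] = set()
    for si, sub in enumerate(config.substituent_library):
        smi = canonical_smiles(mono_t.format(sub))
        if smi not in seen:
            seen.add(smi)
            members.append((f"F{family}M{si}", smi, (sub,)))
    if config.include_disubstituted:
        for di, (a, b) in enumerate(
            combinations_with_replacement(config.substituent_library, 2)
        ):
            smi = canonical_smiles(di_t.format(a, b))
            if smi not in seen:
                seen.add(smi)
                members.append((f"F{family}D{di}", smi, (a, b)))
    return members


def generate_series(
    config: SyntheticConfig,
) -> tuple[list[dict], GroundTruth]:
    """Generate one endpoint's activity table plus ground truth.

    Rows carry the default input schema (``chem_id,name,smiles,modl_ga,hit_c,
    endpoint``) with ``modl_ga = 6 - pac50`` so they round-trip through the
    real curation pipeline.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    families = [
        _build_family_members(config, f) for f in range(config.n_scaffold_families)
    ]
    lo, hi = config.base_pac50_range
    bases = rng.uniform(lo, hi, size=len(families))
    effects = {
        (f, s): e
        for f in range(len(families))
        for s, e in zip(
            config.substituent_library,
            rng.uniform(-config.effect_max, config.effect_max,
                        size=len(config.substituent_library)),
        )
    }

    n_jump = int(round(config.planted_cliff_fraction * len(families)))
    jump_families = list(rng.choice(len(families), size=n_jump, replace=False))

    rows: list[dict] = []
    ids: list[str] = []
    smiles: list[str] = []
    family_of: dict[str, int] = {}
    for f, members in enumerate(families):
        jump_member = int(rng.integers(len(members))) if f in jump_families else -1
        noise = _clipped_normal(rng, config.noise_sd, len(members))
        for m, (cid, smi, subs) in enumerate(members):
            true = bases[f] + sum(effects[(f, s)] for s in subs)
            if m == jump_member:
                true += config.cliff_jump
                truth.jumped_ids.add(cid)
            truth.true_pac50[cid] = true
            pac50 = true + float(noise[m])
            rows.append(
                {
                    "chem_id": cid,
                    "name": cid,
                    "smiles": smi,
                    "modl_ga": 6.0 - pac50,
                    "hit_c": 1,
                    "endpoint": "agonist",
                }
            )
            ids.append(cid)
            smiles.append(smi)
            family_of[cid] = f

    # Derive ground truth from actual similarities and noiseless activities.
    fps = [compute_ecfp4(s, config.n_bits).bits for s in smiles]
    noise_band = 2 * (3 * config.noise_sd)
    cliff_partners: dict[str, int] = {cid: 0 for cid in ids}
    for i, j in combinations(range(len(ids)), 2):
        sim = DataStructs.TanimotoSimilarity(fps[i], fps[j])
        if sim <= config.sim_threshold:
            continue
        gap = abs(truth.true_pac50[ids[i]] - truth.true_pac50[ids[j]])
        if gap - noise_band >= config.act_threshold:
            pair = tuple(sorted((ids[i], ids[j])))
            truth.planted_cliff_pairs.add(pair)  # type: ignore[arg-type]
            cliff_partners[ids[i]] += 1
            cliff_partners[ids[j]] += 1
        elif gap + noise_band >= config.act_threshold:
            if config.assert_recovery:
                raise ConfigError(
                    f"pair ({ids[i]}, {ids[j]}) is ambiguous: noiseless gap "
                    f"{gap:.3f} within the noise band of the threshold"
                )
    truth.planted_acg_ids = {cid for cid, n in cliff_partners.items() if n >= 5}

    # Planted MMPs: mono-substituted analogs within a family are single-site
    # substituent swaps sharing the attachment-labelled family core.
    for f, members in enumerate(families):
        mono_t = FAMILY_TEMPLATES[f][0]
        expected_const = canonical_smiles(mono_t.format("[*:1]"))
        monos = [(cid, subs) for cid, _, subs in members if len(subs) == 1]
        for (ca, sa), (cb, sb) in combinations(monos, 2):
            if sa != sb:
                truth.planted_mmp_pairs[tuple(sorted((ca, cb)))] = expected_const  # type: ignore[index]

    return rows, truth


_MOA_TUPLES = {
    "strong_moa_cliff": (("active", "inactive"), ("inactive", "active")),
    "same_moa": (("active", "active"), ("active", "active")),
    "weak_moa_cliff": (("active", "active"), ("active", "inactive")),
}


def generate_dual_endpoint(
    config: SyntheticConfig,
    label_counts: dict[str, int] | None = None,
) -> tuple[list[dict], list[dict], GroundTruth]:
    """Agonist + antagonist tables realizing requested strong/same/weak counts.

    Each requested pair occupies its own scaffold family (two mono-substituted
    analogs), so the similar-pair set is exactly the planted set; cross-family
    similarity is verified to stay below the threshold.
    """
    label_counts = label_counts or {"strong_moa_cliff": 1, "same_moa": 1, "weak_moa_cliff": 1}
    unknown = set(label_counts) - set(_MOA_TUPLES)
    if unknown:
        raise ConfigError(f"unknown MOA labels: {sorted(unknown)}")
    wanted = [
        (label, k)
        for label in ("strong_moa_cliff", "same_moa", "weak_moa_cliff")
        for k in range(label_counts.get(label, 0))
    ]
    if len(wanted) > config.n_scaffold_families:
        raise ConfigError(
            f"{len(wanted)} pairs requested but only {config.n_scaffold_families} "
            "scaffold families configured"
        )
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    ago_rows: list[dict] = []
    ant_rows: list[dict] = []
    all_ids: list[str] = []
    all_fps = []

    lo, hi = config.base_pac50_range
    for f, (label, _) in enumerate(wanted):
        members = _build_family_members(config, f)[:2]
        if len(members) < 2:
            raise ConfigError("substituent library too small for a pair")
        base = float(rng.uniform(lo, hi))
        tup_a, tup_b = _MOA_TUPLES[label]
        pair_ids = []
        fps = []
        for (cid, smi, _subs), tup in zip(members, (tup_a, tup_b)):
            truth.hit_tuples[cid] = tup
            pac = base + float(_clipped_normal(rng, config.noise_sd, 1)[0])
            truth.true_pac50[cid] = pac
            for rows, endpoint, hit in (
                (ago_rows, "agonist", tup[0]),
                (ant_rows, "antagonist", tup[1]),
            ):
                rows.append(
                    {
                        "chem_id": cid,
                        "name": cid,
                        "smiles": smi,
                        "modl_ga": 6.0 - pac,
                        "hit_c": 1 if hit == "active" else 0,
                        "endpoint": endpoint,
                    }
                )
            pair_ids.append(cid)
            fps.append(compute_ecfp4(smi, config.n_bits).bits)
        sim = DataStructs.TanimotoSimilarity(fps[0], fps[1])
        if sim <= config.sim_threshold:
            raise ConfigError(
                f"family {f} pair similarity {sim:.3f} below threshold; "
                "choose a larger shared core"
            )
        truth.planted_moa_labels[tuple(sorted(pair_ids))] = label  # type: ignore[index]
        all_ids.extend(pair_ids)
        all_fps.extend(fps)

    # cross-family pairs must stay dissimilar, else extra similar pairs appear
    for i, j in combinations(range(len(all_ids)), 2):
        same_family = i // 2 == j // 2
        if same_family:
            continue
        sim = DataStructs.TanimotoSimilarity(all_fps[i], all_fps[j])
        if sim > config.sim_threshold:
            raise ConfigError(
                f"cross-family pair ({all_ids[i]}, {all_ids[j]}) similarity "
                f"{sim:.3f} exceeds threshold"
            )
    return ago_rows, ant_rows, truth


@dataclass(frozen=True)
class MicroFixture:
    name: str
    molecules: dict[str, str]
    expected: dict


def micro_fixtures() -> dict[str, MicroFixture]:
    """Hand-curated tiny molecule sets with worked answers.

    Expected values were derived by hand (bond-by-bond enumeration for the MMP
    set, rule-by-rule application for the curation set) and are independent of
    the package's implementation.
    """
    return {
        "mmp_basic": MicroFixture(
            name="mmp_basic",
            molecules={
                "benzene": "c1ccccc1",
                "toluene": "Cc1ccccc1",
                "chlorobenzene": "Clc1ccccc1",
                "ethylbenzene": "CCc1ccccc1",
            },
            expected={
                # single-cut, no hydrogen substitution: every substituted pair
                # shares the attachment-labelled phenyl constant; benzene has
                # no cuttable acyclic bond and pairs with nothing.
                "pairs_no_h": {
                    ("chlorobenzene", "toluene"),
                    ("chlorobenzene", "ethylbenzene"),
                    ("ethylbenzene", "toluene"),
                },
                # with hydrogen substitution benzene additionally matches each
                # substituted partner via an H-for-fragment exchange.
                "extra_pairs_with_h": {
                    ("benzene", "toluene"),
                    ("benzene", "chlorobenzene"),
                    ("benzene", "ethylbenzene"),
                },
                "shared_constant": canonical_smiles("[*:1]c1ccccc1"),
            },
        ),
        "curation": MicroFixture(
            name="curation",
            molecules={},
            expected={
                "rows": [
                    # (chem_id, smiles, modl_ga) -- hand-applied rules below
                    ("ok1", "Cc1ccccc1", "1.0"),         # survives
                    ("ok2", "Clc1ccccc1", "0.5"),        # survives
                    ("salt", "CC(=O)O.[Na+]", "0.2"),    # salt stripped but acyclic -> linear drop
                    ("miss", "Oc1ccccc1", ""),           # missing modl_ga
                    ("mix", "c1ccccc1.c1ccncc1", "0.1"),  # mixture
                    ("dup", "Cc1ccccc1", "2.0"),          # duplicate of ok1
                    ("bad", "C1CC", "0.3"),               # invalid
                    ("hexane", "CCCCCC", "0.4"),          # linear
                ],
                "survivor_ids": ["ok1", "ok2"],
                "report": {
                    "missing_activity": 1,
                    "invalid": 1,
                    "mixture": 1,
                    "duplicate": 1,
                    "linear": 2,
                },
            },
        ),
        "skeleton": MicroFixture(
            name="skeleton",
            molecules={"pyridine": "c1ccncc1", "benzene": "c1ccccc1"},
            expected={"same_skeleton": True},
        ),
        "topology": MicroFixture(
            name="topology",
            molecules={"ortho_cresol": "Cc1ccccc1O", "para_cresol": "Cc1ccc(O)cc1"},
            expected={"label": "topology"},
        ),
    }


def write_rows_csv(rows: Sequence[dict], path: str | Path) -> None:
    path = Path(path)
    fieldnames = ["chem_id", "name", "smiles", "modl_ga", "hit_c", "endpoint"]
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in fieldnames})
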