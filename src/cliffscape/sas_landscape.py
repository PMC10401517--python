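"""SAS-map regions, activity cliffs, cliff generators and the map plot.

Region semantics (fixed boundary operators):

    similar            <=> tanimoto  >  sim_threshold   (strict >)
    different-activity <=> |dpAC50| >=  act_threshold   (>=)

    I   scaffold hops   not similar, not different
    II  smooth          similar,     not different
    III cliffs          similar,     different
    IV  uncertain       not similar, different
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from cliffscape.similarity import PairAssessment


@dataclass(frozen=True)
class SASThresholds:
    sim_threshold: float = 0.35
    act_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.sim_threshold < 1.0):
            raise ValueError("sim_threshold must lie in (0, 1)")
        if self.act_threshold <= 0:
            raise ValueError("act_threshold must be positive")


@dataclass
class CliffGenerator:
    chem_id: str
    cliff_pair_count: int
    partner_ids: list[str] = field(default_factory=list)


def assign_region(tanimoto: float, activity_diff: float, thresholds: SASThresholds) -> str:
    similar = tanimoto > thresholds.sim_threshold
    different = activity_diff >= thresholds.act_threshold
    if similar:
        return "III" if different else "II"
    return "IV" if different else "I"


def assign_regions(pairs: Sequence[PairAssessment], thresholds: SASThresholds) -> Counter:
    """Label every pair in place; returns the region count tally."""
    counts: Counter = Counter()
    for p in pairs:
        p.region = assign_region(p.tanimoto, p.activity_diff, thresholds)
        counts[p.region] += 1
    for region in ("I", "II", "III", "IV"):
        counts.setdefault(region, 0)
    return counts


def find_activity_cliffs(
    pairs: Sequence[PairAssessment], thresholds: SASThresholds | None = None
) -> tuple[list[PairAssessment], int]:
    """Region-III pairs and the count of unique chemicals forming them."""
    thresholds = thresholds or SASThresholds()
    cliffs = [
        p
        for p in pairs
        if assign_region(p.tanimoto, p.activity_diff, thresholds) == "III"
    ]
    for p in cliffs:
        p.region = "III"
    unique = {c for p in cliffs for c in (p.id_i, p.id_j)}
    return cliffs, len(unique)


def find_acgs(cliffs: Sequence[PairAssessment], min_pairs: int = 5) -> list[CliffGenerator]:
    """Chemicals participating in >= min_pairs cliffs, sorted by count desc then id."""
    partners: dict[str, list[str]] = defaultdict(list)
    for p in cliffs:
        partners[p.id_i].append(p.id_j)
        partners[p.id_j].append(p.id_i)
    acgs = [
        CliffGenerator(chem_id=cid, cliff_pair_count=len(ps), partner_ids=sorted(ps))
        for cid, ps in partners.items()
        if len(ps) >= min_pairs
    ]
    acgs.sort(key=lambda g: (-g.cliff_pair_count, g.chem_id))
    return acgs


def render_sas_map(
    pairs: Sequence[PairAssessment],
    thresholds: SASThresholds,
    out_path: str | Path,
) -> Path:
    """Density-shaded scatter of (tanimoto, |dpAC50|) with threshold lines and
    per-quadrant counts annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    if not pairs:
        raise ValueError("pairs must be non-empty")
    x = np.array([p.tanimoto for p in pairs])
    y = np.array([p.activity_diff for p in pairs])
    counts = Counter(assign_region(p.tanimoto, p.activity_diff, thresholds) for p in pairs)

    fig, ax = plt.subplots(figsize=(6, 5))
    if len(pairs) > 1:
        # Gaussian-kernel-free density proxy: 2-D histogram lookup per point.
        hist, xe, ye = np.histogram2d(x, y, bins=40)
        xi = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, hist.shape[0] - 1)
        yi = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, hist.shape[1] - 1)
        dens = hist[xi, yi]
        order = np.argsort(dens)
        sc = ax.scatter(x[order], y[order], c=dens[order], s=8, cmap="viridis")
        fig.colorbar(sc, ax=ax, label="pair density")
    else:
        ax.scatter(x, y, s=20)
    ax.axvline(thresholds.sim_threshold, color="red", lw=1, ls="--")
    ax.axhline(thresholds.act_threshold, color="red", lw=1, ls="--")
    ymax = max(float(y.max()), thresholds.act_threshold) * 1.05 + 0.1
    anno = {
        "I": (thresholds.sim_threshold / 2, thresholds.act_threshold / 2),
        "II": ((1 + thresholds.sim_threshold) / 2, thresholds.act_threshold / 2),
        "III": ((1 + thresholds.sim_threshold) / 2, (ymax + thresholds.act_threshold) / 2),
        "IV": (thresholds.sim_threshold / 2, (ymax + thresholds.act_threshold) / 2),
    }
    for region, (ax_x, ax_y) in anno.items():
        ax.text(ax_x, ax_y, f"{region}: {counts.get(region, 0)}", ha="center", color="dimgray")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, ymax)
    ax.set_xlabel("Tanimoto similarity (ECFP4)")
    ax.set_ylabel("activity difference (|ΔpAC50|)")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def write_cliffs_csv(cliffs: Sequence[PairAssessment], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_i", "id_j", "tanimoto", "activity_diff"])
        for p in cliffs:
            writer.writerow([p.id_i, p.id_j, repr(p.tanimoto), repr(p.activity_diff)])


def write_acgs_csv(acgs: Sequence[CliffGenerator], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chem_id", "cliff_pair_count", "partners"])
        for g in acgs:
            writer.writerow([g.chem_id, g.cliff_pair_count, ";".join(g.partner_ids)])
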