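"""DEG set construction and pairwise Venn analysis.

Builds per-contrast DEG sets split by direction and computes
common/unique counts between two contrasts, tracking "inconsistent"
common genes — genes significant in both contrasts but with opposite
direction. By default such genes stay in the common count and are
reported separately in parentheses-style bookkeeping; a flag excludes
them from common instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .de import ContrastResult
from .exceptions import UndefinedRatioError


@dataclass(frozen=True)
class DegSet:
    """Up/down-regulated gene-id sets for one contrast."""

    name: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"genes both up and down in {self.name}: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    @property
    def total(self) -> int:
        return len(self.up) + len(self.down)

    def direction_of(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        return "none"


def deg_set(result: ContrastResult) -> DegSet:
    """Collect the DEGs of one contrast into direction-split id sets."""
    t = result.table
    return DegSet(
        result.name,
        frozenset(t.index[t["direction"] == "up"]),
        frozenset(t.index[t["direction"] == "down"]),
    )


@dataclass(frozen=True)
class VennSummary:
    """Two-set Venn bookkeeping between contrasts A and B.

    ``common`` counts genes significant in both contrasts;
    ``inconsistent_common`` is the subset whose direction differs between
    A and B. Invariants: |A| = common + unique_a, |B| = common + unique_b.
    """

    name_a: str
    name_b: str
    common: int
    unique_a: int
    unique_b: int
    inconsistent_common: int
    common_ids: frozenset[str] = field(repr=False)
    unique_a_ids: frozenset[str] = field(repr=False)
    unique_b_ids: frozenset[str] = field(repr=False)
    inconsistent_ids: frozenset[str] = field(repr=False)
    # direction splits: uniques by own direction, common by direction in A
    unique_a_up: int = 0
    unique_a_down: int = 0
    unique_b_up: int = 0
    unique_b_down: int = 0
    common_up_a: int = 0
    common_down_a: int = 0

    @property
    def union(self) -> int:
        return self.common + self.unique_a + self.unique_b

    def to_dict(self) -> dict:
        return {
            "contrast_a": self.name_a,
            "contrast_b": self.name_b,
            "common": self.common,
            "unique_a": self.unique_a,
            "unique_b": self.unique_b,
            "inconsistent_common": self.inconsistent_common,
            "unique_a_up": self.unique_a_up,
            "unique_a_down": self.unique_a_down,
            "unique_b_up": self.unique_b_up,
            "unique_b_down": self.unique_b_down,
        }


def venn_pairwise(
    a: DegSet, b: DegSet, exclude_inconsistent_from_common: bool = False
) -> VennSummary:
    """Common/unique DEG counts between two contrasts.

    A gene significant in both with opposite directions is counted in
    ``common`` and flagged ``inconsistent_common`` unless
    ``exclude_inconsistent_from_common`` moves it to both unique sets'
    complement (it is then dropped from common but not added to uniques,
    mirroring exclusion bookkeeping).
    """
    common_ids = a.genes & b.genes
    inconsistent = frozenset(
        g for g in common_ids if a.direction_of(g) != b.direction_of(g)
    )
    if exclude_inconsistent_from_common:
        common_ids = common_ids - inconsistent
    unique_a = a.genes - b.genes
    unique_b = b.genes - a.genes
    return VennSummary(
        name_a=a.name,
        name_b=b.name,
        common=len(common_ids),
        unique_a=len(unique_a),
        unique_b=len(unique_b),
        inconsistent_common=len(inconsistent),
        common_ids=frozenset(common_ids),
        unique_a_ids=frozenset(unique_a),
        unique_b_ids=frozenset(unique_b),
        inconsistent_ids=inconsistent,
        unique_a_up=len(unique_a & a.up),
        unique_a_down=len(unique_a & a.down),
        unique_b_up=len(unique_b & b.up),
        unique_b_down=len(unique_b & b.down),
        common_up_a=len(common_ids & a.up),
        common_down_a=len(common_ids & a.down),
    )


def unique_ratio(a: DegSet, b: DegSet, common: int) -> float:
    """(|A| - common) / (|B| - common): how lopsided the unique DEGs are."""
    if common > min(a.total, b.total):
        raise ValueError("common exceeds a set's size")
    denom = b.total - common
    if denom == 0:
        raise UndefinedRatioError(
            f"unique ratio undefined: contrast {b.name} has no unique DEGs"
        )
    return (a.total - common) / denom


def write_venn_tsv(v: VennSummary, path: str | Path) -> None:
    rows = [
        ("common", v.common, sorted(v.common_ids)),
        (f"unique_{v.name_a}", v.unique_a, sorted(v.unique_a_ids)),
        (f"unique_{v.name_b}", v.unique_b, sorted(v.unique_b_ids)),
        ("inconsistent_common", v.inconsistent_common, sorted(v.inconsistent_ids)),
    ]
    df = pd.DataFrame(
        [(r, c, ",".join(ids)) for r, c, ids in rows],
        columns=["region", "count", "gene_ids"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_venn_json(v: VennSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(v.to_dict(), indent=2))


def plot_venn(v: VennSummary, path: str | Path) -> None:
    """Minimal two-circle Venn figure with region counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((-0.55, 0), 1.0, alpha=0.35, color="tab:blue"))
    ax.add_patch(Circle((0.55, 0), 1.0, alpha=0.35, color="tab:orange"))
    ax.text(-1.0, 0, str(v.unique_a), ha="center", va="center", fontsize=12)
    ax.text(1.0, 0, str(v.unique_b), ha="center", va="center", fontsize=12)
    label = str(v.common)
    if v.inconsistent_common:
        label += f"\n({v.inconsistent_common})"
    ax.text(0, 0, label, ha="center", va="center", fontsize=12)
    ax.text(-0.9, 1.12, v.name_a, ha="center", fontsize=10)
    ax.text(0.9, 1.12, v.name_b, ha="center", fontsize=10)
    ax.set_xlim(-1.9, 1.9)
    ax.set_ylim(-1.4, 1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
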