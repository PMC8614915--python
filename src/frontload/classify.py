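"""Frontloaded / relatively-upregulated gene classification.

The central question: among genes that respond to nitrogen deficiency in
only ONE of two near-isogenic genotypes, which ones does the *other*
(focal) genotype keep constitutively high — "frontloaded" — and which does
it raise only under stress — "relatively upregulated"?

Pipeline for a focal genotype F with other genotype O:

1. genotype-specific response: DEGs of O's N0-vs-N1 contrast minus DEGs of
   F's, each tagged with its direction in O;
2. expression filter: drop genes essentially unexpressed in F (mean
   normalized count below the floor in both treatments);
3. trend filter: drop genes whose between-genotype DE log2FC sign
   contradicts the raw normalized-mean difference, and genes with
   undefined F/O ratios;
4. split by O-direction: up -> frontload candidates, down -> relative-up
   candidates;
5. keep candidates significantly DE between genotypes under BOTH nitrogen
   levels;
6. classify by fold-change ratios r = (F mean + eps)/(O mean + eps):
   frontloaded iff r_N1 > ratio_high and r_N0 < ratio_low;
   relatively upregulated iff r_N1 < ratio_low and r_N0 > ratio_high.

Every stage's head-count is kept in :class:`Bookkeeping` so runs can be
audited the way published DEG-funnel numbers are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .de import ContrastResult, ContrastSpec, group_token, normalized_counts, size_factors
from .exceptions import ContrastSpecError, UndefinedRatioError
from .io import GENOTYPES, CountMatrix

LABELS = (
    "frontloaded",
    "relatively_upregulated",
    "candidate_unclassified",
    "not_candidate",
    "excluded_trend",
    "excluded_not_expressed",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the classification pipeline.

    ratio_high/ratio_low are the fold-change-ratio cuts (defaults 2 and
    0.5); expression_floor is the minimum mean normalized count, in at
    least one treatment of the focal genotype, for a gene to count as
    expressed; alpha/fc_min/pseudocount are shared with the DE stage.
    """

    ratio_high: float = 2.0
    ratio_low: float = 0.5
    expression_floor: float = 1.0
    alpha: float = 0.05
    fc_min: float = 1.0
    pseudocount: float = 1.0
    fc_strict: bool = False
    trend_filter_enabled: bool = True
    use_de_log2fc: bool = False

    def __post_init__(self) -> None:
        if not (self.ratio_low < 1.0 < self.ratio_high):
            raise ValueError("need ratio_low < 1 < ratio_high")


@dataclass(frozen=True)
class Bookkeeping:
    """Stage-by-stage gene counts of one classification run."""

    n_specific: int
    n_not_expressed: int
    n_trend_inconsistent: int
    n_classifiable: int
    n_up: int
    n_down: int
    n_candidate_front: int
    n_candidate_relup: int
    n_front: int
    n_relup: int

    def __post_init__(self) -> None:
        checks = [
            self.n_classifiable
            == self.n_specific - self.n_not_expressed - self.n_trend_inconsistent,
            self.n_classifiable == self.n_up + self.n_down,
            0 <= self.n_front <= self.n_candidate_front <= self.n_up,
            0 <= self.n_relup <= self.n_candidate_relup <= self.n_down,
        ]
        if not all(checks):
            raise ValueError(f"inconsistent bookkeeping: {self}")

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _require_response(r: ContrastResult, role: str) -> str:
    """Validate a within-genotype N0-vs-N1 contrast; return its genotype."""
    (g_num, t_num), (g_den, t_den) = r.spec.numerator, r.spec.denominator
    if g_num != g_den or (t_num, t_den) != ("N0", "N1"):
        raise ContrastSpecError(
            f"{role} contrast {r.name} is not a within-genotype N0-vs-N1 response"
        )
    return g_num


def genotype_specific_response(
    other_response: ContrastResult, focal_response: ContrastResult
) -> pd.Series:
    """DEGs responsive to N deficiency in the other genotype only.

    Returns a Series gene_id -> direction ('up'/'down') in the OTHER
    genotype, for genes DE in the other genotype's response contrast but
    not in the focal genotype's.
    """
    g_other = _require_response(other_response, "other")
    g_focal = _require_response(focal_response, "focal")
    if g_other == g_focal:
        raise ContrastSpecError("other and focal response contrasts share a genotype")
    other_t = other_response.table
    other_degs = other_t.index[other_t["is_deg"]]
    focal_t = focal_response.table
    focal_degs = set(focal_t.index[focal_t["is_deg"]])
    keep = [g for g in other_degs if g not in focal_degs]
    return other_t.loc[keep, "direction"].copy()


def expression_filter(
    genes: pd.Index | list[str],
    m: CountMatrix,
    focal: str,
    cfg: ClassifierConfig,
    norm: pd.DataFrame | None = None,
) -> tuple[list[str], int]:
    """Drop genes unexpressed in the focal genotype under both treatments."""
    if norm is None:
        norm = normalized_counts(m)
    genes = list(genes)
    mean_n1 = norm.loc[genes, m.samples.samples_for(focal, "N1")].mean(axis=1)
    mean_n0 = norm.loc[genes, m.samples.samples_for(focal, "N0")].mean(axis=1)
    expressed = (mean_n1 >= cfg.expression_floor) | (mean_n0 >= cfg.expression_floor)
    kept = [g for g, ok in zip(genes, expressed) if ok]
    return kept, len(genes) - len(kept)


def _sign_consistent(t: pd.DataFrame, genes: list[str]) -> pd.Series:
    """log2fc sign agrees with the raw mean difference (NaN means -> pass)."""
    sub = t.loc[genes]
    diff = sub["mean_num"] - sub["mean_den"]
    ok = np.sign(sub["log2fc"]) == np.sign(diff)
    return ok | diff.isna()


def trend_filter(
    genes: pd.Series,
    between_n1: ContrastResult,
    between_n0: ContrastResult,
) -> tuple[pd.Series, int]:
    """Drop direction-ambiguous genes before ratio classification.

    ``genes`` maps gene_id -> other-genotype direction. Both between
    contrasts must be oriented focal-vs-other. Removes genes whose DE-table
    log2fc sign disagrees with the sign of the raw normalized-mean
    difference in either contrast, and genes whose other-genotype mean is
    zero under both treatments (their raw fold-change ratio is undefined
    without a pseudocount).
    """
    ids = list(genes.index)
    if not ids:
        return genes, 0
    ok = _sign_consistent(between_n1.table, ids) & _sign_consistent(between_n0.table, ids)
    other_zero = (
        (between_n1.table.loc[ids, "mean_den"] == 0)
        & (between_n0.table.loc[ids, "mean_den"] == 0)
    ).fillna(False)
    keep = ok & ~other_zero
    kept = genes[keep.to_numpy()]
    return kept, len(ids) - len(kept)


def flip_contrast(r: ContrastResult) -> ContrastResult:
    """Swap numerator and denominator: negate log2fc, swap means and directions."""
    spec = ContrastSpec(
        f"{group_token(r.spec.denominator)}_vs_{group_token(r.spec.numerator)}",
        r.spec.denominator,
        r.spec.numerator,
    )
    t = r.table.copy()
    t[["mean_num", "mean_den"]] = t[["mean_den", "mean_num"]].to_numpy()
    t["log2fc"] = -t["log2fc"]
    t["direction"] = t["direction"].map({"up": "down", "down": "up", "none": "none"})
    return ContrastResult(spec, t, alpha=r.alpha, fc_min=r.fc_min)


@dataclass(frozen=True)
class ClassificationResult:
    """Per-gene labels and funnel bookkeeping for one focal genotype.

    ``table`` is indexed by gene_id (the genotype-specific response set)
    with columns other_direction, r_n1, r_n0, label.
    """

    focal: str
    table: pd.DataFrame
    bookkeeping: Bookkeeping
    config: ClassifierConfig

    def genes_labeled(self, label: str) -> list[str]:
        return sorted(self.table.index[self.table["label"] == label])

    @property
    def frontloaded(self) -> list[str]:
        return self.genes_labeled("frontloaded")

    @property
    def relatively_upregulated(self) -> list[str]:
        return self.genes_labeled("relatively_upregulated")

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "bookkeeping": self.bookkeeping.to_dict(),
            "thresholds": {
                "ratio_high": self.config.ratio_high,
                "ratio_low": self.config.ratio_low,
                "expression_floor": self.config.expression_floor,
                "alpha": self.config.alpha,
                "fc_min": self.config.fc_min,
                "pseudocount": self.config.pseudocount,
            },
        }


def _quartet_result(quartet: Mapping[str, ContrastResult], key: str) -> ContrastResult:
    try:
        return quartet[key]
    except KeyError:
        raise ContrastSpecError(
            f"contrast quartet missing {key!r}; need response_HI, response_LO, "
            "between_N1, between_N0"
        ) from None


def classify(
    m: CountMatrix,
    quartet: Mapping[str, ContrastResult],
    focal: str,
    cfg: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Run the full classification pipeline for one focal genotype.

    ``quartet`` holds the four standard contrasts keyed ``response_HI``,
    ``response_LO``, ``between_N1``, ``between_N0`` (between contrasts
    oriented HI vs LO; they are flipped internally when focal is LO).
    """
    cfg = cfg or ClassifierConfig()
    if focal not in GENOTYPES:
        raise ContrastSpecError(f"unknown focal genotype {focal!r}")
    other = "LO" if focal == "HI" else "HI"

    focal_resp = _quartet_result(quartet, f"response_{focal}")
    other_resp = _quartet_result(quartet, f"response_{other}")
    between_n1 = _quartet_result(quartet, "between_N1")
    between_n0 = _quartet_result(quartet, "between_N0")
    if focal == "LO":
        between_n1 = flip_contrast(between_n1)
        between_n0 = flip_contrast(between_n0)
    for r, tr in ((between_n1, "N1"), (between_n0, "N0")):
        if r.spec.numerator != (focal, tr) or r.spec.denominator != (other, tr):
            raise ContrastSpecError(
                f"between_{tr} contrast {r.name} is not oriented {focal} vs {other} within {tr}"
            )

    # stage 1: genotype-specific N response, tagged with the other genotype's direction
    directions = genotype_specific_response(other_resp, focal_resp)
    n_specific = len(directions)

    sf = size_factors(m)
    norm = normalized_counts(m, sf)

    # stage 2: expression floor in the focal genotype
    expressed, n_not_expressed = expression_filter(
        directions.index, m, focal, cfg, norm=norm
    )
    after_expr = directions.loc[expressed]

    # stage 3: trend consistency
    if cfg.trend_filter_enabled:
        classifiable, n_trend = trend_filter(after_expr, between_n1, between_n0)
    else:
        classifiable, n_trend = after_expr, 0

    # fold-change ratios focal/other per treatment, for every specific gene
    eps = cfg.pseudocount
    if cfg.use_de_log2fc:
        r_n1_all = np.power(2.0, between_n1.table["log2fc"])
        r_n0_all = np.power(2.0, between_n0.table["log2fc"])
    else:
        focal_mean = {
            tr: norm[m.samples.samples_for(focal, tr)].mean(axis=1) for tr in ("N1", "N0")
        }
        other_mean = {
            tr: norm[m.samples.samples_for(other, tr)].mean(axis=1) for tr in ("N1", "N0")
        }
        r_n1_all = (focal_mean["N1"] + eps) / (other_mean["N1"] + eps)
        r_n0_all = (focal_mean["N0"] + eps) / (other_mean["N0"] + eps)

    genes = list(directions.index)
    table = pd.DataFrame(
        {
            "other_direction": directions,
            "r_n1": r_n1_all.reindex(genes),
            "r_n0": r_n0_all.reindex(genes),
            "label": "not_candidate",
        },
        index=pd.Index(genes, name="gene_id"),
    )
    removed_expr = set(genes) - set(expressed)
    removed_trend = set(expressed) - set(classifiable.index)
    table.loc[sorted(removed_expr), "label"] = "excluded_not_expressed"
    table.loc[sorted(removed_trend), "label"] = "excluded_trend"

    # stages 4-6 on the classifiable set
    n_up = int((classifiable == "up").sum())
    n_down = int((classifiable == "down").sum())
    deg_both = (
        between_n1.table["is_deg"].reindex(classifiable.index, fill_value=False)
        & between_n0.table["is_deg"].reindex(classifiable.index, fill_value=False)
    )
    cand_front = classifiable.index[(classifiable == "up") & deg_both]
    cand_relup = classifiable.index[(classifiable == "down") & deg_both]
    table.loc[list(cand_front) + list(cand_relup), "label"] = "candidate_unclassified"

    r1 = table["r_n1"]
    r0 = table["r_n0"]
    front = [
        g for g in cand_front
        if r1[g] > cfg.ratio_high and r0[g] < cfg.ratio_low
    ]
    relup = [
        g for g in cand_relup
        if r1[g] < cfg.ratio_low and r0[g] > cfg.ratio_high
    ]
    table.loc[front, "label"] = "frontloaded"
    table.loc[relup, "label"] = "relatively_upregulated"

    bk = Bookkeeping(
        n_specific=n_specific,
        n_not_expressed=n_not_expressed,
        n_trend_inconsistent=n_trend,
        n_classifiable=len(classifiable),
        n_up=n_up,
        n_down=n_down,
        n_candidate_front=len(cand_front),
        n_candidate_relup=len(cand_relup),
        n_front=len(front),
        n_relup=len(relup),
    )
    return ClassificationResult(focal=focal, table=table, bookkeeping=bk, config=cfg)


def summary_ratio(res_a: ClassificationResult, res_b: ClassificationResult) -> float:
    """Ratio of frontloaded-gene counts between the two focal genotypes."""
    if res_b.bookkeeping.n_front == 0:
        raise UndefinedRatioError(
            f"no frontloaded genes in focal {res_b.focal}; ratio undefined"
        )
    return res_a.bookkeeping.n_front / res_b.bookkeeping.n_front
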