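"""Negative-binomial count simulation with planted gene archetypes.

Generates two-genotype x two-nitrogen-level count matrices whose genes
follow known expression archetypes, together with a ground-truth table, so
the whole downstream pipeline (differential expression, set algebra,
frontloaded-gene classification) can be benchmarked without any external
dataset.

Archetypes (focal genotype HI shown; LO archetypes are genotype mirrors):

* ``frontloaded_in_HI`` — HI sits high and flat across nitrogen levels;
  LO starts low under normal N and surges under deficiency. The gene is
  N-responsive only in LO, higher in HI under N1 and lower under N0.
* ``relatively_up_in_HI`` — the mirror image: HI low and flat, LO starts
  high and collapses under deficiency.
* ``shared_response`` — both genotypes respond to deficiency equally.
* ``constitutive_difference`` — a fixed between-genotype offset, no
  nitrogen response.
* ``null`` — flat everywhere.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleSheet


class Archetype(str, enum.Enum):
    FRONTLOADED_IN_HI = "frontloaded_in_HI"
    RELATIVELY_UP_IN_HI = "relatively_up_in_HI"
    FRONTLOADED_IN_LO = "frontloaded_in_LO"
    RELATIVELY_UP_IN_LO = "relatively_up_in_LO"
    SHARED_RESPONSE = "shared_response"
    CONSTITUTIVE_DIFFERENCE = "constitutive_difference"
    NULL = "null"


class GroupMeans(NamedTuple):
    """Expected fragments per cell of the 2x2 design (at unit size factor)."""

    hi_n1: float
    hi_n0: float
    lo_n1: float
    lo_n0: float


@dataclass(frozen=True)
class ArchetypeSpec:
    """How many genes of one archetype to plant, and at what effect sizes.

    ``between_genotype_fold`` separates the genotypes (default 4, i.e. a
    comfortable margin over the classifier's ratio-2 threshold);
    ``response_fold`` is the nitrogen-deficiency response of the responsive
    genotype (default 16, log2FC = 4).
    """

    name: Archetype
    n_genes: int
    baseline_mean: float = 100.0
    between_genotype_fold: float = 4.0
    response_fold: float = 16.0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.name != Archetype.NULL and (
            self.between_genotype_fold <= 1 or self.response_fold <= 1
        ):
            raise ValueError("effect folds must exceed 1 for non-null archetypes")


def plant_means(spec: ArchetypeSpec) -> GroupMeans:
    """Expected group means for one gene of the given archetype.

    For ``frontloaded_in_HI`` with baseline m and folds (g, r):
    (HI,N1)=g*m, (HI,N0)=g*m, (LO,N1)=m, (LO,N0)=r*m — so the HI/LO ratio
    is g under normal N and g/r under deficiency, and only LO responds.
    ``relatively_up_in_HI`` divides instead of multiplying.
    """
    m = spec.baseline_mean
    g = spec.between_genotype_fold
    r = spec.response_fold
    a = spec.name
    if a == Archetype.NULL:
        return GroupMeans(m, m, m, m)
    if a == Archetype.FRONTLOADED_IN_HI:
        return GroupMeans(g * m, g * m, m, r * m)
    if a == Archetype.RELATIVELY_UP_IN_HI:
        return GroupMeans(m / g, m / g, m, m / r)
    if a == Archetype.FRONTLOADED_IN_LO:
        return GroupMeans(m, r * m, g * m, g * m)
    if a == Archetype.RELATIVELY_UP_IN_LO:
        return GroupMeans(m, m / r, m / g, m / g)
    if a == Archetype.SHARED_RESPONSE:
        return GroupMeans(m, r * m, m, r * m)
    if a == Archetype.CONSTITUTIVE_DIFFERENCE:
        return GroupMeans(g * m, g * m, m, m)
    raise ValueError(f"unknown archetype {a!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated experiment.

    Counts are drawn NB(mean mu * depth, variance mu + phi * mu^2); the
    dispersion ``phi`` (default 0.05) is shared across genes. Depth factors
    default to 1.0 per sample; ``lognormal_depth_sigma`` > 0 draws them
    log-normally to mimic library-size variation.
    """

    archetypes: tuple[ArchetypeSpec, ...]
    replicates_per_group: int = 3
    dispersion: float = 0.05
    depth_factors: tuple[float, ...] | None = None
    lognormal_depth_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "archetypes", tuple(self.archetypes))
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        n_samples = 4 * self.replicates_per_group
        if self.depth_factors is not None:
            df = tuple(float(x) for x in self.depth_factors)
            if len(df) != n_samples or any(x <= 0 for x in df):
                raise ValueError(f"depth_factors must be {n_samples} positive reals")
            object.__setattr__(self, "depth_factors", df)

    @property
    def n_genes(self) -> int:
        return sum(a.n_genes for a in self.archetypes)


# Planted composition used throughout the package's own benchmarks:
# 2000 genes, both focal genotypes represented, plus confounder archetypes.
DEFAULT_PLANT = (
    (Archetype.FRONTLOADED_IN_HI, 120),
    (Archetype.RELATIVELY_UP_IN_HI, 80),
    (Archetype.FRONTLOADED_IN_LO, 120),
    (Archetype.RELATIVELY_UP_IN_LO, 80),
    (Archetype.SHARED_RESPONSE, 300),
    (Archetype.CONSTITUTIVE_DIFFERENCE, 300),
    (Archetype.NULL, 1000),
)


def default_config(seed: int = 0, replicates_per_group: int = 3) -> SimulationConfig:
    """The standard benchmark: 2000 genes with the default planted classes."""
    return SimulationConfig(
        archetypes=tuple(ArchetypeSpec(name, n) for name, n in DEFAULT_PLANT),
        replicates_per_group=replicates_per_group,
        seed=seed,
    )


def null_config(n_genes: int = 2000, seed: int = 0) -> SimulationConfig:
    """An all-null simulation for false-positive control checks."""
    return SimulationConfig(
        archetypes=(ArchetypeSpec(Archetype.NULL, n_genes),), seed=seed
    )


def design_sheet(replicates_per_group: int = 3) -> SampleSheet:
    """Sample sheet for the 2x2 factorial with the given replication."""
    rows = []
    for g in ("HI", "LO"):
        for tr in ("N1", "N0"):
            for rep in range(1, replicates_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{tr}_{g}_r{rep}",
                        "genotype": g,
                        "treatment": tr,
                        "replicate": rep,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    # NB with variance mu + phi*mu^2 <=> shape n = 1/phi, p = n/(n+mu)
    n = 1.0 / phi
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its ground-truth table.

    Returns
    -------
    (CountMatrix, DataFrame)
        The truth table has one row per gene: ``gene_id``, ``archetype``,
        and the four planted cell means ``mu_hi_n1 .. mu_lo_n0``.
    """
    rng = np.random.default_rng(config.seed)
    sheet = design_sheet(config.replicates_per_group)
    n_samples = len(sheet.sample_ids)

    if config.depth_factors is not None:
        depth = np.asarray(config.depth_factors, dtype=float)
    elif config.lognormal_depth_sigma > 0:
        depth = rng.lognormal(0.0, config.lognormal_depth_sigma, size=n_samples)
    else:
        depth = np.ones(n_samples)

    gene_ids: list[str] = []
    truth_rows: list[dict] = []
    mu_rows: list[np.ndarray] = []
    cell_of_sample = [
        (row.genotype, row.treatment) for row in sheet.table.itertuples()
    ]
    for spec in config.archetypes:
        means = plant_means(spec)
        cell_mu = {
            ("HI", "N1"): means.hi_n1,
            ("HI", "N0"): means.hi_n0,
            ("LO", "N1"): means.lo_n1,
            ("LO", "N0"): means.lo_n0,
        }
        per_sample = np.array([cell_mu[c] for c in cell_of_sample])
        for i in range(spec.n_genes):
            gid = f"{spec.name.value}_{i:04d}"
            gene_ids.append(gid)
            truth_rows.append(
                {
                    "gene_id": gid,
                    "archetype": spec.name.value,
                    "mu_hi_n1": means.hi_n1,
                    "mu_hi_n0": means.hi_n0,
                    "mu_lo_n1": means.lo_n1,
                    "mu_lo_n0": means.lo_n0,
                }
            )
            mu_rows.append(per_sample)

    if gene_ids:
        mu = np.vstack(mu_rows) * depth[None, :]
        counts = _nb_draw(rng, mu, config.dispersion)
    else:
        counts = np.zeros((0, n_samples), dtype=int)
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                     columns=sheet.sample_ids),
        sheet,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "archetype", "mu_hi_n1", "mu_hi_n0", "mu_lo_n1", "mu_lo_n0"],
    )
    return cm, truth


def write_dataset(
    config: SimulationConfig, outdir: str | Path
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate and write counts.tsv, samples.tsv, truth.tsv and meta.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate(config)
    cm.to_tsv(outdir / "counts.tsv")
    cm.samples.to_tsv(outdir / "samples.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    meta = {
        "seed": config.seed,
        "replicates_per_group": config.replicates_per_group,
        "dispersion": config.dispersion,
        "n_genes": config.n_genes,
        "archetypes": [
            {
                "name": a.name.value,
                "n_genes": a.n_genes,
                "baseline_mean": a.baseline_mean,
                "between_genotype_fold": a.between_genotype_fold,
                "response_fold": a.response_fold,
            }
            for a in config.archetypes
        ],
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    return cm, truth
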