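"""Model/Results interface tying the pipeline together.

:class:`FrontloadModel` holds a count matrix plus thresholds;
:meth:`FrontloadModel.fit` runs size-factor normalization, the four
standard contrasts, the Venn set algebra and the frontloaded-gene
classification for both focal genotypes, returning a
:class:`FrontloadResults` carrying every intermediate table, the funnel
bookkeeping, and a printable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .simulate import SimulationConfig, default_config
from .simulate import simulate as run_simulation
from .classify import (
    ClassificationResult,
    ClassifierConfig,
    classify,
    summary_ratio,
)
from .de import ContrastResult, de_quartet, read_contrast_table, size_factors
from .exceptions import FrontloadError, UndefinedRatioError
from .io import CountMatrix, SampleSheet
from .sets import DegSet, VennSummary, deg_set, plot_venn, venn_pairwise, write_venn_tsv

logger = logging.getLogger(__name__)


class FrontloadModel:
    """Dual-genotype nitrogen-response analysis of one count matrix.

    Parameters
    ----------
    counts : CountMatrix
        Gene-level fragment counts with a 2x2 (genotype x nitrogen)
        design and >= 2 replicates per cell.
    config : ClassifierConfig, optional
        Shared thresholds for the DE stage and the classifier.
    """

    def __init__(self, counts: CountMatrix, config: ClassifierConfig | None = None):
        counts.samples.validate_design()
        self.counts = counts
        self.config = config or ClassifierConfig()

    @classmethod
    def from_files(
        cls,
        counts_tsv: str | Path,
        sheet_tsv: str | Path,
        config: ClassifierConfig | None = None,
    ) -> "FrontloadModel":
        from .io import read_counts

        sheet = SampleSheet.from_tsv(sheet_tsv)
        return cls(read_counts(counts_tsv, sheet), config=config)

    @classmethod
    def from_simulation(
        cls, sim_config: SimulationConfig, config: ClassifierConfig | None = None
    ) -> tuple["FrontloadModel", pd.DataFrame]:
        counts, truth = run_simulation(sim_config)
        return cls(counts, config=config), truth

    def fit(
        self, quartet: Mapping[str, ContrastResult] | None = None
    ) -> "FrontloadResults":
        """Run the full pipeline.

        ``quartet`` may inject externally computed contrast tables (keys
        response_HI, response_LO, between_N1, between_N0); missing keys
        are computed internally.
        """
        cfg = self.config
        computed = de_quartet(
            self.counts,
            alpha=cfg.alpha,
            fc_min=cfg.fc_min,
            pseudocount=cfg.pseudocount,
            fc_strict=cfg.fc_strict,
        )
        if quartet:
            computed.update(quartet)
        degs = {k: deg_set(r) for k, r in computed.items()}
        venns = {
            "response": venn_pairwise(degs["response_LO"], degs["response_HI"]),
            "between": venn_pairwise(degs["between_N1"], degs["between_N0"]),
        }
        classifications = {
            g: classify(self.counts, computed, focal=g, cfg=cfg) for g in ("HI", "LO")
        }
        return FrontloadResults(
            model=self,
            size_factors=size_factors(self.counts),
            contrasts=dict(computed),
            deg_sets=degs,
            venns=venns,
            classifications=classifications,
        )


@dataclass
class FrontloadResults:
    """Everything one fit produced, with savers and a text summary."""

    model: FrontloadModel
    size_factors: pd.Series
    contrasts: dict[str, ContrastResult]
    deg_sets: dict[str, DegSet]
    venns: dict[str, VennSummary]
    classifications: dict[str, ClassificationResult]

    def summary_ratio(self, focal_a: str = "HI", focal_b: str = "LO") -> float:
        return summary_ratio(self.classifications[focal_a], self.classifications[focal_b])

    def deg_counts(self) -> pd.DataFrame:
        rows = [
            {"contrast": r.name, "up": len(self.deg_sets[k].up),
             "down": len(self.deg_sets[k].down), "total": self.deg_sets[k].total}
            for k, r in self.contrasts.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Frontload analysis summary", "=" * 60]
        lines.append(f"genes: {self.model.counts.shape[0]}  "
                     f"samples: {self.model.counts.shape[1]}")
        cfg = self.model.config
        lines.append(
            f"thresholds: alpha={cfg.alpha} |log2FC|>={cfg.fc_min} "
            f"ratio>{cfg.ratio_high}/<{cfg.ratio_low} floor={cfg.expression_floor}"
        )
        lines.append("")
        lines.append("DEG counts per contrast")
        lines.append(self.deg_counts().to_string(index=False))
        lines.append("")
        for key, v in self.venns.items():
            lines.append(
                f"Venn [{key}] {v.name_a} vs {v.name_b}: common={v.common} "
                f"(inconsistent {v.inconsistent_common}), "
                f"unique={v.unique_a}/{v.unique_b}"
            )
        lines.append("")
        for g, c in self.classifications.items():
            bk = c.bookkeeping
            lines.append(
                f"focal {g}: specific={bk.n_specific} "
                f"-{bk.n_not_expressed} not-expressed -{bk.n_trend_inconsistent} trend "
                f"-> {bk.n_classifiable} ({bk.n_up} up / {bk.n_down} down); "
                f"frontloaded={bk.n_front} relatively_up={bk.n_relup}"
            )
        try:
            lines.append(f"frontloaded ratio HI/LO: {self.summary_ratio():.2f}")
        except UndefinedRatioError:
            lines.append("frontloaded ratio HI/LO: undefined (zero in denominator)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        report = {
            "deg_counts": self.deg_counts().to_dict(orient="records"),
            "venn": {k: v.to_dict() for k, v in self.venns.items()},
            "classification": {g: c.to_dict() for g, c in self.classifications.items()},
        }
        try:
            report["frontloaded_ratio_HI_over_LO"] = self.summary_ratio()
        except UndefinedRatioError:
            report["frontloaded_ratio_HI_over_LO"] = None
        return report

    def save(self, outdir: str | Path, figures: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.size_factors.rename_axis("sample_id").to_csv(
            outdir / "size_factors.tsv", sep="\t"
        )
        for key, r in self.contrasts.items():
            r.to_tsv(outdir / f"contrast_{r.name}.tsv")
        for key, v in self.venns.items():
            write_venn_tsv(v, outdir / f"venn_{key}.tsv")
            if figures:
                plot_venn(v, outdir / f"venn_{key}.png")
        for g, c in self.classifications.items():
            c.to_tsv(outdir / f"classification_{g}.tsv")
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_classification(
    classifications: Mapping[str, ClassificationResult], truth: pd.DataFrame
) -> pd.DataFrame:
    """Sensitivity/precision of the classifier against a planted truth table.

    For each focal genotype G, planted archetype ``frontloaded_in_G`` is
    the positive set for label ``frontloaded``, and ``relatively_up_in_G``
    for ``relatively_upregulated``.
    """
    truth_sets = {
        a: set(truth.loc[truth["archetype"] == a, "gene_id"]) for a in truth["archetype"].unique()
    }
    rows = []
    for g, c in classifications.items():
        for label, archetype in (
            ("frontloaded", f"frontloaded_in_{g}"),
            ("relatively_upregulated", f"relatively_up_in_{g}"),
        ):
            pred = set(c.genes_labeled(label))
            pos = truth_sets.get(archetype, set())
            tp = len(pred & pos)
            rows.append(
                {
                    "focal": g,
                    "class": label,
                    "n_true": len(pos),
                    "n_pred": len(pred),
                    "tp": tp,
                    "sensitivity": tp / len(pos) if pos else float("nan"),
                    "precision": tp / len(pred) if pred else float("nan"),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-loadable)."""

    counts: str | None = None
    sheet: str | None = None
    lengths: str | None = None
    term_map: str | None = None
    ct_table: str | None = None
    outdir: str = "frontload_out"
    seed: int = 0
    simulate: bool = False
    n_null_genes: int | None = None
    figures: bool = False
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(**self.thresholds)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> FrontloadResults:
    """Execute the full pipeline from a run configuration.

    With ``simulate`` true (or no counts path), the default planted
    benchmark is generated at ``seed``; otherwise counts and sheet are
    read from the configured paths. All outputs, a summary report and the
    run metadata (config hash + seed) land in ``outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ccfg = cfg.classifier_config()
    truth = None
    if cfg.simulate or cfg.counts is None:
        sim_cfg = default_config(seed=cfg.seed)
        model, truth = FrontloadModel.from_simulation(sim_cfg, config=ccfg)
        model.counts.to_tsv(outdir / "counts.tsv")
        model.counts.samples.to_tsv(outdir / "samples.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    else:
        model = FrontloadModel.from_files(cfg.counts, cfg.sheet, config=ccfg)
    results = model.fit()
    results.save(outdir, figures=cfg.figures)
    if truth is not None:
        metrics = evaluate_classification(results.classifications, truth)
        metrics.to_csv(outdir / "recovery_metrics.tsv", sep="\t", index=False)
    meta = {"config_hash": cfg.digest(), "seed": cfg.seed, "config": asdict(cfg)}
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))
    logger.info("pipeline finished; outputs in %s", outdir)
    return results
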