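"""Per-contrast differential expression.

The pipeline needs, for each named contrast, per-gene normalized group
means, a log2 fold change, a p-value, a Benjamini-Hochberg adjusted
p-value, and the DEG flag (adjusted p < alpha and |log2FC| >= fc_min).
Counts are normalized by median-of-ratios size factors. The default test
engine is a moderated two-sided t on log2(normalized count + 1): per-gene
pooled variances are shrunk toward a common prior fitted across genes by
empirical Bayes (Smyth's scaled inverse-chi-squared moment fit), which is
what gives usable power at 3 replicates. A plain Welch t is available via
``engine="welch"``, and the engine is deliberately pluggable — results
from any external DE tool can be ingested through
:func:`read_contrast_table` and flow through the rest of the pipeline
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ContrastSpecError, DomainError, SchemaError
from .io import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)

Group = tuple[str, str]  # (genotype, treatment)


def group_token(group: Group) -> str:
    genotype, treatment = group
    return f"{treatment}_{genotype}"


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-group comparison; the numerator is the first-listed group."""

    name: str
    numerator: Group
    denominator: Group

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ContrastSpecError(f"contrast {self.name}: numerator == denominator")

    @classmethod
    def between(cls, numerator: Group, denominator: Group) -> "ContrastSpec":
        name = f"{group_token(numerator)}_vs_{group_token(denominator)}"
        return cls(name, numerator, denominator)


def response_contrast(genotype: str) -> ContrastSpec:
    """Within-genotype nitrogen response: N0 (deficient) vs N1 (normal)."""
    return ContrastSpec.between((genotype, "N0"), (genotype, "N1"))


def between_contrast(treatment: str, focal: str = "HI", other: str = "LO") -> ContrastSpec:
    """Between-genotype contrast within one nitrogen level, focal vs other."""
    return ContrastSpec.between((focal, treatment), (other, treatment))


def quartet_specs() -> dict[str, ContrastSpec]:
    """The four standard contrasts of the 2x2 design."""
    return {
        "response_HI": response_contrast("HI"),
        "response_LO": response_contrast("LO"),
        "between_N1": between_contrast("N1"),
        "between_N0": between_contrast("N0"),
    }


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene DE statistics for one contrast.

    ``table`` is indexed by gene_id with columns mean_num, mean_den,
    log2fc, p, padj, is_deg, direction ('up'/'down'/'none').
    """

    spec: ContrastSpec
    table: pd.DataFrame
    alpha: float = 0.05
    fc_min: float = 1.0

    @property
    def name(self) -> str:
        return self.spec.name

    def deg_ids(self) -> pd.Index:
        return self.table.index[self.table["is_deg"]]

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    factor_j = median over genes g of count_gj / geomean_g, taken over
    genes with strictly positive counts in every sample. When no such gene
    exists the factors fall back to column sums scaled to mean 1 (logged
    as a warning).
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        logger.warning(
            "no gene has positive counts in every sample; "
            "falling back to column-sum size factors"
        )
        colsum = counts.sum(axis=0)
        if colsum.sum() == 0:
            raise DomainError("count matrix is all zero; size factors undefined")
        sf = colsum / colsum.mean()
    else:
        logs = np.log(counts[all_pos])
        log_geomean = logs.mean(axis=1)
        sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=m.counts.columns, name="size_factor")


def normalized_counts(m: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(m)
    return m.counts / sf


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y + 1/(2y^2); start from the 1/y approximation
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = (tri - x) / special.polygamma(2, y)
        y -= step
        if y <= 0:
            y = 1e-8
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment fit of the scaled inverse-chi^2 variance prior (s0^2, d0).

    Per-gene sample variances s2 (residual df d each) are modeled as
    s0^2 * chi^2_d/d scaled by a gene-level inverse-chi^2_{d0} prior; the
    fit works on log variances via digamma/trigamma moments.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return float(s2.mean()) if s2.size else 0.0, np.inf
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        return float(np.exp(emean)), np.inf
    half_d0 = _trigamma_inverse(float(evar))
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return s0_2, d0


def _moderated_t_pvalues(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Empirical-Bayes moderated t p-values between two log-expression groups."""
    n1, n2 = la.shape[1], lb.shape[1]
    d = n1 + n2 - 2
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * va + (n2 - 1) * vb) / d
    s0_2, d0 = _fit_variance_prior(s2, d)
    if not np.isfinite(d0):
        s2_post = np.full_like(s2, s0_2)
        df = 1e6  # prior dominates: effectively a z-test
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df = d0 + d
    diff = la.mean(axis=1) - lb.mean(axis=1)
    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # all-variances-zero corner: call equal means null, unequal means certain
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        p = np.where(degenerate, np.where(np.isclose(diff, 0.0), 1.0, 0.0), p)
    return p


def _welch_t_pvalues(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    return p


ENGINES = {"moderated": _moderated_t_pvalues, "welch": _welch_t_pvalues}


def _flag(table: pd.DataFrame, alpha: float, fc_min: float, fc_strict: bool) -> pd.DataFrame:
    fc_ok = (
        table["log2fc"].abs() > fc_min if fc_strict else table["log2fc"].abs() >= fc_min
    )
    table["is_deg"] = (table["padj"] < alpha) & fc_ok
    table["direction"] = np.where(
        ~table["is_deg"], "none", np.where(table["log2fc"] > 0, "up", "down")
    )
    return table


def de_test(
    m: CountMatrix,
    contrast: ContrastSpec,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    pseudocount: float = 1.0,
    fc_strict: bool = False,
    sf: pd.Series | None = None,
    engine: str = "moderated",
) -> ContrastResult:
    """Differential expression for one contrast.

    log2fc = log2((mean_num + eps) / (mean_den + eps)) on size-factor
    normalized counts; p from the selected engine's two-sided t on
    log2(normalized + 1) (``moderated`` = empirical-Bayes variance
    shrinkage, ``welch`` = plain per-gene Welch); padj by
    Benjamini-Hochberg. Genes where both groups have zero variance get
    p = 1 when the group means agree and p = 0 otherwise.
    """
    sheet: SampleSheet = m.samples
    num_cols = sheet.samples_for(*contrast.numerator)
    den_cols = sheet.samples_for(*contrast.denominator)
    for group, cols in ((contrast.numerator, num_cols), (contrast.denominator, den_cols)):
        if len(cols) < 2:
            raise ContrastSpecError(
                f"contrast {contrast.name}: group {group} has {len(cols)} samples; need >= 2"
            )
    norm = normalized_counts(m, sf)
    a = norm[num_cols].to_numpy()
    b = norm[den_cols].to_numpy()
    mean_num = a.mean(axis=1)
    mean_den = b.mean(axis=1)
    log2fc = np.log2((mean_num + pseudocount) / (mean_den + pseudocount))

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    try:
        p = ENGINES[engine](la, lb)
    except KeyError:
        raise ValueError(f"unknown DE engine {engine!r}; choose from {sorted(ENGINES)}") from None

    table = pd.DataFrame(
        {
            "mean_num": mean_num,
            "mean_den": mean_den,
            "log2fc": log2fc,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=m.counts.index,
    )
    table = _flag(table, alpha, fc_min, fc_strict)
    return ContrastResult(contrast, table, alpha=alpha, fc_min=fc_min)


def de_quartet(
    m: CountMatrix,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    pseudocount: float = 1.0,
    fc_strict: bool = False,
    engine: str = "moderated",
) -> dict[str, ContrastResult]:
    """Run the four standard contrasts with shared size factors."""
    m.samples.validate_design()
    sf = size_factors(m)
    return {
        key: de_test(m, spec, alpha=alpha, fc_min=fc_min,
                     pseudocount=pseudocount, fc_strict=fc_strict, sf=sf,
                     engine=engine)
        for key, spec in quartet_specs().items()
    }


def read_contrast_table(
    path: str | Path,
    name: str = "external",
    alpha: float = 0.05,
    fc_min: float = 1.0,
    fc_strict: bool = False,
    numerator: Group = ("HI", "N0"),
    denominator: Group = ("HI", "N1"),
) -> ContrastResult:
    """Ingest a DE table produced by any external tool.

    Requires columns gene_id, log2fc, p; padj is recomputed by BH when
    absent. DEG flags are always recomputed from the thresholds, never
    trusted from the file.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "p"} - set(df.columns)
    if missing:
        raise SchemaError(f"DE table {path} missing columns: {sorted(missing)}")
    df = df.set_index(df["gene_id"].astype(str)).drop(columns="gene_id")
    if "padj" not in df.columns:
        df["padj"] = bh_adjust(df["p"].to_numpy())
    for col in ("mean_num", "mean_den"):
        if col not in df.columns:
            df[col] = np.nan
    table = df[["mean_num", "mean_den", "log2fc", "p", "padj"]].copy()
    table = _flag(table, alpha, fc_min, fc_strict)
    return ContrastResult(ContrastSpec(name, numerator, denominator), table,
                          alpha=alpha, fc_min=fc_min)
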