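"""Core data containers and TSV readers/writers.

The analysis operates on a gene-level fragment count matrix for a
two-genotype (high-NUE ``HI`` / low-NUE ``LO``) by two-nitrogen-level
(normal ``N1`` / deficient ``N0``) factorial design with biological
replicates. This module holds the sample sheet and count matrix
containers, FPKM computation, and the read-mapping QC percentage
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, TableParseError, UndefinedRatioError

GENOTYPES = ("HI", "LO")
TREATMENTS = ("N1", "N0")

SHEET_COLUMNS = ["sample_id", "genotype", "treatment", "replicate"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how tables print percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SampleSheet:
    """Design metadata: one row per sequenced library.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``sample_id``, ``genotype`` (``HI``/``LO``), ``treatment``
        (``N1``/``N0``), ``replicate`` (positive integer).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"sample sheet missing columns: {missing}")
        t = self.table.reset_index(drop=True)[SHEET_COLUMNS].copy()
        t["sample_id"] = t["sample_id"].astype(str)
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise SchemaError(f"duplicate sample ids: {dups}")
        bad_g = sorted(set(t["genotype"]) - set(GENOTYPES))
        if bad_g:
            raise SchemaError(f"unknown genotypes {bad_g}; expected {GENOTYPES}")
        bad_t = sorted(set(t["treatment"]) - set(TREATMENTS))
        if bad_t:
            raise SchemaError(f"unknown treatments {bad_t}; expected {TREATMENTS}")
        rep = pd.to_numeric(t["replicate"], errors="coerce")
        if rep.isna().any() or (rep <= 0).any() or (rep != rep.astype(int)).any():
            raise SchemaError("replicate must be a positive integer for every sample")
        t["replicate"] = rep.astype(int)
        object.__setattr__(self, "table", t)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, genotype: str, treatment: str) -> list[str]:
        """Sample ids belonging to one (genotype, treatment) group."""
        m = (self.table["genotype"] == genotype) & (self.table["treatment"] == treatment)
        return list(self.table.loc[m, "sample_id"])

    def validate_design(self, min_replicates: int = 2) -> None:
        """Require every genotype x treatment cell, each with enough replicates."""
        for g in GENOTYPES:
            for tr in TREATMENTS:
                n = len(self.samples_for(g, tr))
                if n < min_replicates:
                    raise SchemaError(
                        f"group ({g}, {tr}) has {n} replicates; "
                        f"need >= {min_replicates}"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CountMatrix:
    """Raw fragment counts, genes x samples, tied to a :class:`SampleSheet`.

    Columns are ordered exactly as the sheet lists its samples; counts are
    non-negative integers.
    """

    counts: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        sheet_ids = self.samples.sample_ids
        cols = list(self.counts.columns)
        missing = [s for s in sheet_ids if s not in cols]
        extra = [s for s in cols if s not in sheet_ids]
        if missing or extra:
            raise SchemaError(
                f"count matrix / sample sheet mismatch: missing={missing}, extra={extra}"
            )
        df = self.counts[sheet_ids].rename_axis("gene_id")
        if df.index.has_duplicates:
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise SchemaError(f"duplicate gene ids: {dups[:10]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            _locate_bad_cell(df)
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            _locate_bad_cell(df)
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def group_columns(self, genotype: str, treatment: str) -> pd.DataFrame:
        return self.counts[self.samples.samples_for(genotype, treatment)]

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def _locate_bad_cell(df: pd.DataFrame) -> None:
    """Raise TableParseError naming the first non-integer / negative cell."""
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        for gene, raw, v in zip(df.index, df[col], vals):
            if pd.isna(v) or v < 0 or v != int(v):
                raise TableParseError(
                    f"invalid count {raw!r} at gene {gene!r}, sample {col!r}: "
                    "counts must be non-negative integers"
                )
    raise TableParseError("count matrix contains invalid cells")


def read_counts(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a genes x samples count TSV and bind it to a sample sheet.

    The first column holds gene ids; the header row holds sample ids, which
    must match the sheet exactly (order may differ; columns are reordered).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix(df, sheet)


class GeneLengths:
    """gene_id -> transcript length in base pairs (all > 0)."""

    def __init__(self, lengths: Mapping[str, int] | pd.Series):
        s = pd.Series(lengths, dtype=float)
        if (s <= 0).any() or s.isna().any():
            bad = sorted(s.index[(s <= 0) | s.isna()])
            raise SchemaError(f"non-positive or missing gene lengths: {bad[:10]}")
        self.series = s

    def __getitem__(self, gene: str) -> float:
        return float(self.series[gene])

    def __contains__(self, gene: str) -> bool:
        return gene in self.series.index

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneLengths":
        df = pd.read_csv(path, sep="\t")
        if not {"gene_id", "length_bp"} <= set(df.columns):
            raise SchemaError("gene-length table needs columns gene_id, length_bp")
        return cls(pd.Series(df["length_bp"].values, index=df["gene_id"].astype(str)))

    def to_tsv(self, path: str | Path) -> None:
        out = self.series.rename("length_bp").rename_axis("gene_id").astype(int)
        out.to_csv(path, sep="\t")


def compute_fpkm(
    m: CountMatrix,
    lengths: GeneLengths,
    library_sizes: Sequence[float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_gj = count_gj * 1e9 / (length_g[bp] * library_size_j).

    ``library_sizes`` defaults to per-sample column sums of the count
    matrix; pass explicit mapped-fragment totals to reproduce
    alignment-report semantics.
    """
    missing = [g for g in m.gene_ids if g not in lengths]
    if missing:
        raise SchemaError(f"genes missing from length table: {missing[:10]}")
    if library_sizes is None:
        lib = m.counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(np.asarray(library_sizes, dtype=float), index=m.counts.columns)
    if (lib <= 0).any():
        raise UndefinedRatioError("library sizes must be positive")
    L = lengths.series.reindex(m.gene_ids).to_numpy()
    fpkm = m.counts.to_numpy(dtype=float) * 1e9 / (L[:, None] * lib.to_numpy()[None, :])
    return pd.DataFrame(fpkm, index=m.counts.index, columns=m.counts.columns)


@dataclass(frozen=True)
class QCRow:
    """One sample's read-mapping QC summary.

    Percentages follow alignment-report conventions: clean% is
    clean/raw, total-mapped% is mapped/clean, uniquely-mapped% is
    unique/mapped — each reported half-up to two decimals.
    """

    sample_id: str
    raw_reads: int
    clean_reads: int
    total_mapped: int
    uniquely_mapped: int
    clean_pct: float = field(init=False)
    total_mapped_pct: float = field(init=False)
    uniquely_mapped_pct: float = field(init=False)

    def __post_init__(self) -> None:
        counts = (self.raw_reads, self.clean_reads, self.total_mapped, self.uniquely_mapped)
        if any(c < 0 for c in counts):
            raise TableParseError(f"negative QC count for {self.sample_id}: {counts}")
        if not (self.uniquely_mapped <= self.total_mapped <= self.clean_reads <= self.raw_reads):
            raise SchemaError(
                f"QC counts out of order for {self.sample_id}: expected "
                "uniquely_mapped <= total_mapped <= clean_reads <= raw_reads"
            )
        for denom, num, name in (
            (self.raw_reads, self.clean_reads, "clean_pct"),
            (self.clean_reads, self.total_mapped, "total_mapped_pct"),
            (self.total_mapped, self.uniquely_mapped, "uniquely_mapped_pct"),
        ):
            if denom == 0:
                raise UndefinedRatioError(
                    f"cannot compute {name} for {self.sample_id}: zero denominator"
                )
            object.__setattr__(self, name, round_half_up(100.0 * num / denom))


def qc_summary(
    raw: int,
    clean: int,
    total_mapped: int,
    uniquely_mapped: int,
    sample_id: str = "sample",
) -> QCRow:
    """Compute the three cascade percentages for one sample's read counts."""
    return QCRow(sample_id, raw, clean, total_mapped, uniquely_mapped)


QC_COLUMNS = [
    "sample_id", "raw_reads", "clean_reads", "total_mapped", "uniquely_mapped",
    "clean_pct", "total_mapped_pct", "uniquely_mapped_pct",
]


def qc_table(rows: Iterable[QCRow]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in QC_COLUMNS} for r in rows])


def read_qc_counts(path: str | Path) -> list[QCRow]:
    """Read a QC TSV (sample_id + the four raw counts) and recompute percentages."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "raw_reads", "clean_reads", "total_mapped", "uniquely_mapped"}
    if not need <= set(df.columns):
        raise SchemaError(f"QC table needs columns {sorted(need)}")
    return [
        qc_summary(
            int(r.raw_reads), int(r.clean_reads), int(r.total_mapped),
            int(r.uniquely_mapped), str(r.sample_id),
        )
        for r in df.itertuples()
    ]
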