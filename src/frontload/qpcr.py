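"""qPCR relative quantification (2^-ddCt) and RNA-seq concordance.

Relative expression of a target gene is computed against a reference gene
(e.g. GAPDH) and normalized to a calibrator sample:
ddCt = (Ct_target - Ct_reference) - (Ct_target_cal - Ct_reference_cal),
relative expression = 2^-ddCt. Technical-replicate Ct values are averaged
before the arithmetic. Concordance between qPCR and RNA-seq log2
fold changes is the squared Pearson correlation.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, SchemaError

CT_COLUMNS = ["gene", "sample", "ct_target", "ct_reference", "is_calibrator"]


def ddct(ct_t: float, ct_r: float, ct_t_cal: float, ct_r_cal: float) -> float:
    """2^-ddCt relative expression versus the calibrator condition."""
    for v in (ct_t, ct_r, ct_t_cal, ct_r_cal):
        if not math.isfinite(v):
            raise DomainError("Ct values must be finite")
    ddct_val = (ct_t - ct_r) - (ct_t_cal - ct_r_cal)
    return 2.0 ** (-ddct_val)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"Ct table missing columns: {sorted(missing)}")
    df["is_calibrator"] = df["is_calibrator"].astype(bool)
    return df


def relative_expression(ct: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, sample) 2^-ddCt from a long-format Ct table.

    Replicate rows for the same (gene, sample) are averaged first. Exactly
    one calibrator sample is required per gene.
    """
    agg = (
        ct.groupby(["gene", "sample"])
        .agg(
            ct_target=("ct_target", "mean"),
            ct_reference=("ct_reference", "mean"),
            is_calibrator=("is_calibrator", "any"),
        )
        .reset_index()
    )
    rows = []
    for gene, sub in agg.groupby("gene"):
        cal = sub[sub["is_calibrator"]]
        if len(cal) != 1:
            raise SchemaError(
                f"gene {gene!r} needs exactly one calibrator sample, found {len(cal)}"
            )
        ct_t_cal = float(cal["ct_target"].iloc[0])
        ct_r_cal = float(cal["ct_reference"].iloc[0])
        for r in sub.itertuples():
            rows.append(
                {
                    "gene": gene,
                    "sample": r.sample,
                    "rel_expr": ddct(r.ct_target, r.ct_reference, ct_t_cal, ct_r_cal),
                    "log2_rel_expr": -((r.ct_target - r.ct_reference) - (ct_t_cal - ct_r_cal)),
                    "is_calibrator": r.is_calibrator,
                }
            )
    return pd.DataFrame(rows)


def concordance(x, y) -> float:
    """Squared Pearson correlation between two log2 fold-change series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("need two equal-length series of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("concordance undefined: a series has zero variance")
    r = stats.pearsonr(x, y).statistic
    return float(r**2)
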