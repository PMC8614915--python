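"""Hypergeometric over-representation analysis for arbitrary gene->term maps.

A generic stand-in for GO/KEGG enrichment: the caller supplies the
annotation (term -> gene set), the gene population, and a study set; each
term gets an upper-tail hypergeometric p-value. Raw p at the significance
cut is the primary flag; BH-adjusted p is emitted alongside, clearly
labeled.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .exceptions import DomainError, SchemaError


class TermMap:
    """term_id -> gene-id set, with optional human-readable labels."""

    def __init__(self, terms: Mapping[str, Iterable[str]], labels: Mapping[str, str] | None = None):
        self.terms: dict[str, frozenset[str]] = {}
        for term, genes in terms.items():
            gs = frozenset(genes)
            if not gs:
                raise SchemaError(f"term {term!r} has no genes")
            self.terms[term] = gs
        self.labels = dict(labels or {})

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermMap":
        """Read a (gene_id, term_id[, label]) TSV."""
        df = pd.read_csv(path, sep="\t")
        if not {"gene_id", "term_id"} <= set(df.columns):
            raise SchemaError("term map needs columns gene_id, term_id")
        terms: dict[str, set[str]] = {}
        labels: dict[str, str] = {}
        for row in df.itertuples():
            terms.setdefault(str(row.term_id), set()).add(str(row.gene_id))
            if "label" in df.columns and pd.notna(row.label):
                labels[str(row.term_id)] = str(row.label)
        return cls(terms, labels)


def hypergeom_enrich(
    study: Iterable[str],
    population: Iterable[str],
    terms: TermMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the study set.

    For a population of N genes, a term annotating K of them, and a study
    set of n genes hitting k, p = P(X >= k) with X ~ Hypergeom(N, K, n).
    Returns one row per term: term, label, k, K, n, N, p, padj (BH),
    enriched (raw p < alpha), study_hits.
    """
    study = set(study)
    population = set(population)
    outside = sorted(study - population)
    if outside:
        raise DomainError(f"study genes outside the population: {outside[:10]}")
    N, n = len(population), len(study)
    rows = []
    for term, genes in sorted(terms.terms.items()):
        term_pop = genes & population
        K = len(term_pop)
        hits = sorted(study & term_pop)
        k = len(hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "label": terms.labels.get(term, ""),
                "k": k, "K": K, "n": n, "N": N,
                "p": min(p, 1.0),
                "study_hits": ",".join(hits),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = bh_adjust(df["p"].to_numpy())
        df["enriched"] = df["p"] < alpha
    else:
        df["padj"] = []
        df["enriched"] = []
    cols = ["term", "label", "k", "K", "n", "N", "p", "padj", "enriched", "study_hits"]
    return df[cols]
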