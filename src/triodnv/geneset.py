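"""Gene-set evaluation statistics.

Fisher exact module-enrichment tests (two-sided, probability-mass
definition), pseudobulk spatial-cluster expression summaries and
Bonferroni screening of gene-based GWAS p-values.  The gene-based and
competitive gene-set regression statistics themselves are consumed as
precomputed inputs, not recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    @classmethod
    def disjoint_from(cls, name: str, genes: Iterable[str], background: "GeneSet"):
        """Construct a set enforcing disjointness from a background list."""
        genes = frozenset(genes)
        overlap = genes & background.genes
        if overlap:
            raise DataError(
                f"gene set {name!r} overlaps its background: {sorted(overlap)}"
            )
        return cls(name, genes)


class FisherResult(NamedTuple):
    odds_ratio: float
    p_two_sided: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool  # an empty margin forced p = 1


def fisher_enrichment(
    gene_set: GeneSet,
    background: GeneSet,
    module: Mapping[str, str],
    module_label: str,
) -> FisherResult:
    """Two-sided Fisher exact test for module membership of a gene set.

    Builds the 2x2 table (in-set x in-module) against the background and
    returns the exact conditional test, two-sided by the conventional
    probability-mass method (sum of table probabilities <= observed).
    """
    if gene_set.genes & background.genes:
        raise DataError("gene set and background must be disjoint")
    a = sum(1 for g in gene_set.genes if module.get(g) == module_label)
    b = len(gene_set.genes) - a
    c = sum(1 for g in background.genes if module.get(g) == module_label)
    d = len(background.genes) - c
    table = ((a, b), (c, d))
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        odds = np.inf if (a > 0 and d > 0) else (0.0 if (b > 0 or c > 0) else np.nan)
        return FisherResult(odds, 1.0, table, True)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(float(odds), float(p), table, False)


def pseudobulk_by_cluster(
    counts: pd.DataFrame,
    clusters: pd.Series,
    genes: Optional[Sequence[str]] = None,
    log_base: float = 2.0,
    offset: float = 1.0,
) -> pd.DataFrame:
    """Per-(gene, cluster) log mean of normalized spot counts.

    ``counts`` is spots x genes (normalized, >= 0); ``clusters`` maps each
    spot to its cluster label.  Counts are averaged across all spots of a
    cluster and then log-transformed (base 2 with a +1 offset by default).
    Clusters present in the label set but without any spot yield NaN.
    """
    if not counts.index.equals(clusters.index):
        clusters = clusters.reindex(counts.index)
        if clusters.isna().any():
            raise DataError("every spot needs a cluster label")
    sub = counts if genes is None else counts.loc[:, list(genes)]
    if (sub.to_numpy() < 0).any():
        raise DataError("normalized counts must be >= 0")
    means = sub.groupby(clusters, observed=True).mean()  # clusters x genes
    out = np.log(means + offset) / np.log(log_base)
    return out.T  # genes x clusters


class BonferroniThreshold(NamedTuple):
    exact: float
    rounded: float  # 2 significant digits, as conventionally reported


def bonferroni_threshold(alpha: float = 0.05, m: int = 24) -> BonferroniThreshold:
    """Family-wise threshold alpha / m, with its 2-significant-digit form."""
    if m < 1:
        raise ConfigurationError(f"number of tests must be >= 1, got {m}")
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0,1), got {alpha}")
    exact = alpha / m
    return BonferroniThreshold(exact, float(f"{exact:.1e}"))


def screen_gene_based(
    results: pd.DataFrame,
    threshold: float,
    p_columns: Sequence[str] = ("p_node", "p_edge"),
) -> pd.DataFrame:
    """Flag gene-based GWAS p-values below a significance threshold.

    Returns a copy of ``results`` with one boolean ``<col>_significant``
    column per p-value measure.  Deterministic; p-values must be in (0, 1].
    """
    out = results.copy()
    for col in p_columns:
        p = out[col].astype(float)
        if ((p <= 0) | (p > 1)).any():
            raise DataError(f"{col}: p-values must be in (0, 1]")
        out[f"{col}_significant"] = p < threshold
    return out
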