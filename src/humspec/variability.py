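"""Intra-human variability: non-synonymous variant counts per gene.

A gene's intra-human variability is the number of its missense, nonsense,
stop-lost and frameshift variant records in a dbSNP-like extract. Comparing
these counts across a gene cluster (and against each gene's fixed
human-lineage substitution count) distinguishes a locally elevated mutation
rate or relaxed constraint — which would inflate *within*-human variation —
from lineage-specific change concentrated in one gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IdMismatchError, UnknownClassError

CONSEQUENCE_CLASSES = frozenset(
    {"missense", "nonsense", "stop_lost", "frameshift", "synonymous", "intron", "other"}
)
#: classes counted as non-synonymous variable positions
NONSYNONYMOUS_CLASSES = frozenset({"missense", "nonsense", "stop_lost", "frameshift"})


def validate_classes(classes: Iterable[str]) -> None:
    unknown = set(classes) - CONSEQUENCE_CLASSES
    if unknown:
        raise UnknownClassError(f"unknown consequence classes: {sorted(unknown)}")


def count_variable_positions(
    records: pd.DataFrame, distinct_positions: bool = False
) -> int:
    """Number of non-synonymous variant records (for one gene).

    With ``distinct_positions`` (and a ``position`` column), multi-allelic
    records at one position count once; the default counts records, matching
    a plain sum of mutation entries.
    """
    if records.empty:
        return 0
    validate_classes(records["consequence_class"])
    hits = records[records["consequence_class"].isin(NONSYNONYMOUS_CLASSES)]
    if distinct_positions and "position" in hits.columns:
        return int(hits["position"].dropna().nunique())
    return int(len(hits))


def count_per_gene(
    table: pd.DataFrame, distinct_positions: bool = False
) -> dict[str, int]:
    """Per-gene variability counts from a (gene, consequence_class[, position]) table."""
    return {
        gene: count_variable_positions(sub, distinct_positions)
        for gene, sub in table.groupby("gene", sort=True)
    }


@dataclass(frozen=True)
class ClusterSummary:
    table: pd.DataFrame  # gene, variability, lineage_substitutions
    minimum: int
    maximum: int
    median: float
    focal_gene: str | None = None
    focal_exceeds_median: bool | None = None


def cluster_summary(
    per_gene_counts: Mapping[str, int],
    lineage_subs: Mapping[str, int],
    focal_gene: str | None = None,
) -> ClusterSummary:
    """Pair variability with lineage substitution counts across a gene cluster.

    The median over an even number of genes is the mean of the two middle
    values. ``focal_gene`` flags whether that gene's variability exceeds the
    cluster median.
    """
    if set(per_gene_counts) != set(lineage_subs):
        raise IdMismatchError(
            "variability and lineage-substitution tables cover different genes"
        )
    genes = sorted(per_gene_counts)
    counts = np.array([per_gene_counts[g] for g in genes])
    df = pd.DataFrame(
        {
            "gene": genes,
            "variability": counts,
            "lineage_substitutions": [lineage_subs[g] for g in genes],
        }
    )
    med = float(np.median(counts))
    exceeds = None
    if focal_gene is not None:
        if focal_gene not in per_gene_counts:
            raise IdMismatchError(f"focal gene {focal_gene!r} not in tables")
        exceeds = per_gene_counts[focal_gene] > med
    return ClusterSummary(
        df, int(counts.min()), int(counts.max()), med, focal_gene, exceeds
    )


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_classes(df["consequence_class"])
    return df


def write_summary(summary: ClusterSummary, path: str | Path) -> Path:
    path = Path(path)
    summary.table.to_csv(path, sep="\t", index=False)
    return path
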