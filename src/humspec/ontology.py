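"""Gene Ontology term-string filtering for brain cell-surface proteins.

The protein universe is restricted by literal GO term *names* (no graph
traversal): a protein passes when it is annotated as an integral or anchored
component of the plasma membrane AND carries at least one neural term — a
term beginning with "nervous", "neuron", "dendr", "axon" or "synap" that is
not a known false friend (enteric/autonomous nervous system, synaptonemal
complex, axoneme, dendritic cells). Because surface annotation is patchy,
protein families — proteins whose UniProt-style accession codes share the
same first three characters — are pulled in whole whenever one member
passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DuplicateIdError, UnknownIdError

MEMBRANE_TERMS = (
    "integral component of plasma membrane",
    "anchored component of external side of plasma membrane",
)
NEURAL_PREFIXES = ("nervous", "neuron", "dendr", "axon", "synap")
NEURAL_EXCLUSIONS = ("enteric", "autonomous", "synaptonem", "axonem", "dendritic cell")

FAMILY_PREFIX_LEN = 3


@dataclass(frozen=True)
class AnnotationRecord:
    protein_id: str
    accession: str
    terms: frozenset[str]

    def __post_init__(self):
        if len(self.accession) < FAMILY_PREFIX_LEN:
            raise ValueError(
                f"{self.protein_id}: accession {self.accession!r} shorter than "
                f"{FAMILY_PREFIX_LEN} characters"
            )

    @property
    def family(self) -> str:
        return self.accession[:FAMILY_PREFIX_LEN]


def _is_neural(term: str) -> bool:
    # exclusion substrings override inclusion prefixes, anywhere in the term
    return term.startswith(NEURAL_PREFIXES) and not any(
        x in term for x in NEURAL_EXCLUSIONS
    )


def passes_surface_filter(terms: Iterable[str], ignore_case: bool = False) -> bool:
    """True iff the term set has a plasma-membrane term and a neural term.

    Matching is case-sensitive by default (the annotation source uses
    lowercase names); ``ignore_case`` lowercases terms first. Membrane terms
    are matched exactly; neural terms by anchored prefix with substring
    exclusions.
    """
    termset = {t.lower() for t in terms} if ignore_case else set(terms)
    if not any(m in termset for m in MEMBRANE_TERMS):
        return False
    return any(_is_neural(t) for t in termset)


def expand_families(
    passing: Iterable[str], records: Iterable[AnnotationRecord]
) -> set[str]:
    """Add every protein whose accession shares a passing member's 3-char prefix."""
    records = list(records)
    by_id = {r.protein_id: r for r in records}
    passing = set(passing)
    unknown = passing - by_id.keys()
    if unknown:
        raise UnknownIdError(f"passing ids absent from records: {sorted(unknown)}")
    families = {by_id[p].family for p in passing}
    return {r.protein_id for r in records if r.family in families} | passing


@dataclass(frozen=True)
class FilterSummary:
    selected: frozenset[str]
    n_selected: int
    n_with_substitution: int


def apply_filter(
    records: Iterable[AnnotationRecord],
    substitutions_per_protein: Mapping[str, int] | None = None,
    ignore_case: bool = False,
) -> FilterSummary:
    """Run the surface filter, expand families, count substitution carriers."""
    records = list(records)
    passing = {
        r.protein_id for r in records if passes_surface_filter(r.terms, ignore_case)
    }
    selected = expand_families(passing, records) if passing else set()
    subs = substitutions_per_protein or {}
    n_with = sum(1 for p in selected if subs.get(p, 0) >= 1)
    return FilterSummary(frozenset(selected), len(selected), n_with)


TERM_SEP = "|"


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> Path:
    """TSV out: protein id, accession, pipe-joined sorted term names."""
    path = Path(path)
    rows = [
        {
            "protein": r.protein_id,
            "accession": r.accession,
            "terms": TERM_SEP.join(sorted(r.terms)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["protein", "accession", "terms"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.protein in seen:
            raise DuplicateIdError(f"duplicate protein id {row.protein!r}")
        seen.add(row.protein)
        terms = frozenset(t for t in str(row.terms).split(TERM_SEP) if t)
        records.append(AnnotationRecord(row.protein, row.accession, terms))
    return records
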