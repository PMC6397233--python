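"""Flat-file clinical variant knowledge base and disease-direction queries.

The knowledge base mirrors a subset of the ClinVar ``variant_summary``
columns (variant_id, gene, condition, clinical_significance, review_status)
so that real exports can be dropped in after column selection.  A disease
query resolves to the seed genes and variants whose known condition matches
the requested disease direction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

__all__ = ["ClinicalRecord", "DiseaseQuery", "QueryResult", "load_kb", "write_kb", "query_kb"]

_REQUIRED_COLUMNS = ("variant_id", "gene", "condition", "clinical_significance")


@dataclass(frozen=True)
class ClinicalRecord:
    variant_id: str
    gene: str
    condition: str
    clinical_significance: str
    review_status: str | None = None

    def __post_init__(self) -> None:
        for name in ("variant_id", "gene", "condition"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        object.__setattr__(self, "gene", self.gene.upper())


@dataclass(frozen=True)
class DiseaseQuery:
    """Disease direction: keywords plus optional include/exclude terms.

    A record matches iff any keyword or include term occurs (case-insensitive
    substring) in its condition and no exclude term does.
    """

    keywords: tuple[str, ...]
    include_terms: tuple[str, ...] = ()
    exclude_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "keywords", tuple(self.keywords))
        object.__setattr__(self, "include_terms", tuple(self.include_terms))
        object.__setattr__(self, "exclude_terms", tuple(self.exclude_terms))
        if not self.keywords:
            raise ValueError("at least one keyword required")
        for term in (*self.keywords, *self.include_terms, *self.exclude_terms):
            if not term:
                raise ValueError("query terms must be non-empty strings")

    def matches(self, condition: str) -> bool:
        cond = condition.lower()
        if any(t.lower() in cond for t in self.exclude_terms):
            return False
        return any(t.lower() in cond for t in (*self.keywords, *self.include_terms))


@dataclass
class QueryResult:
    genes: set[str] = field(default_factory=set)
    variants: set[str] = field(default_factory=set)
    records: list[ClinicalRecord] = field(default_factory=list)


def load_kb(path) -> list[ClinicalRecord]:
    """Load a knowledge-base TSV; duplicate variant rows are retained since
    one variant may map to several conditions."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        records: list[ClinicalRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    ClinicalRecord(
                        variant_id=row["variant_id"],
                        gene=row["gene"],
                        condition=row["condition"],
                        clinical_significance=row["clinical_significance"],
                        review_status=row.get("review_status") or None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_kb(records: list[ClinicalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([*_REQUIRED_COLUMNS, "review_status"])
        for r in records:
            writer.writerow(
                [r.variant_id, r.gene, r.condition, r.clinical_significance, r.review_status or ""]
            )


def query_kb(kb: list[ClinicalRecord], q: DiseaseQuery) -> QueryResult:
    """Resolve a disease direction into seed genes/variants (empty is valid)."""
    if not kb:
        raise ValueError("knowledge base is empty")
    result = QueryResult()
    for rec in kb:
        if q.matches(rec.condition):
            result.records.append(rec)
            result.genes.add(rec.gene)
            result.variants.add(rec.variant_id)
    return result
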