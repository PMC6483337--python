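"""Two-dimensional case matching: genomic proximity refined by phenotype.

Candidate variant pairs between a query case and every other watch-list case
are first binned into four proximity categories — identical variant, same
genomic position, same codon, same gene — and ranked category-first.  Within
a category, candidates are ordered by decreasing case-level phenotype
similarity (path-Jaccard best-match average over the two HPO profiles), so a
genetically close hit always outranks a phenotypically close but genetically
distant one.  The ranked list is pruned to a configurable number of top hits
(default 5).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .annotation import AnnotatedVariant
from .ontology import PathCache, case_similarity
from .variants import Variant

__all__ = [
    "ProximityCategory",
    "MatchRecord",
    "MatchReport",
    "proximity_category",
    "rank_matches",
    "match_case",
    "build_match_reports",
    "report_to_tsv",
    "report_to_json",
]

DEFAULT_TOP_N = 5


class ProximityCategory(enum.IntEnum):
    """Four-level genomic match hierarchy; lower rank = stronger match."""

    IDENTICAL = 1
    SAME_POSITION = 2
    SAME_CODON = 3
    SAME_GENE = 4


def proximity_category(
    a: AnnotatedVariant, b: AnnotatedVariant
) -> ProximityCategory | None:
    """Classify the genomic proximity of two annotated variants.

    Both variants must be normalized and on the same assembly.  Two variants
    share a codon when at least one transcript hit by both assigns them the
    same codon ordinal; they share a gene when their gene sets intersect.
    Returns None when the variants are not comparable at any level.
    """
    va, vb = a.variant, b.variant
    if va.assembly != vb.assembly:
        raise ValueError(
            f"cannot compare variants on different assemblies "
            f"({va.assembly} vs {vb.assembly})"
        )
    if (va.chrom, va.pos, va.ref, va.alt) == (vb.chrom, vb.pos, vb.ref, vb.alt):
        return ProximityCategory.IDENTICAL
    if (va.chrom, va.pos) == (vb.chrom, vb.pos):
        return ProximityCategory.SAME_POSITION
    codons_a = {
        h.transcript_id: h.codon_index
        for h in a.transcript_hits
        if h.codon_index is not None
    }
    for h in b.transcript_hits:
        if h.codon_index is not None and codons_a.get(h.transcript_id) == h.codon_index:
            return ProximityCategory.SAME_CODON
    if a.gene_ids & b.gene_ids:
        return ProximityCategory.SAME_GENE
    return None


@dataclass(frozen=True)
class MatchRecord:
    query_case_id: str
    query_variant: Variant
    hit_case_id: str
    hit_variant: Variant
    category: ProximityCategory
    phenotype_similarity: float
    hit_owner: str = ""
    same_owner: bool = False
    hit_submitted_at: str = ""
    created_at: str = ""

    def swapped(self) -> "MatchRecord":
        """The same match seen from the hit case's perspective."""
        return replace(
            self,
            query_case_id=self.hit_case_id,
            query_variant=self.hit_variant,
            hit_case_id=self.query_case_id,
            hit_variant=self.query_variant,
        )


def rank_matches(candidates: Iterable[MatchRecord]) -> list[MatchRecord]:
    """Deterministic global ordering of match candidates.

    Category rank dominates; within a category higher phenotype similarity
    wins; remaining ties break on hit-case submission time, then hit case id.
    """
    return sorted(
        candidates,
        key=lambda m: (
            int(m.category),
            -m.phenotype_similarity,
            m.hit_submitted_at,
            m.hit_case_id,
        ),
    )


def match_case(
    query,
    others: Sequence,
    cache: PathCache,
    top_n: int = DEFAULT_TOP_N,
    created_at: str = "",
) -> list[MatchRecord]:
    """Match one processed case against the rest of the watch list.

    ``query`` and each element of ``others`` are case records exposing
    ``case_id``, ``owner``, ``variants`` (annotated), ``profile`` and
    ``submitted_at``.  Only filter-passing variants on both sides form
    candidates; retracted or failed cases must already be excluded by the
    caller.  At most one record is kept per (query variant, hit case) — the
    lowest category rank, ties resolved toward higher similarity — and the
    globally ranked list is truncated to ``top_n``.
    """
    candidates: dict[tuple[object, str], MatchRecord] = {}
    query_vars = [av for av in query.variants if av.passed_filters]
    for other in others:
        if other.case_id == query.case_id:
            continue
        other_vars = [av for av in other.variants if av.passed_filters]
        if not other_vars:
            continue
        similarity: float | None = None
        for q in query_vars:
            for h in other_vars:
                category = proximity_category(q, h)
                if category is None:
                    continue
                if similarity is None:
                    similarity = case_similarity(cache, query.profile, other.profile)
                record = MatchRecord(
                    query_case_id=query.case_id,
                    query_variant=q.variant,
                    hit_case_id=other.case_id,
                    hit_variant=h.variant,
                    category=category,
                    phenotype_similarity=similarity,
                    hit_owner=other.owner,
                    same_owner=other.owner == query.owner,
                    hit_submitted_at=other.submitted_at,
                    created_at=created_at,
                )
                key = (q.variant.key, other.case_id)
                best = candidates.get(key)
                if best is None or int(category) < int(best.category):
                    candidates[key] = record
    ranked = rank_matches(candidates.values())
    return ranked[: max(0, top_n)]


@dataclass
class MatchReport:
    """One party's view of a matching event (give-and-take reporting)."""

    recipient_user: str
    case_id: str
    matches: list[MatchRecord] = field(default_factory=list)
    generated_at: str = ""


def build_match_reports(
    new_case,
    matches: Sequence[MatchRecord],
    generated_at: str = "",
    suppress_empty: bool = False,
) -> list[MatchReport]:
    """Fan a ranked match list out to every involved party.

    The submitter of the new case receives all matches; each distinct owner
    of a hit case receives the records involving their cases, with roles
    swapped so their case appears as the query.  An empty match list still
    yields one (empty) report to the submitter unless suppressed.
    """
    reports: list[MatchReport] = []
    if matches or not suppress_empty:
        reports.append(
            MatchReport(
                recipient_user=new_case.owner,
                case_id=new_case.case_id,
                matches=list(matches),
                generated_at=generated_at,
            )
        )
    by_owner: dict[str, list[MatchRecord]] = {}
    for m in matches:
        by_owner.setdefault(m.hit_owner, []).append(m)
    for owner in sorted(by_owner):
        swapped = rank_matches(m.swapped() for m in by_owner[owner])
        # Group the owner's records under their first involved case id.
        reports.append(
            MatchReport(
                recipient_user=owner,
                case_id=swapped[0].query_case_id,
                matches=swapped,
                generated_at=generated_at,
            )
        )
    return reports


_TSV_HEADER = (
    "rank\tcategory\tsimilarity\tquery_variant\thit_variant\t"
    "hit_case\towner\tsame_owner"
)


def report_to_tsv(report: MatchReport) -> str:
    lines = [_TSV_HEADER]
    for rank, m in enumerate(report.matches, start=1):
        lines.append(
            "\t".join(
                [
                    str(rank),
                    m.category.name,
                    f"{m.phenotype_similarity:.6f}",
                    str(m.query_variant),
                    str(m.hit_variant),
                    m.hit_case_id,
                    m.hit_owner,
                    "yes" if m.same_owner else "no",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _variant_dict(v: Variant) -> dict:
    return {
        "assembly": v.assembly,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
    }


def report_to_json(report: MatchReport) -> str:
    payload = {
        "recipient_user": report.recipient_user,
        "case_id": report.case_id,
        "generated_at": report.generated_at,
        "matches": [
            {
                "rank": rank,
                "category": m.category.name,
                "phenotype_similarity": round(m.phenotype_similarity, 6),
                "query_case_id": m.query_case_id,
                "query_variant": _variant_dict(m.query_variant),
                "hit_case_id": m.hit_case_id,
                "hit_variant": _variant_dict(m.hit_variant),
                "hit_owner": m.hit_owner,
                "same_owner": m.same_owner,
            }
            for rank, m in enumerate(report.matches, start=1)
        ],
    }
    return json.dumps(payload, sort_keys=True)
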