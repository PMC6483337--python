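"""The case watch list: persistence and the end-to-end submission pipeline.

Every submission runs through the same deterministic stage sequence:
validate -> extract -> assembly-convert -> left-normalize -> annotate ->
beacon-check -> filter -> match.  Stage failures never abort a submission as
a whole (only validation can); per-variant problems are recorded in a
processing trace for submitter follow-up.  Matching is triggered by each new
submission against all previously processed, non-retracted cases, and match
reports are produced for both parties ("give and take"): the watch list is
never queried directly, it grows with every use.

Persistence is a single JSON-lines file (one case per line, deterministic
key order), suitable for a single-operator deployment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from .annotation import (
    AnnotatedVariant,
    FilterConfig,
    GeneModelSet,
    TranscriptHit,
    annotate_variant,
    apply_filters,
)
from .matching import (
    DEFAULT_TOP_N,
    MatchRecord,
    MatchReport,
    build_match_reports,
    match_case,
)
from .ontology import Ontology, PathCache, PhenotypeProfile
from .variants import (
    ReferenceGenome,
    ValidationResult,
    Variant,
    VariantError,
    convert_assembly,
    left_normalize,
    parse_generic_record,
    parse_hgvs_g,
    read_vcf,
    validate_submission,
)

__all__ = [
    "SystemClock",
    "LogicalClock",
    "TraceEntry",
    "CaseRecord",
    "KnownVariantStore",
    "MafTable",
    "WatchList",
    "WatchListError",
    "UnknownCaseError",
    "AlreadyRetractedError",
    "beacon_check",
]


class WatchListError(Exception):
    pass


class UnknownCaseError(WatchListError, KeyError):
    pass


class AlreadyRetractedError(WatchListError):
    pass


class SystemClock:
    """Wall-clock timestamps (UTC, second resolution)."""

    def now(self) -> str:
        return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


class LogicalClock:
    """Deterministic event clock: a fixed epoch advanced by one second per
    tick.  Used wherever byte-identical replays matter (tests, exports)."""

    def __init__(self, start: str = "2000-01-01T00:00:00Z"):
        self._t = datetime.strptime(start, "%Y-%m-%dT%H:%M:%SZ").replace(
            tzinfo=timezone.utc
        )

    def now(self) -> str:
        stamp = self._t.strftime("%Y-%m-%dT%H:%M:%SZ")
        self._t += timedelta(seconds=1)
        return stamp


@dataclass
class TraceEntry:
    stage: str
    record: str
    reason: str
    at: str = ""

    def to_dict(self) -> dict:
        return {"stage": self.stage, "record": self.record,
                "reason": self.reason, "at": self.at}


VALID_STATUS = ("RECEIVED", "PROCESSED", "FAILED", "RETRACTED")


@dataclass
class CaseRecord:
    """One submitted case: in-limbo variants plus an HPO phenotype profile."""

    case_id: str
    owner: str
    variants: list[AnnotatedVariant] = field(default_factory=list)
    profile: PhenotypeProfile | None = None
    mode_of_inheritance: str | None = None
    age_of_onset: str | None = None
    assembly_submitted: str = ""
    status: str = "RECEIVED"
    trace: list[TraceEntry] = field(default_factory=list)
    submitted_at: str = ""

    @property
    def matchable_variants(self) -> list[AnnotatedVariant]:
        return [av for av in self.variants if av.passed_filters]

    def add_trace(self, stage: str, record: str, reason: str, at: str) -> None:
        self.trace.append(TraceEntry(stage, record, reason, at))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "owner": self.owner,
            "assembly_submitted": self.assembly_submitted,
            "status": self.status,
            "submitted_at": self.submitted_at,
            "mode_of_inheritance": self.mode_of_inheritance,
            "age_of_onset": self.age_of_onset,
            "profile": sorted(self.profile.term_ids) if self.profile else [],
            "variants": [_annotated_to_dict(av) for av in self.variants],
            "trace": [t.to_dict() for t in self.trace],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CaseRecord":
        return cls(
            case_id=d["case_id"],
            owner=d["owner"],
            variants=[_annotated_from_dict(x) for x in d.get("variants", [])],
            profile=PhenotypeProfile(frozenset(d["profile"])) if d.get("profile") else None,
            mode_of_inheritance=d.get("mode_of_inheritance"),
            age_of_onset=d.get("age_of_onset"),
            assembly_submitted=d.get("assembly_submitted", ""),
            status=d.get("status", "RECEIVED"),
            trace=[TraceEntry(**t) for t in d.get("trace", [])],
            submitted_at=d.get("submitted_at", ""),
        )


def _annotated_to_dict(av: AnnotatedVariant) -> dict:
    v = av.variant
    return {
        "variant": {"assembly": v.assembly, "chrom": v.chrom, "pos": v.pos,
                    "ref": v.ref, "alt": v.alt},
        "gene_ids": sorted(av.gene_ids),
        "transcript_hits": [
            {
                "transcript_id": h.transcript_id,
                "gene_id": h.gene_id,
                "region": h.region,
                "consequence": h.consequence,
                "impact": h.impact,
                "codon_index": h.codon_index,
                "canonical": h.canonical,
                "biotype": h.biotype,
            }
            for h in av.transcript_hits
        ],
        "maf": av.maf,
        "passed_filters": av.passed_filters,
        "beacon_hit": av.beacon_hit,
        "filter_reasons": list(av.filter_reasons),
    }


def _annotated_from_dict(d: Mapping) -> AnnotatedVariant:
    return AnnotatedVariant(
        variant=Variant(**d["variant"]),
        gene_ids=frozenset(d.get("gene_ids", [])),
        transcript_hits=[TranscriptHit(**h) for h in d.get("transcript_hits", [])],
        maf=d.get("maf"),
        passed_filters=d.get("passed_filters", False),
        beacon_hit=d.get("beacon_hit", False),
        filter_reasons=list(d.get("filter_reasons", [])),
    )


class KnownVariantStore:
    """Local stand-in for a beacon network: exact normalized-allele lookup.

    Entries are normalized with the same left-normalizer as submissions, so
    a non-minimal representation in the source VCF still hits.
    """

    def __init__(self, source_label: str = "local"):
        self.entries: set[tuple[str, str, int, str, str]] = set()
        self.source_label = source_label

    def add(self, v: Variant) -> None:
        self.entries.add(v.key)

    @classmethod
    def from_vcf(
        cls,
        path: str | Path,
        assembly: str,
        ref_genome: ReferenceGenome,
        source_label: str = "local",
    ) -> "KnownVariantStore":
        store = cls(source_label=source_label)
        result = read_vcf(path, assembly)
        for v in result.variants:
            store.add(left_normalize(v, ref_genome))
        return store

    def __contains__(self, v: Variant) -> bool:
        return v.key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def beacon_check(v: Variant, store: KnownVariantStore | None) -> bool:
    """Yes/no presence of a normalized allele in the known-variant store."""
    return store is not None and v in store


class MafTable:
    """Population allele frequencies keyed by normalized variant tuple,
    loaded from a VCF whose INFO field carries ``AF``."""

    def __init__(self):
        self.frequencies: dict[tuple[str, str, int, str, str], float] = {}

    @classmethod
    def from_vcf(
        cls, path: str | Path, assembly: str, ref_genome: ReferenceGenome
    ) -> "MafTable":
        table = cls()
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                afs = rec.info.get("AF")
                if afs is None:
                    continue
                if not isinstance(afs, tuple):
                    afs = (afs,)
                for alt, af in zip(rec.alts or (), afs):
                    try:
                        v = left_normalize(
                            Variant(assembly, rec.chrom, rec.pos, rec.ref, alt),
                            ref_genome,
                        )
                    except (VariantError, ValueError):
                        continue
                    table.frequencies[v.key] = float(af)
        return table

    def lookup(self, v: Variant) -> float | None:
        return self.frequencies.get(v.key)


class WatchList:
    """The persistent case store plus the full submission pipeline."""

    def __init__(
        self,
        ontology: Ontology,
        path_cache: PathCache,
        ref_genome: ReferenceGenome,
        gene_models: GeneModelSet,
        known_store: KnownVariantStore | None = None,
        maf_table: MafTable | None = None,
        filter_config: FilterConfig | None = None,
        top_n: int = DEFAULT_TOP_N,
        accepted_assemblies: Sequence[str] | None = None,
        assembly_maps: Mapping[str, object] | None = None,
        clock=None,
        store_path: str | Path | None = None,
    ):
        self.ontology = ontology
        self.path_cache = path_cache
        self.ref_genome = ref_genome
        self.gene_models = gene_models
        self.known_store = known_store
        self.maf_table = maf_table
        self.filter_config = filter_config or FilterConfig()
        self.top_n = top_n
        self.target_assembly = ref_genome.assembly
        self.accepted_assemblies = tuple(
            accepted_assemblies or (self.target_assembly,)
        )
        #: source assembly label -> coordinate-mapping provider
        self.assembly_maps = dict(assembly_maps or {})
        self.clock = clock or SystemClock()
        self.store_path = Path(store_path) if store_path else None
        self.cases: dict[str, CaseRecord] = {}
        self._match_counts: dict[str, dict[str, int]] = {}
        self._counter = 0
        if self.store_path and self.store_path.exists():
            self._load()

    # -- persistence --------------------------------------------------------

    def _load(self) -> None:
        for line in self.store_path.read_text().splitlines():
            if not line.strip():
                continue
            payload = json.loads(line)
            case = CaseRecord.from_dict(payload["case"])
            self.cases[case.case_id] = case
            self._match_counts[case.case_id] = payload.get("match_counts", {})
        self._counter = len(self.cases)

    def save(self) -> None:
        if self.store_path:
            self.export_jsonl(self.store_path)

    def export_jsonl(self, path: str | Path) -> None:
        """One case per line, in submission order, deterministic key order."""
        lines = [
            json.dumps(
                {"case": case.to_dict(),
                 "match_counts": self._match_counts.get(case.case_id, {})},
                sort_keys=True,
            )
            for case in self.cases.values()
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def _new_case_id(self) -> str:
        # Zero-padded sequential ids: sortable, unique, replay-stable.
        self._counter += 1
        return f"CW{self._counter:06d}"

    # -- pipeline stages ----------------------------------------------------

    def _extract(self, raw: Mapping, validation: ValidationResult,
                 case: CaseRecord) -> list[Variant]:
        variants: list[Variant] = []
        assembly = raw.get("assembly", "")
        for kind, payload in validation.accepted:
            try:
                if kind == "generic":
                    variants.append(parse_generic_record(payload, assembly))
                elif kind == "hgvs":
                    if assembly != self.target_assembly:
                        raise VariantError(
                            "HGVS coordinates must be given on "
                            f"{self.target_assembly}"
                        )
                    variants.append(parse_hgvs_g(payload, self.ref_genome))
                elif kind == "vcf":
                    result = read_vcf(payload, assembly)
                    variants.extend(result.variants)
                    for rec, reason in result.rejected:
                        case.add_trace("extract", rec, reason, self.clock.now())
            except VariantError as exc:
                case.add_trace("extract", str(payload), str(exc), self.clock.now())
        return variants

    def _convert(self, variants: list[Variant], case: CaseRecord) -> list[Variant]:
        converted: list[Variant] = []
        for v in variants:
            if v.assembly == self.target_assembly:
                converted.append(v)
                continue
            mapping = self.assembly_maps.get(v.assembly)
            if mapping is None:
                case.add_trace(
                    "convert", str(v),
                    f"no conversion provider for assembly {v.assembly!r}",
                    self.clock.now(),
                )
                continue
            try:
                converted.append(convert_assembly(v, mapping, self.ref_genome))
            except VariantError as exc:
                case.add_trace("convert", str(v), str(exc), self.clock.now())
        return converted

    def _normalize(self, variants: list[Variant], case: CaseRecord) -> list[Variant]:
        normalized: list[Variant] = []
        for v in variants:
            try:
                normalized.append(left_normalize(v, self.ref_genome))
            except (VariantError, ValueError) as exc:
                case.add_trace("normalize", str(v), str(exc), self.clock.now())
        return normalized

    def _annotate_and_filter(
        self, variants: list[Variant], case: CaseRecord
    ) -> list[AnnotatedVariant]:
        annotated: list[AnnotatedVariant] = []
        seen: set[tuple] = set()
        for v in variants:
            if v.key in seen:
                case.add_trace("annotate", str(v), "duplicate variant in submission",
                               self.clock.now())
                continue
            seen.add(v.key)
            av = annotate_variant(v, self.gene_models, self.ref_genome)
            if self.maf_table is not None:
                av.maf = self.maf_table.lookup(v)
            if beacon_check(v, self.known_store):
                av.beacon_hit = True
                case.add_trace(
                    "beacon", str(v),
                    f"already publicized in {self.known_store.source_label}",
                    self.clock.now(),
                )
            av = apply_filters(av, self.filter_config)
            if not av.passed_filters:
                case.add_trace(
                    "filter", str(v),
                    "excluded from matching: " + "; ".join(av.filter_reasons),
                    self.clock.now(),
                )
            annotated.append(av)
        return annotated

    # -- public operations --------------------------------------------------

    def submit_case(
        self, raw: Mapping
    ) -> tuple[CaseRecord, list[MatchReport]]:
        """Run the full pipeline on one submission document.

        Returns the persisted case record and the give-and-take match
        reports.  The case joins the watch list (status PROCESSED) whenever
        at least one variant survives validation/extraction, even if none is
        matchable; it is stored as FAILED when validation rejects the
        submission outright.
        """
        now = self.clock.now()
        case = CaseRecord(
            case_id=self._new_case_id(),
            owner=str(raw.get("owner", "")),
            assembly_submitted=str(raw.get("assembly", "")),
            mode_of_inheritance=raw.get("mode_of_inheritance"),
            age_of_onset=raw.get("age_of_onset"),
            submitted_at=now,
        )
        validation = validate_submission(raw, self.ontology, self.accepted_assemblies)
        for record, reason in validation.rejected:
            case.add_trace("validate", str(record), reason, self.clock.now())
        for term, issue in validation.term_issues:
            case.add_trace("validate", term, issue, self.clock.now())
        if not validation.assembly_ok:
            case.add_trace(
                "validate", str(raw.get("assembly")),
                "missing or unsupported assembly "
                f"(accepted: {', '.join(self.accepted_assemblies)})",
                self.clock.now(),
            )
        if not validation.profile_ok:
            case.add_trace("validate", "hpo_terms", "missing phenotype: at least "
                           "one resolvable HPO term is required", self.clock.now())
        if not validation.accepted:
            case.add_trace("validate", "variants", "no valid variant source",
                           self.clock.now())
        if not validation.ok:
            case.status = "FAILED"
            self.cases[case.case_id] = case
            self.save()
            return case, []

        case.profile = PhenotypeProfile(frozenset(validation.resolved_terms))
        variants = self._extract(raw, validation, case)
        variants = self._convert(variants, case)
        variants = self._normalize(variants, case)
        case.variants = self._annotate_and_filter(variants, case)

        if not case.variants:
            case.status = "FAILED"
            case.add_trace("pipeline", "variants",
                           "no variant survived processing", self.clock.now())
            self.cases[case.case_id] = case
            self.save()
            return case, []

        case.status = "PROCESSED"
        if not case.matchable_variants:
            case.add_trace("filter", "variants",
                           "no matchable variants", self.clock.now())

        matches = self._run_matching(case)
        self.cases[case.case_id] = case
        self._record_match_counts(case, matches)
        reports = build_match_reports(case, matches, generated_at=self.clock.now())
        self.save()
        return case, reports

    def _active_cases(self, exclude: str | None = None) -> list[CaseRecord]:
        return [
            c
            for c in self.cases.values()
            if c.status == "PROCESSED" and c.case_id != exclude
        ]

    def _run_matching(self, case: CaseRecord) -> list[MatchRecord]:
        if case.profile is None or not case.matchable_variants:
            return []
        return match_case(
            case,
            self._active_cases(exclude=case.case_id),
            self.path_cache,
            top_n=self.top_n,
            created_at=self.clock.now(),
        )

    def _record_match_counts(
        self, case: CaseRecord, matches: Sequence[MatchRecord]
    ) -> None:
        self._match_counts.setdefault(case.case_id, {})
        for m in matches:
            mine = self._match_counts.setdefault(m.query_case_id, {})
            mine[str(m.query_variant)] = mine.get(str(m.query_variant), 0) + 1
            theirs = self._match_counts.setdefault(m.hit_case_id, {})
            theirs[str(m.hit_variant)] = theirs.get(str(m.hit_variant), 0) + 1

    def rescan(self, case_id: str) -> list[MatchReport]:
        """Re-run matching for an existing case (after config or ontology
        changes); does not touch stored match counts of other cases."""
        case = self._get(case_id)
        matches = self._run_matching(case)
        return build_match_reports(case, matches, generated_at=self.clock.now())

    def _get(self, case_id: str) -> CaseRecord:
        try:
            return self.cases[case_id]
        except KeyError:
            raise UnknownCaseError(case_id) from None

    def retract_case(self, case_id: str) -> CaseRecord:
        """Withdraw a case from all future matching; past reports stand."""
        case = self._get(case_id)
        if case.status == "RETRACTED":
            raise AlreadyRetractedError(case_id)
        case.status = "RETRACTED"
        case.add_trace("retract", case_id, "retracted by owner", self.clock.now())
        self.save()
        return case

    def case_status(self, case_id: str) -> dict:
        """Status summary: per-variant filter/beacon flags, match counts, trace."""
        case = self._get(case_id)
        counts = self._match_counts.get(case_id, {})
        return {
            "case_id": case.case_id,
            "owner": case.owner,
            "status": case.status,
            "submitted_at": case.submitted_at,
            "profile": sorted(case.profile.term_ids) if case.profile else [],
            "variants": [
                {
                    "variant": str(av.variant),
                    "passed_filters": av.passed_filters,
                    "beacon_hit": av.beacon_hit,
                    "max_impact": av.max_impact,
                    "genes": sorted(av.gene_ids),
                    "match_count": counts.get(str(av.variant), 0),
                }
                for av in case.variants
            ],
            "trace": [t.to_dict() for t in case.trace],
        }

    def export_variants_vcf(self, path: str | Path) -> None:
        from .variants import write_vcf

        variants = [
            av.variant
            for case in self.cases.values()
            if case.status == "PROCESSED"
            for av in case.variants
        ]
        write_vcf(variants, path, assembly=self.target_assembly)
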