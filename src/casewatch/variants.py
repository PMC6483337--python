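"""Variant ingestion and normalization.

Variants are held in a VCF-like minimal representation: assembly label,
chromosome, 1-based position of the first reference base, and non-empty
uppercase ref/alt alleles.  Indels always carry a left anchor base.  All
coordinates in this package are 1-based inclusive.

Ingestion paths: VCF site records (via pysam), genomic-level (``g.``) HGVS
descriptions, and generic ``{assembly, chrom, pos, ref, alt}`` records.
Every ingested variant is left-normalized against the reference before it is
stored or compared, so that equivalent descriptions of the same indel in a
repeat tract collapse to one canonical (left-most, minimal) form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Callable, Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "Variant",
    "ReferenceGenome",
    "ValidationResult",
    "VcfReadResult",
    "VariantError",
    "ReferenceMismatchError",
    "BoundaryError",
    "HgvsError",
    "UnsupportedHgvsLevelError",
    "UnmappableVariantError",
    "UnsupportedConversionError",
    "IdentityAssemblyMap",
    "OffsetIntervalMap",
    "canonical_chrom",
    "read_vcf",
    "write_vcf",
    "parse_hgvs_g",
    "apply_variant",
    "left_normalize",
    "convert_assembly",
    "parse_generic_record",
    "validate_submission",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class VariantError(Exception):
    """Base class for variant-level failures (recorded per variant, not fatal)."""


class ReferenceMismatchError(VariantError):
    """Declared ref allele disagrees with the reference genome."""


class BoundaryError(VariantError):
    """An operation walked outside the contig bounds."""


class HgvsError(VariantError):
    """Malformed or unsupported HGVS description."""


class UnsupportedHgvsLevelError(HgvsError):
    """Non-genomic (c./p./r./n./m.) HGVS descriptions are not resolved locally."""


class UnmappableVariantError(VariantError):
    """No interval of the assembly map covers the variant position."""


class UnsupportedConversionError(VariantError):
    """No provider registered for the requested assembly pair."""


def canonical_chrom(name: str) -> str:
    """Strip a ``chr``/``Chr``/``CHR`` prefix to the bare sequence name."""
    return name[3:] if name[:3].lower() == "chr" else name


@dataclass(frozen=True)
class Variant:
    """An assembly-tagged small variant in VCF-like representation."""

    assembly: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", canonical_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def end(self) -> int:
        """1-based inclusive last reference position covered by ref."""
        return self.pos + len(self.ref) - 1

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.assembly, self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class ReferenceGenome:
    """Uppercase in-memory reference with 1-based inclusive lookups."""

    def __init__(self, sequences: Mapping[str, str], assembly: str):
        self.sequences = {canonical_chrom(n): s.upper() for n, s in sequences.items()}
        self.assembly = assembly

    @classmethod
    def from_fasta(cls, path: str | Path | IO[str], assembly: str) -> "ReferenceGenome":
        records = SeqIO.parse(path if hasattr(path, "read") else str(path), "fasta")
        return cls({rec.id: str(rec.seq) for rec in records}, assembly)

    def __contains__(self, chrom: str) -> bool:
        return canonical_chrom(chrom) in self.sequences

    def length(self, chrom: str) -> int:
        return len(self._seq(chrom))

    def _seq(self, chrom: str) -> str:
        try:
            return self.sequences[canonical_chrom(chrom)]
        except KeyError:
            raise BoundaryError(f"unknown contig {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases at [start, end], both 1-based inclusive."""
        seq = self._seq(chrom)
        if start < 1 or end > len(seq) or start > end:
            raise BoundaryError(
                f"{chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


# ---------------------------------------------------------------------------
# VCF

@dataclass
class VcfReadResult:
    variants: list[Variant]
    rejected: list[tuple[str, str]]  # (record as text, reason)


def _check_allele(allele: str, what: str) -> str | None:
    if allele in ("", "."):
        return f"missing {what} allele"
    if any(ch in allele for ch in "<>[]"):
        return "symbolic allele"
    if allele == "*":
        return "overlapping-deletion placeholder allele"
    if not _ALLELE_RE.match(allele.upper()):
        return f"non-ACGT {what} allele"
    return None


def read_vcf(path: str | Path, assembly: str) -> VcfReadResult:
    """Read site records from an (uncompressed or bgzipped) VCF.

    Multi-allelic rows are split into one :class:`Variant` per ALT allele.
    Symbolic alleles, breakends and non-ACGT alleles are rejected per allele
    with a reason; a bad allele never aborts the whole file.  Genotype and
    sample columns are ignored.
    """
    result = VcfReadResult([], [])
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            label = f"{rec.chrom}:{rec.pos}:{rec.ref}"
            reason = _check_allele(rec.ref or "", "ref")
            if reason:
                result.rejected.append((label, reason))
                continue
            for alt in rec.alts or ():
                allele_label = f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}"
                reason = _check_allele(alt, "alt")
                if reason is None and alt.upper() == (rec.ref or "").upper():
                    reason = "ref and alt alleles identical"
                if reason:
                    result.rejected.append((allele_label, reason))
                    continue
                result.variants.append(
                    Variant(assembly, rec.chrom, rec.pos, rec.ref, alt)
                )
    return result


def write_vcf(
    variants: Iterable[Variant],
    path: str | Path,
    assembly: str | None = None,
    chr_prefix: bool = True,
) -> None:
    """Write site-only VCF 4.2 (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    variants = list(variants)
    lines = ["##fileformat=VCFv4.2"]
    if assembly:
        lines.append(f"##reference={assembly}")
    contigs = sorted({v.chrom for v in variants})
    for c in contigs:
        lines.append(f"##contig=<ID={'chr' + c if chr_prefix else c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        chrom = ("chr" + v.chrom) if chr_prefix else v.chrom
        lines.append(f"{chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# HGVS (genomic level only)

_HGVS_SPLIT = re.compile(r"^(?P<acc>[^:\s]+):(?P<level>[a-z])\.(?P<desc>\S+)$")
_HGVS_SUB = re.compile(r"^(?P<pos>\d+)(?P<ref>[ACGTacgt])>(?P<alt>[ACGTacgt])$")
_HGVS_DELINS = re.compile(r"^(?P<start>\d+)(?:_(?P<end>\d+))?delins(?P<alt>[ACGTacgt]+)$")
_HGVS_DEL = re.compile(r"^(?P<start>\d+)(?:_(?P<end>\d+))?del(?P<seq>[ACGTacgt]*)$")
_HGVS_DUP = re.compile(r"^(?P<start>\d+)(?:_(?P<end>\d+))?dup(?P<seq>[ACGTacgt]*)$")
_HGVS_INS = re.compile(r"^(?P<start>\d+)_(?P<end>\d+)ins(?P<alt>[ACGTacgt]+)$")


def _anchored_deletion(
    chrom: str, start: int, end: int, genome: ReferenceGenome, assembly: str
) -> Variant:
    if start > 1:
        anchor = start - 1
        ref = genome.fetch(chrom, anchor, end)
        return Variant(assembly, chrom, anchor, ref, ref[0])
    # Deletion at the very 5' end: anchor on the base to the right.
    anchor = end + 1
    ref = genome.fetch(chrom, start, anchor)
    return Variant(assembly, chrom, start, ref, ref[-1])


def parse_hgvs_g(
    expr: str,
    ref_genome: ReferenceGenome,
    contig_map: Mapping[str, str] | None = None,
) -> Variant:
    """Convert a genomic-level HGVS description into a VCF-like variant.

    Supported: substitution (``g.3G>T``), deletion (``g.4_5del``,
    ``g.4delC``), duplication (``g.4_8dup``), insertion (``g.3_4insTT``) and
    delins (``g.4_6delinsA``), all with explicit numeric coordinates.
    Deletions/insertions are returned with a left anchor base so alleles are
    never empty.  ``contig_map`` translates accessions (e.g. RefSeq ``NC_``
    names) to reference sequence names; without it the accession itself must
    name a contig of ``ref_genome``.

    Coding/protein/RNA-level descriptions require transcript projection,
    which this engine does not perform locally; they raise
    :class:`UnsupportedHgvsLevelError` so the caller can trace the record.
    """
    m = _HGVS_SPLIT.match(expr.strip())
    if not m:
        raise HgvsError(f"cannot parse HGVS expression {expr!r}")
    if m["level"] != "g":
        raise UnsupportedHgvsLevelError(
            f"{expr!r}: only genomic (g.) descriptions are resolved locally"
        )
    acc = m["acc"]
    chrom = (contig_map or {}).get(acc, acc)
    if chrom not in ref_genome:
        raise HgvsError(f"unknown sequence accession {acc!r}")
    desc = m["desc"]
    assembly = ref_genome.assembly

    if sub := _HGVS_SUB.match(desc):
        pos = int(sub["pos"])
        ref = sub["ref"].upper()
        actual = ref_genome.base(chrom, pos)
        if actual != ref:
            raise ReferenceMismatchError(
                f"{expr}: reference has {actual} at {chrom}:{pos}, not {ref}"
            )
        return Variant(assembly, chrom, pos, ref, sub["alt"].upper())

    if dl := _HGVS_DELINS.match(desc):
        start = int(dl["start"])
        end = int(dl["end"] or start)
        ref = ref_genome.fetch(chrom, start, end)
        return Variant(assembly, chrom, start, ref, dl["alt"].upper())

    if d := _HGVS_DEL.match(desc):
        start = int(d["start"])
        end = int(d["end"] or start)
        if d["seq"]:
            actual = ref_genome.fetch(chrom, start, end)
            if actual != d["seq"].upper():
                raise ReferenceMismatchError(
                    f"{expr}: reference has {actual} at {chrom}:{start}-{end}"
                )
        return _anchored_deletion(chrom, start, end, ref_genome, assembly)

    if dup := _HGVS_DUP.match(desc):
        start = int(dup["start"])
        end = int(dup["end"] or start)
        unit = ref_genome.fetch(chrom, start, end)
        if dup["seq"] and unit != dup["seq"].upper():
            raise ReferenceMismatchError(
                f"{expr}: reference has {unit} at {chrom}:{start}-{end}"
            )
        # Duplication == insertion of the unit after its last base.
        anchor = ref_genome.base(chrom, end)
        return Variant(assembly, chrom, end, anchor, anchor + unit)

    if ins := _HGVS_INS.match(desc):
        start, end = int(ins["start"]), int(ins["end"])
        if end != start + 1:
            raise HgvsError(f"{expr}: insertion coordinates must be adjacent")
        anchor = ref_genome.base(chrom, start)
        return Variant(assembly, chrom, start, anchor, anchor + ins["alt"].upper())

    raise HgvsError(f"unsupported HGVS description {expr!r}")


# ---------------------------------------------------------------------------
# Normalization

def apply_variant(v: Variant, ref_genome: ReferenceGenome) -> str:
    """Return the full mutated contig sequence after applying ``v``.

    Used as the semantic oracle for normalization: two representations are
    equivalent iff they produce the same mutated sequence.
    """
    seq = ref_genome._seq(v.chrom)
    if v.end > len(seq):
        raise BoundaryError(f"{v} extends beyond contig end {len(seq)}")
    if seq[v.pos - 1 : v.end].upper() != v.ref:
        raise ReferenceMismatchError(
            f"{v}: reference has {seq[v.pos - 1 : v.end]} at {v.chrom}:{v.pos}"
        )
    return seq[: v.pos - 1] + v.alt + seq[v.end :]


def left_normalize(v: Variant, ref_genome: ReferenceGenome) -> Variant:
    """Left-align and trim a variant to its minimal representation.

    Iteratively strips identical terminal bases (re-anchoring one base to
    the left whenever an allele would become empty), then trims identical
    leading bases while both alleles keep length >= 2.  The result applies
    to the reference identically to the input, is idempotent, and is the
    left-most shortest representation of the edit.
    """
    seq = ref_genome._seq(v.chrom)
    if v.end > len(seq):
        raise BoundaryError(f"{v} extends beyond contig end {len(seq)}")
    if seq[v.pos - 1 : v.end].upper() != v.ref:
        raise ReferenceMismatchError(
            f"{v}: reference has {seq[v.pos - 1 : v.end]} at {v.chrom}:{v.pos}"
        )

    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        changed = False
        # (a) strip identical terminal bases
        while ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
            # (b) re-anchor left when an allele empties
            if not ref or not alt:
                if pos == 1:
                    raise BoundaryError(
                        f"{v}: normalization walked off the 5' end of {v.chrom}"
                    )
                pos -= 1
                base = seq[pos - 1].upper()
                ref, alt = base + ref, base + alt
        if not changed:
            break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(v.assembly, v.chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Assembly conversion

class IdentityAssemblyMap:
    """Trivial provider for equal source/target labels (no-op remap)."""

    def __init__(self, assembly: str):
        self.source = assembly
        self.target = assembly

    def map_position(self, chrom: str, pos: int) -> tuple[str, int] | None:
        return (chrom, pos)


class OffsetIntervalMap:
    """Interval+offset coordinate map, loadable from 4-column text.

    Each line: ``chrom  start  end  offset`` (1-based inclusive source
    interval; target position = source + offset).  This covers fixture-scale
    conversions; a chain-file liftover provider can implement the same
    two-method protocol.
    """

    def __init__(
        self,
        intervals: Sequence[tuple[str, int, int, int]],
        source: str,
        target: str,
    ):
        self.intervals = [
            (canonical_chrom(c), s, e, off) for c, s, e, off in intervals
        ]
        self.source = source
        self.target = target

    @classmethod
    def from_file(cls, path: str | Path, source: str, target: str) -> "OffsetIntervalMap":
        intervals = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, offset = line.split()
            intervals.append((chrom, int(start), int(end), int(offset)))
        return cls(intervals, source, target)

    def map_position(self, chrom: str, pos: int) -> tuple[str, int] | None:
        chrom = canonical_chrom(chrom)
        for c, start, end, offset in self.intervals:
            if c == chrom and start <= pos <= end:
                return (chrom, pos + offset)
        return None


def convert_assembly(
    v: Variant,
    mapping,
    target_genome: ReferenceGenome | None = None,
) -> Variant:
    """Remap a variant onto the target assembly of ``mapping``.

    Identity when the variant already carries the target label.  After
    remapping, the ref allele is re-verified against ``target_genome`` when
    one is supplied; a mismatch or an uncovered position raises, and the
    pipeline traces the variant instead of storing it.
    """
    if v.assembly == mapping.target:
        return v
    if v.assembly != mapping.source:
        raise UnsupportedConversionError(
            f"no provider for {v.assembly} -> {mapping.target}"
        )
    mapped = mapping.map_position(v.chrom, v.pos)
    if mapped is None:
        raise UnmappableVariantError(f"{v}: position not covered by the assembly map")
    chrom, pos = mapped
    converted = Variant(mapping.target, chrom, pos, v.ref, v.alt)
    if target_genome is not None:
        actual = target_genome.fetch(chrom, pos, pos + len(v.ref) - 1)
        if actual != v.ref:
            raise ReferenceMismatchError(
                f"{v}: target reference has {actual} at {chrom}:{pos}"
            )
    return converted


# ---------------------------------------------------------------------------
# Submission validation

@dataclass
class ValidationResult:
    """Outcome of the submission sanity check.

    ``accepted`` and ``rejected`` partition the raw variant records of the
    submission; ``rejected`` pairs each failing record with a reason.
    """

    accepted: list = field(default_factory=list)
    rejected: list[tuple[object, str]] = field(default_factory=list)
    profile_ok: bool = False
    assembly_ok: bool = False
    resolved_terms: list[str] = field(default_factory=list)
    term_issues: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.profile_ok and self.assembly_ok and bool(self.accepted)


def parse_generic_record(record: Mapping, assembly: str) -> Variant:
    """Build a Variant from a generic ``{chrom, pos, ref, alt}`` JSON object."""
    try:
        chrom = record["chrom"]
        pos = int(record["pos"])
        ref = str(record["ref"])
        alt = str(record["alt"])
    except (KeyError, TypeError, ValueError) as exc:
        raise VariantError(f"malformed generic record: {exc}") from exc
    for allele, what in ((ref, "ref"), (alt, "alt")):
        reason = _check_allele(allele, what)
        if reason:
            raise VariantError(reason)
    return Variant(record.get("assembly", assembly), chrom, pos, ref, alt)


def validate_submission(
    raw: Mapping,
    ontology,
    accepted_assemblies: Sequence[str],
) -> ValidationResult:
    """Format-level sanity check of a raw submission document.

    Requirements: a declared assembly among ``accepted_assemblies``, at
    least one variant source (``variants`` generic records, a ``vcf`` path
    or an ``hgvs`` list), and at least one phenotype term that resolves to a
    live ontology term (aliases and replaced-by redirects are followed).
    Per-record failures are collected, never fatal; the submission as a
    whole fails only when nothing valid remains.
    """
    result = ValidationResult()

    assembly = raw.get("assembly")
    result.assembly_ok = assembly in accepted_assemblies
    seen: set[str] = set()
    for term in raw.get("hpo_terms", []) or []:
        resolved = ontology.resolve(term)
        if resolved is None:
            result.term_issues.append((term, "unknown or obsolete phenotype term"))
        elif resolved not in seen:
            seen.add(resolved)
            result.resolved_terms.append(resolved)
        if resolved is not None and resolved != term:
            result.term_issues.append((term, f"resolved to {resolved}"))
    result.profile_ok = bool(result.resolved_terms)

    for record in raw.get("variants", []) or []:
        try:
            parse_generic_record(record, assembly or "")
            result.accepted.append(("generic", record))
        except VariantError as exc:
            result.rejected.append((record, str(exc)))

    vcf_path = raw.get("vcf")
    if vcf_path:
        if Path(vcf_path).is_file():
            result.accepted.append(("vcf", vcf_path))
        else:
            result.rejected.append((vcf_path, "VCF file not found"))

    for expr in raw.get("hgvs", []) or []:
        m = _HGVS_SPLIT.match(str(expr).strip())
        if not m:
            result.rejected.append((expr, "malformed HGVS expression"))
        elif m["level"] != "g":
            result.rejected.append(
                (expr, f"unsupported HGVS level '{m['level']}.' (genomic only)")
            )
        else:
            result.accepted.append(("hgvs", expr))

    return result
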