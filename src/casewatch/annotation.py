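"""Local, deterministic variant annotation against GFF3 gene models.

This is a deliberately minimal effect annotator covering exactly what
codon-level case matching needs: which gene(s) a variant hits, its region
(CDS / UTR / intron / upstream / downstream / intergenic), the 1-based codon
ordinal for coding positions, a coding consequence from the standard genetic
code, and a four-level impact class (HIGH > MODERATE > LOW > MODIFIER)
mirroring the usual effect-predictor vocabulary.  Splice sites, regulatory
features and pathogenicity scores are out of scope; intronic positions are
plain MODIFIER.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import gffutils
from Bio.Seq import Seq

from .variants import ReferenceGenome, Variant, canonical_chrom

__all__ = [
    "IMPACT_RANK",
    "Gene",
    "Transcript",
    "GeneModelSet",
    "TranscriptHit",
    "AnnotatedVariant",
    "FilterConfig",
    "GeneModelError",
    "read_gff3",
    "codon_index",
    "annotate_variant",
    "apply_filters",
]

IMPACT_RANK: dict[str, int] = {"HIGH": 4, "MODERATE": 3, "LOW": 2, "MODIFIER": 1}

_CONSEQUENCE_IMPACT = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift_variant": "HIGH",
    "missense_variant": "MODERATE",
    "inframe_indel": "MODERATE",
    "synonymous_variant": "LOW",
    "UTR_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}

#: How far up/downstream of a transcript a variant still yields a hit (bp).
FLANK_BP = 1000


class GeneModelError(Exception):
    """Structurally invalid gene models (e.g. CDS without a parent transcript)."""


@dataclass(frozen=True)
class Gene:
    id: str
    name: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    canonical: bool = False
    exons: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons.sort()
        self.cds.sort()

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_positions(self) -> list[int]:
        """Genomic positions of coding bases in transcript (5'->3') order.

        For minus-strand transcripts the list runs in descending genomic
        order, so that index arithmetic is identical for both strands.
        """
        positions: list[int] = []
        for start, end in self.cds:
            positions.extend(range(start, end + 1))
        if self.strand == "-":
            positions.reverse()
        return positions

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass
class GeneModelSet:
    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts.values():
            self._by_chrom.setdefault(t.chrom, []).append(t)
        for txs in self._by_chrom.values():
            txs.sort(key=lambda t: (t.span, t.id))

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def overlapping(
        self, chrom: str, start: int, end: int, flank: int = 0
    ) -> list[Transcript]:
        chrom = canonical_chrom(chrom)
        hits = []
        for t in self._by_chrom.get(chrom, []):
            lo, hi = t.span
            if start <= hi + flank and end >= lo - flank:
                hits.append(t)
        return hits


def _attr(feature, *names: str, default: str | None = None) -> str | None:
    for name in names:
        values = feature.attributes.get(name)
        if values:
            return values[0]
    return default


def read_gff3(source: str | Path) -> GeneModelSet:
    """Assemble gene models from GFF3 gene/mRNA/exon/CDS features.

    ``source`` may be a path or GFF3 text.  A transcript is marked canonical
    when it carries a truthy ``canonical``/``Ensembl_canonical`` attribute;
    otherwise the longest-CDS transcript of each gene is flagged.  CDS
    intervals must be attached (via Parent) to a transcript feature.
    """
    text_input = isinstance(source, str) and "\n" in source
    data = source if text_input else str(source)
    db = gffutils.create_db(
        data,
        ":memory:",
        from_string=text_input,
        merge_strategy="create_unique",
        keep_order=True,
    )

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    for g in db.features_of_type("gene"):
        genes[g.id] = Gene(
            id=g.id,
            name=_attr(g, "Name", default=g.id),
            chrom=canonical_chrom(g.seqid),
            strand=g.strand,
            biotype=_attr(g, "biotype", "gene_biotype", default="protein_coding"),
        )
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            canonical_attr = _attr(t, "canonical", "Ensembl_canonical")
            tx = Transcript(
                id=t.id,
                gene_id=g.id,
                chrom=canonical_chrom(t.seqid),
                strand=t.strand,
                biotype=_attr(t, "biotype", "transcript_biotype",
                              default=genes[g.id].biotype),
                canonical=str(canonical_attr).strip() in ("1", "true", "True"),
            )
            for e in db.children(t, featuretype="exon", order_by="start"):
                tx.exons.append((e.start, e.end))
            for c in db.children(t, featuretype="CDS", order_by="start"):
                tx.cds.append((c.start, c.end))
            tx.exons.sort()
            tx.cds.sort()
            if not tx.exons and tx.cds:
                tx.exons = list(tx.cds)
            if tx.exons:
                transcripts[tx.id] = tx

    for c in db.features_of_type("CDS"):
        parents = [p for p in db.parents(c, featuretype=("mRNA", "transcript"))]
        if not parents:
            raise GeneModelError(
                f"CDS feature without parent transcript at "
                f"{c.seqid}:{c.start}-{c.end}"
            )

    # Default canonical flag: longest CDS per gene wins, ties by id.
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts.values():
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gene_id, txs in by_gene.items():
        if not any(t.canonical for t in txs):
            best = max(txs, key=lambda t: (t.cds_length, t.id))
            best.canonical = True

    return GeneModelSet(genes=genes, transcripts=transcripts)


def codon_index(transcript: Transcript, genomic_pos: int) -> int | None:
    """1-based codon ordinal of a coding position, or None outside the CDS.

    The ordinal counts codons 5'->3' in transcript orientation: coding
    offset // 3 + 1.  On the minus strand the first codon therefore sits at
    the highest genomic coordinates.
    """
    if not transcript.in_cds(genomic_pos):
        return None
    positions = transcript.cds_positions()
    offset = positions.index(genomic_pos)
    return offset // 3 + 1


@dataclass(frozen=True)
class TranscriptHit:
    transcript_id: str
    gene_id: str
    region: str  # CDS | UTR | intron | upstream | downstream
    consequence: str
    impact: str
    codon_index: int | None = None
    canonical: bool = False
    biotype: str = "protein_coding"


@dataclass
class AnnotatedVariant:
    variant: Variant
    gene_ids: frozenset[str] = frozenset()
    transcript_hits: list[TranscriptHit] = field(default_factory=list)
    maf: float | None = None
    passed_filters: bool = False
    beacon_hit: bool = False
    filter_reasons: list[str] = field(default_factory=list)

    @property
    def max_impact(self) -> str | None:
        if not self.transcript_hits:
            return None
        return max(self.transcript_hits, key=lambda h: IMPACT_RANK[h.impact]).impact


def _snv_consequence(
    tx: Transcript, v: Variant, genome: ReferenceGenome
) -> tuple[str, int]:
    """Consequence and codon ordinal for a CDS substitution."""
    positions = tx.cds_positions()
    offset = positions.index(v.pos)
    ordinal = offset // 3 + 1
    codon_slots = positions[(offset // 3) * 3 : (offset // 3) * 3 + 3]
    if len(codon_slots) < 3:  # CDS not a codon multiple; treat as missense-like edge
        return ("missense_variant", ordinal)

    def oriented(base: str) -> str:
        return str(Seq(base).complement()) if tx.strand == "-" else base

    ref_codon = "".join(oriented(genome.base(tx.chrom, p)) for p in codon_slots)
    within = offset % 3
    alt_bases = list(ref_codon)
    alt_bases[within] = oriented(v.alt)
    alt_codon = "".join(alt_bases)

    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return ("synonymous_variant", ordinal)
    if ordinal == 1 and aa_ref == "M":
        return ("start_lost", ordinal)
    if aa_ref == "*":
        return ("stop_lost", ordinal)
    if aa_alt == "*":
        return ("stop_gained", ordinal)
    return ("missense_variant", ordinal)


def _indel_codon(tx: Transcript, v: Variant) -> int | None:
    """Codon ordinal for an in-frame length change fully inside one codon."""
    if (len(v.ref) - len(v.alt)) % 3 != 0:
        return None
    ordinals = {codon_index(tx, p) for p in range(v.pos, v.end + 1)}
    if len(ordinals) == 1 and None not in ordinals:
        return ordinals.pop()
    return None


def annotate_variant(
    v: Variant,
    models: GeneModelSet,
    ref_genome: ReferenceGenome,
) -> AnnotatedVariant:
    """Annotate a normalized variant against every overlapping transcript.

    A variant outside all transcripts (even their flanks) is annotated as
    intergenic with no gene assignment — that is a value, not an error.
    """
    hits: list[TranscriptHit] = []
    for tx in models.overlapping(v.chrom, v.pos, v.end, flank=FLANK_BP):
        lo, hi = tx.span
        codon: int | None = None
        if v.pos > hi or v.end < lo:
            before = v.end < lo
            upstream = before if tx.strand == "+" else not before
            region = "upstream" if upstream else "downstream"
            consequence = f"{region}_gene_variant"
        elif any(tx.in_cds(p) for p in range(v.pos, v.end + 1)):
            region = "CDS"
            if v.is_snv:
                consequence, codon = _snv_consequence(tx, v, ref_genome)
            elif len(v.ref) != len(v.alt):
                if (len(v.ref) - len(v.alt)) % 3 != 0:
                    consequence = "frameshift_variant"
                else:
                    consequence = "inframe_indel"
                    codon = _indel_codon(tx, v)
            else:  # multi-nucleotide substitution
                consequence = "missense_variant"
                ordinals = {codon_index(tx, p) for p in range(v.pos, v.end + 1)}
                if len(ordinals) == 1 and None not in ordinals:
                    codon = ordinals.pop()
        elif any(tx.in_exon(p) for p in range(v.pos, v.end + 1)):
            region = "UTR"
            consequence = "UTR_variant"
        else:
            region = "intron"
            consequence = "intron_variant"
        hits.append(
            TranscriptHit(
                transcript_id=tx.id,
                gene_id=tx.gene_id,
                region=region,
                consequence=consequence,
                impact=_CONSEQUENCE_IMPACT[consequence],
                codon_index=codon,
                canonical=tx.canonical,
                biotype=tx.biotype,
            )
        )
    gene_ids = frozenset(
        h.gene_id for h in hits if h.region in ("CDS", "UTR", "intron")
    )
    return AnnotatedVariant(variant=v, gene_ids=gene_ids, transcript_hits=hits)


@dataclass(frozen=True)
class FilterConfig:
    """Gates deciding whether an annotated variant enters matching.

    ``max_maf``: highest tolerated population allele frequency (absent MAF
    passes — absence of evidence does not exclude).  ``min_impact``: lowest
    impact class still considered a deleterious effect.  The biotype and
    canonical gates restrict which transcript hits may satisfy the impact
    requirement.
    """

    max_maf: float = 0.01
    min_impact: str = "MODERATE"
    require_protein_coding: bool = False
    canonical_only: bool = False

    def __post_init__(self) -> None:
        if self.min_impact not in IMPACT_RANK:
            raise ValueError(f"unknown impact class {self.min_impact!r}")
        if not 0.0 <= self.max_maf <= 1.0:
            raise ValueError("max_maf must be a frequency in [0, 1]")


def apply_filters(av: AnnotatedVariant, cfg: FilterConfig) -> AnnotatedVariant:
    """Evaluate the filter gates and drop non-qualifying transcript hits.

    A variant passes when its MAF is under the threshold (or unknown) and at
    least one transcript hit meets the impact / biotype / canonical
    requirements.  Surviving hits replace the hit list so that downstream
    matching only ever sees qualifying transcripts; the reasons for failure
    are recorded for the processing trace.
    """
    reasons: list[str] = []
    if av.maf is not None and av.maf > cfg.max_maf:
        reasons.append(f"MAF {av.maf:g} above threshold {cfg.max_maf:g}")

    min_rank = IMPACT_RANK[cfg.min_impact]
    surviving = [
        h
        for h in av.transcript_hits
        if IMPACT_RANK[h.impact] >= min_rank
        and (not cfg.require_protein_coding or h.biotype == "protein_coding")
        and (not cfg.canonical_only or h.canonical)
    ]
    if not surviving:
        reasons.append(f"no transcript hit with impact >= {cfg.min_impact}")

    passed = not reasons
    hits = surviving if passed else list(av.transcript_hits)
    return AnnotatedVariant(
        variant=av.variant,
        gene_ids=frozenset(
            h.gene_id for h in hits if h.region in ("CDS", "UTR", "intron")
        ),
        transcript_hits=hits,
        maf=av.maf,
        passed_filters=passed,
        beacon_hit=av.beacon_hit,
        filter_reasons=reasons,
    )
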