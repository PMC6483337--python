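"""Synthetic fixture generators: mini ontologies, toy genomes with gene
models, and case cohorts with planted match structure.

Everything the engine consumes can be generated offline and
deterministically from a seed: an OBO ontology shaped like a phenotype
hierarchy (single root, configurable depth/branching and multi-parent
fraction), a FASTA reference with GFF3 gene models (ATG-initiated,
stop-terminated CDS on both strands, with a tandem-repeat tract for
normalization tests), and cohorts of submission documents in which selected
case pairs realize an exact genomic proximity category and a requested
phenotype-overlap bracket while filler cases are guaranteed not to match
anything.  Fixtures are structural, not biological: no realistic allele
frequencies, splice signals or disease genes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from .annotation import (
    GeneModelSet,
    Transcript,
    annotate_variant,
    apply_filters,
    codon_index,
    FilterConfig,
)
from .ontology import Ontology
from .variants import ReferenceGenome, Variant

__all__ = [
    "OntologySpec",
    "GenomeSpec",
    "PlantedPair",
    "CohortSpec",
    "FixtureSpec",
    "generate_mini_ontology",
    "generate_toy_genome",
    "generate_cohort",
    "deleterious_snv_candidates",
    "generate_category_showcase",
    "write_fixture_bundle",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
]
REPEAT_TRACT = "CACACACACA"

CATEGORIES = ("IDENTICAL", "SAME_POSITION", "SAME_CODON", "SAME_GENE")
OVERLAPS = ("high", "medium", "low")


@dataclass(frozen=True)
class OntologySpec:
    depth: int = 4
    branching: int = 2
    multi_parent_fraction: float = 0.0


@dataclass(frozen=True)
class GenomeSpec:
    n_chroms: int = 1
    chrom_length: int = 8000
    n_genes: int = 8
    strand_mix: str = "both"  # both | forward | reverse


@dataclass(frozen=True)
class PlantedPair:
    category: str
    phenotype_overlap: str = "high"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown proximity category {self.category!r}")
        if self.phenotype_overlap not in OVERLAPS:
            raise ValueError(f"unknown overlap bracket {self.phenotype_overlap!r}")


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = 20
    planted_pairs: tuple[PlantedPair, ...] = ()


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    ontology: OntologySpec = OntologySpec()
    genome: GenomeSpec = GenomeSpec()
    cohort: CohortSpec = CohortSpec()


# ---------------------------------------------------------------------------
# Ontology

def generate_mini_ontology(
    spec: OntologySpec = OntologySpec(), seed: int = 0
) -> tuple[str, dict[str, int]]:
    """Emit OBO text for a rooted DAG plus a term -> depth table.

    The backbone is a complete tree of the requested depth and branching
    (depth counts edges below the root, so depth=4, branching=2 gives
    1+2+4+8+16 = 31 terms).  ``multi_parent_fraction`` of the terms at depth
    >= 2 receive one extra is_a parent chosen among strictly shallower
    terms, which keeps the graph acyclic while creating multiple root paths.
    """
    if spec.depth < 2 or spec.branching < 1:
        raise ValueError("ontology fixture needs depth >= 2 and branching >= 1")
    if spec.multi_parent_fraction > 0 and (spec.depth < 3 or spec.branching < 2):
        raise ValueError(
            "multi-parent terms need depth >= 3 and branching >= 2 to have "
            "a non-ancestor extra parent available"
        )
    rng = random.Random(seed)

    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"HP:{counter:07d}"

    root = new_id()
    depths = {root: 0}
    parents: dict[str, list[str]] = {root: []}
    levels: list[list[str]] = [[root]]
    for d in range(1, spec.depth + 1):
        level: list[str] = []
        for parent in levels[d - 1]:
            for _ in range(spec.branching):
                tid = new_id()
                depths[tid] = d
                parents[tid] = [parent]
                level.append(tid)
        levels.append(level)

    eligible = [t for t in depths if depths[t] >= 2]
    n_multi = round(spec.multi_parent_fraction * len(eligible))
    for tid in rng.sample(sorted(eligible), n_multi):
        shallower = [
            s for s in depths
            if depths[s] < depths[tid] and s not in parents[tid] and s != root
        ]
        if shallower:
            parents[tid].append(rng.choice(sorted(shallower)))

    lines = [
        "format-version: 1.2",
        f"data-version: toy/{seed}",
        "ontology: toy-phenotype",
        "",
    ]
    for tid in sorted(depths):
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: term depth {depths[tid]} ({tid})")
        for p in parents[tid]:
            lines.append(f"is_a: {p} ! parent")
        lines.append("")
    return "\n".join(lines), depths


# ---------------------------------------------------------------------------
# Genome + gene models

def _split_lengths(rng: random.Random, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` chunks of >= 3, multiple-of-1 sizes."""
    cuts = sorted(rng.sample(range(3, total - 2, 3), parts - 1)) if parts > 1 else []
    bounds = [0, *cuts, total]
    return [bounds[i + 1] - bounds[i] for i in range(parts)]


def generate_toy_genome(
    spec: GenomeSpec = GenomeSpec(), seed: int = 0
) -> tuple[str, str]:
    """Emit FASTA + GFF3 texts for a toy genome with planted gene models.

    Genes carry 1-3 exons, an ATG-initiated, stop-terminated CDS whose
    length is a multiple of three, short UTRs, and sit in non-overlapping
    slots.  Chromosome 1 additionally carries a CA tandem-repeat tract
    (positions 31-40) for normalization tests.  Strand per gene follows
    ``strand_mix``.
    """
    if spec.chrom_length < 200 * max(1, spec.n_genes) // max(1, spec.n_chroms):
        raise ValueError("chrom_length too small for the requested gene count")
    rng = random.Random(seed)

    chroms = {
        f"chr{i + 1}": [rng.choice(_BASES) for _ in range(spec.chrom_length)]
        for i in range(spec.n_chroms)
    }
    first = f"chr1"
    for i, base in enumerate(REPEAT_TRACT):
        chroms[first][30 + i] = base

    gff = ["##gff-version 3"]
    for name in chroms:
        gff.append(f"##sequence-region {name} 1 {spec.chrom_length}")

    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1

    gene_no = 0
    for ci, (chrom, seq) in enumerate(chroms.items()):
        n_here = per_chrom[ci]
        if n_here == 0:
            continue
        usable_start = 60  # keep clear of the repeat tract on chr1
        slot = (spec.chrom_length - usable_start - 20) // n_here
        for gi in range(n_here):
            gene_no += 1
            gene_id = f"gene{gene_no}"
            tx_id = f"tx{gene_no}.1"
            if spec.strand_mix == "forward":
                strand = "+"
            elif spec.strand_mix == "reverse":
                strand = "-"
            else:
                strand = "+" if gene_no % 2 else "-"

            n_codons = rng.randint(10, 16)
            coding = "ATG" + "".join(
                rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2)
            ) + rng.choice(sorted(_STOPS))
            n_exons = rng.randint(1, 3)
            chunks = _split_lengths(rng, len(coding), n_exons)

            utr5, utr3 = 8, 8
            start = usable_start + gi * slot + rng.randint(0, 10)
            # Build exon/CDS intervals in ascending genomic order.  For the
            # minus strand the transcript's 5' end is genomic-rightmost, so
            # the chunk order along the genome is reversed.
            genomic_chunks = chunks if strand == "+" else list(reversed(chunks))
            exons: list[tuple[int, int]] = []
            cds: list[tuple[int, int]] = []
            pos = start
            for k, chunk in enumerate(genomic_chunks):
                exon_start = pos
                lead = utr5 if (k == 0 and strand == "+") else (
                    utr3 if (k == 0 and strand == "-") else 0
                )
                cds_start = exon_start + lead
                cds_end = cds_start + chunk - 1
                tail = utr3 if (k == len(genomic_chunks) - 1 and strand == "+") else (
                    utr5 if (k == len(genomic_chunks) - 1 and strand == "-") else 0
                )
                exon_end = cds_end + tail
                exons.append((exon_start, exon_end))
                cds.append((cds_start, cds_end))
                pos = exon_end + rng.randint(20, 40) + 1

            # Write coding bases into the chromosome, strand-aware.
            positions: list[int] = []
            for s, e in cds:
                positions.extend(range(s, e + 1))
            if strand == "-":
                positions.reverse()
            for base, p in zip(coding, positions):
                seq[p - 1] = base if strand == "+" else str(Seq(base).complement())

            gene_start, gene_end = exons[0][0], exons[-1][1]
            attrs = f"ID={gene_id};Name={gene_id.upper()};biotype=protein_coding"
            gff.append(
                f"{chrom}\ttoy\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t{attrs}"
            )
            gff.append(
                f"{chrom}\ttoy\tmRNA\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t"
                f"ID={tx_id};Parent={gene_id};biotype=protein_coding;canonical=1"
            )
            for k, (s, e) in enumerate(exons, start=1):
                gff.append(
                    f"{chrom}\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={tx_id}.e{k};Parent={tx_id}"
                )
            # Phase is defined along the transcript: bases carried over from
            # the previous CDS segment.
            tx_order = cds if strand == "+" else list(reversed(cds))
            cum = 0
            phases: dict[tuple[int, int], int] = {}
            for s, e in tx_order:
                phases[(s, e)] = (3 - (cum % 3)) % 3
                cum += e - s + 1
            for k, (s, e) in enumerate(cds, start=1):
                gff.append(
                    f"{chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{strand}\t{phases[(s, e)]}\t"
                    f"ID={tx_id}.c{k};Parent={tx_id}"
                )

    fasta_lines = []
    for name, seq in chroms.items():
        fasta_lines.append(f">{name}")
        s = "".join(seq)
        fasta_lines.extend(s[i : i + 60] for i in range(0, len(s), 60))
    return "\n".join(fasta_lines) + "\n", "\n".join(gff) + "\n"


# ---------------------------------------------------------------------------
# Cohorts with planted truth

def deleterious_snv_candidates(
    tx: Transcript,
    models: GeneModelSet,
    ref_genome: ReferenceGenome,
    cfg: FilterConfig | None = None,
) -> dict[int, list[Variant]]:
    """Filter-passing missense/nonsense SNV candidates per CDS position.

    The first and last codons are skipped so planted variants never touch
    the start or stop codon (keeping consequences predictable).
    """
    cfg = cfg or FilterConfig()
    positions = tx.cds_positions()
    interior = positions[3:-3]
    out: dict[int, list[Variant]] = {}
    for pos in interior:
        ref = ref_genome.base(tx.chrom, pos)
        for alt in _BASES:
            if alt == ref:
                continue
            v = Variant(ref_genome.assembly, tx.chrom, pos, ref, alt)
            av = apply_filters(annotate_variant(v, models, ref_genome), cfg)
            if av.passed_filters and any(
                h.consequence in ("missense_variant", "stop_gained")
                for h in av.transcript_hits
            ):
                out.setdefault(pos, []).append(v)
    return out


def _term_depths(ontology: Ontology) -> dict[str, int]:
    depths = {ontology.root_id: 0}
    frontier = [ontology.root_id]
    children: dict[str, list[str]] = {}
    for t in ontology.live_terms():
        for p in t.parent_ids:
            children.setdefault(p, []).append(t.id)
    while frontier:
        nxt = []
        for node in frontier:
            for child in children.get(node, []):
                if child not in depths:
                    depths[child] = depths[node] + 1
                    nxt.append(child)
        frontier = nxt
    return depths


def _branch_of(ontology: Ontology, term: str) -> str:
    """The depth-1 ancestor (top-level branch) of a term."""
    current = term
    while True:
        t = ontology[current]
        if not t.parent_ids:
            return current
        parent = sorted(t.parent_ids)[0]
        if parent == ontology.root_id:
            return current
        current = parent


def _plant_profiles(
    ontology: Ontology, overlap: str, rng: random.Random
) -> tuple[list[str], list[str]]:
    depths = _term_depths(ontology)
    children: dict[str, list[str]] = {}
    for t in ontology.live_terms():
        for p in t.parent_ids:
            children.setdefault(p, []).append(t.id)
    max_depth = max(depths.values())
    deep = sorted(t for t, d in depths.items() if d == max_depth)

    if overlap == "high":
        profile = rng.sample(deep, min(2, len(deep)))
        return list(profile), list(profile)

    if overlap == "medium":
        # two siblings under the deepest possible shared non-root parent
        candidates = sorted(
            p for p, kids in children.items()
            if len(set(kids)) >= 2 and p != ontology.root_id
        )
        if not candidates:
            raise ValueError(
                "medium-overlap planting needs a non-root term with two children"
            )
        parent = max(candidates, key=lambda p: (depths[p], p))
        sibs = sorted(set(children[parent]))
        return [sibs[0]], [sibs[1]]

    # low: two deep terms sharing as little ancestry as possible (ideally
    # only the root), found by exhaustive pairwise search over deep terms
    def lineage(term: str) -> frozenset[str]:
        seen, stack = {term}, [term]
        while stack:
            for p in ontology[stack.pop()].parent_ids:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return frozenset(seen)

    candidates = deep if len(deep) >= 2 else sorted(
        t for t, d in depths.items() if d >= max_depth - 1
    )
    if len(candidates) < 2:
        raise ValueError("low-overlap planting needs >= 2 deep terms")
    lineages = {t: lineage(t) for t in candidates}
    best_pair, best_overlap = None, None
    for i, t1 in enumerate(candidates):
        for t2 in candidates[i + 1 :]:
            overlap = len(lineages[t1] & lineages[t2])
            if best_overlap is None or overlap < best_overlap:
                best_pair, best_overlap = (t1, t2), overlap
    return [best_pair[0]], [best_pair[1]]


def _variant_record(v: Variant) -> dict:
    return {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}


def generate_cohort(
    spec: CohortSpec,
    ontology: Ontology,
    models: GeneModelSet,
    ref_genome: ReferenceGenome,
    seed: int = 0,
    assembly: str | None = None,
    filter_config: FilterConfig | None = None,
) -> tuple[list[dict], dict]:
    """Build submission documents with planted match structure plus truth.

    Each planted pair occupies its own gene, so pairs never interfere; each
    filler case also gets a private gene, guaranteeing category ``none``
    against every other case.  Returns ``(submissions, truth)`` where truth
    records, per planted pair, the 0-based submission indices, the planted
    proximity category and the overlap bracket.
    """
    assembly = assembly or ref_genome.assembly
    cfg = filter_config or FilterConfig()
    rng = random.Random(seed)

    n_planted_cases = 2 * len(spec.planted_pairs)
    n_fillers = spec.n_cases - n_planted_cases
    if n_fillers < 0:
        raise ValueError("n_cases smaller than the planted cases")

    genes_needed = len(spec.planted_pairs) + n_fillers
    canonical_txs = sorted(
        (t for t in models.transcripts.values() if t.canonical),
        key=lambda t: t.id,
    )
    if len(canonical_txs) < genes_needed:
        raise ValueError(
            f"genome has {len(canonical_txs)} genes but the cohort needs "
            f"{genes_needed}"
        )
    rng.shuffle(canonical_txs)

    cases: list[tuple[dict, str | None]] = []  # (submission, plant tag)

    def submission(variants: Sequence[Variant], terms: Sequence[str]) -> dict:
        return {
            "assembly": assembly,
            "variants": [_variant_record(v) for v in variants],
            "hpo_terms": sorted(set(terms)),
        }

    for pi, pair in enumerate(spec.planted_pairs):
        tx = canonical_txs[pi]
        cands = deleterious_snv_candidates(tx, models, ref_genome, cfg)
        if not cands:
            raise ValueError(f"gene {tx.gene_id}: no plantable deleterious SNV")
        order = sorted(cands)
        va, vb = _plant_variant_pair(pair.category, tx, cands, order, rng)
        prof_a, prof_b = _plant_profiles(ontology, pair.phenotype_overlap, rng)
        cases.append((submission([va], prof_a), f"pair{pi}a"))
        cases.append((submission([vb], prof_b), f"pair{pi}b"))

    depths = _term_depths(ontology)
    all_terms = sorted(t for t, d in depths.items() if d >= 1)
    for fi in range(n_fillers):
        tx = canonical_txs[len(spec.planted_pairs) + fi]
        cands = deleterious_snv_candidates(tx, models, ref_genome, cfg)
        pos = rng.choice(sorted(cands))
        v = rng.choice(sorted(cands[pos], key=lambda x: x.alt))
        terms = rng.sample(all_terms, min(2, len(all_terms)))
        cases.append((submission([v], terms), None))

    rng.shuffle(cases)
    submissions = []
    index_of: dict[str, int] = {}
    for idx, (sub, tag) in enumerate(cases):
        sub = dict(sub)
        sub["owner"] = f"user-{idx:02d}"
        submissions.append(sub)
        if tag:
            index_of[tag] = idx

    truth = {
        "n_cases": spec.n_cases,
        "assembly": assembly,
        "pairs": [
            {
                "case_index_a": index_of[f"pair{pi}a"],
                "case_index_b": index_of[f"pair{pi}b"],
                "category": pair.category,
                "overlap": pair.phenotype_overlap,
            }
            for pi, pair in enumerate(spec.planted_pairs)
        ],
    }
    return submissions, truth


def _plant_variant_pair(
    category: str,
    tx: Transcript,
    cands: dict[int, list[Variant]],
    order: list[int],
    rng: random.Random,
) -> tuple[Variant, Variant]:
    def pick(pos: int) -> Variant:
        return rng.choice(sorted(cands[pos], key=lambda v: v.alt))

    if category == "IDENTICAL":
        v = pick(rng.choice(order))
        return v, v
    if category == "SAME_POSITION":
        multi = [p for p in order if len(cands[p]) >= 2]
        pos = rng.choice(multi)
        opts = sorted(cands[pos], key=lambda v: v.alt)
        return opts[0], opts[1]
    if category == "SAME_CODON":
        by_codon: dict[int, list[int]] = {}
        for p in order:
            c = codon_index(tx, p)
            by_codon.setdefault(c, []).append(p)
        codons = sorted(c for c, ps in by_codon.items() if len(ps) >= 2)
        if not codons:
            raise ValueError(f"gene {tx.gene_id}: no codon with two plantable sites")
        c = rng.choice(codons)
        p1, p2 = sorted(by_codon[c])[:2]
        return pick(p1), pick(p2)
    # SAME_GENE: two positions in different codons
    by_codon = {}
    for p in order:
        by_codon.setdefault(codon_index(tx, p), []).append(p)
    codons = sorted(by_codon)
    if len(codons) < 2:
        raise ValueError(f"gene {tx.gene_id}: fewer than two plantable codons")
    c1, c2 = rng.sample(codons, 2)
    return pick(sorted(by_codon[c1])[0]), pick(sorted(by_codon[c2])[0])


def generate_category_showcase(
    ontology: Ontology,
    models: GeneModelSet,
    ref_genome: ReferenceGenome,
    seed: int = 0,
    assembly: str | None = None,
) -> tuple[list[dict], dict]:
    """One query case plus four hit cases, one per proximity category.

    All five cases target the same gene: the query variant, an identical
    copy, a different allele at the same position, a variant at a different
    position of the same codon, and a variant in a different codon.
    Phenotype overlaps are deliberately scrambled (the identical-variant hit
    gets the *least* similar profile) so that ranking must be category-first
    to come out in the canonical order.

    Returns ``(submissions, expected)`` where submissions[0] holds the four
    hit cases' documents followed by the query, and ``expected`` names the
    category each hit case should appear under in the query's report.
    """
    assembly = assembly or ref_genome.assembly
    rng = random.Random(seed)
    cfg = FilterConfig()

    for tx in sorted(
        (t for t in models.transcripts.values() if t.canonical), key=lambda t: t.id
    ):
        cands = deleterious_snv_candidates(tx, models, ref_genome, cfg)
        by_codon: dict[int, list[int]] = {}
        for p in sorted(cands):
            by_codon.setdefault(codon_index(tx, p), []).append(p)
        shared = sorted(
            c for c, ps in by_codon.items()
            if len(ps) >= 2 and any(len(cands[p]) >= 2 for p in ps)
        )
        if shared and len(by_codon) >= 2:
            codon = shared[0]
            anchor = next(p for p in sorted(by_codon[codon]) if len(cands[p]) >= 2)
            other_in_codon = next(p for p in sorted(by_codon[codon]) if p != anchor)
            other_codon = next(c for c in sorted(by_codon) if c != codon)
            other_codon_pos = sorted(by_codon[other_codon])[0]
            alts = sorted(cands[anchor], key=lambda v: v.alt)
            query_v = alts[0]
            hits = {
                "IDENTICAL": alts[0],
                "SAME_POSITION": alts[1],
                "SAME_CODON": sorted(cands[other_in_codon], key=lambda v: v.alt)[0],
                "SAME_GENE": sorted(cands[other_codon_pos], key=lambda v: v.alt)[0],
            }
            break
    else:
        raise ValueError("no gene supports all four proximity categories")

    # Profiles: give the strongest genomic hit the weakest phenotype overlap.
    depths = _term_depths(ontology)
    deep = sorted(t for t, d in depths.items() if d == max(depths.values()))
    query_profile = [deep[0]]
    hit_profiles = {
        "IDENTICAL": _plant_profiles(ontology, "low", rng)[1],
        "SAME_POSITION": [deep[min(1, len(deep) - 1)]],
        "SAME_CODON": query_profile,
        "SAME_GENE": query_profile,
    }

    submissions = []
    expected = {}
    for i, cat in enumerate(CATEGORIES):
        submissions.append(
            {
                "owner": f"hit-owner-{i}",
                "assembly": assembly,
                "variants": [_variant_record(hits[cat])],
                "hpo_terms": sorted(set(hit_profiles[cat])),
            }
        )
        expected[cat] = i  # submission index of the case expected at this category
    submissions.append(
        {
            "owner": "query-owner",
            "assembly": assembly,
            "variants": [_variant_record(query_v)],
            "hpo_terms": sorted(set(query_profile)),
        }
    )
    return submissions, expected


# ---------------------------------------------------------------------------
# Bundles (for the CLI `fixtures` command and worked examples)

def write_fixture_bundle(
    outdir: str | Path,
    spec: FixtureSpec = FixtureSpec(),
    assembly: str = "ToyRef-1",
) -> dict:
    """Write a complete offline fixture set: OBO, FASTA, GFF3, an empty
    known-variant VCF, submission JSON documents, planted truth and a ready
    engine config.  Returns a manifest of the written paths."""
    import json

    from .ontology import parse_obo
    from .annotation import read_gff3

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    obo_text, _ = generate_mini_ontology(spec.ontology, seed=spec.seed)
    fasta_text, gff_text = generate_toy_genome(spec.genome, seed=spec.seed)
    (out / "ontology.obo").write_text(obo_text)
    (out / "genome.fa").write_text(fasta_text)
    (out / "models.gff3").write_text(gff_text)
    (out / "known.vcf").write_text(
        "##fileformat=VCFv4.2\n"
        f"##reference={assembly}\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )

    ontology = parse_obo(str(out / "ontology.obo"))
    ref_genome = ReferenceGenome.from_fasta(out / "genome.fa", assembly)
    models = read_gff3(out / "models.gff3")
    submissions, truth = generate_cohort(
        spec.cohort, ontology, models, ref_genome, seed=spec.seed, assembly=assembly
    )

    subdir = out / "submissions"
    subdir.mkdir(exist_ok=True)
    sub_paths = []
    for i, sub in enumerate(submissions):
        p = subdir / f"case{i:03d}.json"
        p.write_text(json.dumps(sub, indent=2, sort_keys=True) + "\n")
        sub_paths.append(str(p))
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")

    config = {
        "ontology": "ontology.obo",
        "genome": "genome.fa",
        "gene_models": "models.gff3",
        "known_variants": "known.vcf",
        "assembly": assembly,
        "accepted_assemblies": [assembly],
        "top_n": 5,
        "filters": {
            "max_maf": 0.01,
            "min_impact": "MODERATE",
            "require_protein_coding": False,
            "canonical_only": False,
        },
        "store_dir": "store",
    }
    import yaml

    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    return {
        "ontology": str(out / "ontology.obo"),
        "genome": str(out / "genome.fa"),
        "gene_models": str(out / "models.gff3"),
        "known_variants": str(out / "known.vcf"),
        "config": str(out / "config.yaml"),
        "truth": str(out / "truth.json"),
        "submissions": sub_paths,
    }
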