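import textwrap

import pytest

from casewatch.annotation import (
    FilterConfig,
    GeneModelError,
    IMPACT_RANK,
    annotate_variant,
    apply_filters,
    codon_index,
    read_gff3,
)
from casewatch.variants import ReferenceGenome, Variant

from _oracles import spliced_consequence_oracle

GFF_ONE_GENE = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\ttoy\tgene\t91\t240\t.\t+\t.\tID=g1;Name=G1;biotype=protein_coding
    chr1\ttoy\tmRNA\t91\t240\t.\t+\t.\tID=t1;Parent=g1
    chr1\ttoy\texon\t91\t130\t.\t+\t.\tID=t1.e1;Parent=t1
    chr1\ttoy\texon\t171\t240\t.\t+\t.\tID=t1.e2;Parent=t1
    chr1\ttoy\tCDS\t101\t130\t.\t+\t0\tID=t1.c1;Parent=t1
    chr1\ttoy\tCDS\t171\t200\t.\t+\t0\tID=t1.c2;Parent=t1
    """
)


class TestReadGff3:
    def test_hand_written_fixture_parses(self):
        models = read_gff3(GFF_ONE_GENE)
        assert set(models.genes) == {"g1"}
        tx = models.transcripts["t1"]
        assert tx.cds_length == 60
        assert tx.exons == [(91, 130), (171, 240)]
        assert tx.canonical  # sole transcript becomes canonical by default

    def test_longest_cds_flagged_canonical_by_default(self):
        gff = GFF_ONE_GENE + textwrap.dedent(
            """\
            chr1\ttoy\tmRNA\t91\t240\t.\t+\t.\tID=t2;Parent=g1
            chr1\ttoy\texon\t91\t130\t.\t+\t.\tID=t2.e1;Parent=t2
            chr1\ttoy\tCDS\t101\t130\t.\t+\t0\tID=t2.c1;Parent=t2
            """
        )
        models = read_gff3(gff)
        assert models.transcripts["t1"].canonical
        assert not models.transcripts["t2"].canonical

    def test_cds_without_parent_transcript_is_error(self):
        gff = GFF_ONE_GENE + "chr1\ttoy\tCDS\t500\t520\t.\t+\t0\tID=orphan\n"
        with pytest.raises(GeneModelError):
            read_gff3(gff)


class TestCodonIndex:
    def test_forward_strand_arithmetic(self):
        tx = read_gff3(GFF_ONE_GENE).transcripts["t1"]
        assert [codon_index(tx, p) for p in (101, 102, 103, 104)] == [1, 1, 1, 2]
        # codon 11 spans the intron: last CDS base of exon1 and first of exon2
        assert codon_index(tx, 130) == 10
        assert codon_index(tx, 171) == 11

    def test_reverse_strand_counts_from_genomic_right(self):
        gff = GFF_ONE_GENE.replace("\t+\t", "\t-\t")
        tx = read_gff3(gff).transcripts["t1"]
        assert codon_index(tx, 200) == 1
        assert codon_index(tx, 197) == 2
        assert codon_index(tx, 101) == 20

    def test_non_cds_positions_are_absent(self):
        tx = read_gff3(GFF_ONE_GENE).transcripts["t1"]
        assert codon_index(tx, 150) is None  # intron
        assert codon_index(tx, 95) is None  # UTR


def _toy_world_gene(world, strand=None):
    """A canonical transcript from the generated toy genome, by strand."""
    txs = sorted(
        (t for t in world["models"].transcripts.values() if t.canonical),
        key=lambda t: t.id,
    )
    if strand:
        txs = [t for t in txs if t.strand == strand]
    return txs[0]


class TestAnnotateVariant:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_cds_snv_consequences_match_splice_translate_oracle(self, toy_world, strand):
        """Every possible CDS substitution of one gene per strand gets the
        same consequence as physically splicing, mutating and translating."""
        tx = _toy_world_gene(toy_world, strand)
        rg = toy_world["ref_genome"]
        models = toy_world["models"]
        seen = set()
        for pos in tx.cds_positions():
            ref = rg.base(tx.chrom, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = Variant(rg.assembly, tx.chrom, pos, ref, alt)
                av = annotate_variant(v, models, rg)
                hit = next(h for h in av.transcript_hits if h.transcript_id == tx.id)
                assert hit.region == "CDS"
                assert hit.consequence == spliced_consequence_oracle(tx, v, rg)
                assert hit.codon_index == codon_index(tx, pos)
                seen.add(hit.consequence)
        assert {"missense_variant", "synonymous_variant", "stop_gained"} <= seen

    def test_impact_classes_follow_consequence(self, toy_world):
        tx = _toy_world_gene(toy_world)
        rg = toy_world["ref_genome"]
        for pos in tx.cds_positions():
            ref = rg.base(tx.chrom, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                av = annotate_variant(
                    Variant(rg.assembly, tx.chrom, pos, ref, alt),
                    toy_world["models"], rg,
                )
                hit = next(h for h in av.transcript_hits if h.transcript_id == tx.id)
                expected = {
                    "stop_gained": "HIGH", "stop_lost": "HIGH", "start_lost": "HIGH",
                    "missense_variant": "MODERATE", "synonymous_variant": "LOW",
                }[hit.consequence]
                assert hit.impact == expected

    def test_two_bp_cds_deletion_is_frameshift(self, toy_world):
        tx = _toy_world_gene(toy_world, "+")
        rg = toy_world["ref_genome"]
        start, end = max(tx.cds, key=lambda c: c[1] - c[0])
        pos = start + 1
        assert pos + 2 <= end
        ref = rg.fetch(tx.chrom, pos, pos + 2)
        av = annotate_variant(
            Variant(rg.assembly, tx.chrom, pos, ref, ref[0]),
            toy_world["models"], rg,
        )
        hit = next(h for h in av.transcript_hits if h.transcript_id == tx.id)
        assert hit.consequence == "frameshift_variant"
        assert hit.impact == "HIGH"

    def test_inframe_deletion_within_one_codon_keeps_codon_index(self, toy_world):
        tx = _toy_world_gene(toy_world, "+")
        rg = toy_world["ref_genome"]
        # first codon fully contained in the largest CDS interval, with the
        # anchor base still inside the CDS
        start, end = max(tx.cds, key=lambda c: c[1] - c[0])
        positions = tx.cds_positions()
        codon2_start = next(
            p for p in positions
            if p > start and p + 2 <= end and codon_index(tx, p) == codon_index(tx, p + 2)
            and positions.index(p) % 3 == 0
        )
        ref = rg.fetch(tx.chrom, codon2_start - 1, codon2_start + 2)
        av = annotate_variant(
            Variant(rg.assembly, tx.chrom, codon2_start - 1, ref, ref[0]),
            toy_world["models"], rg,
        )
        hit = next(h for h in av.transcript_hits if h.transcript_id == tx.id)
        assert hit.consequence == "inframe_indel"
        assert hit.impact == "MODERATE"

    def test_noncoding_regions_classified(self, toy_world):
        tx = _toy_world_gene(toy_world, "+")
        rg = toy_world["ref_genome"]
        models = toy_world["models"]

        def hit_at(pos):
            ref = rg.base(tx.chrom, pos)
            alt = "A" if ref != "A" else "C"
            av = annotate_variant(Variant(rg.assembly, tx.chrom, pos, ref, alt), models, rg)
            return next(h for h in av.transcript_hits if h.transcript_id == tx.id)

        utr = hit_at(tx.exons[0][0])  # 5' UTR base
        assert (utr.region, utr.impact) == ("UTR", "MODIFIER")
        if len(tx.exons) > 1:
            intron = hit_at(tx.exons[0][1] + 2)
            assert (intron.region, intron.impact) == ("intron", "MODIFIER")
        upstream = hit_at(tx.span[0] - 5)
        assert upstream.region == "upstream"
        assert not upstream.region == "CDS"

    def test_variant_outside_all_models_is_intergenic(self, toy_world):
        rg = toy_world["ref_genome"]
        v = Variant(rg.assembly, "chr1", 5, rg.base("chr1", 5),
                    "A" if rg.base("chr1", 5) != "A" else "C")
        av = annotate_variant(v, toy_world["models"], rg)
        assert av.gene_ids == frozenset()
        assert all(h.region in ("upstream", "downstream") for h in av.transcript_hits)


def _annotated(world, consequence_wanted):
    """First SNV of the first forward gene with the wanted consequence."""
    tx = _toy_world_gene(world, "+")
    rg = world["ref_genome"]
    for pos in tx.cds_positions():
        ref = rg.base(tx.chrom, pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            av = annotate_variant(
                Variant(rg.assembly, tx.chrom, pos, ref, alt), world["models"], rg
            )
            hit = next(h for h in av.transcript_hits if h.transcript_id == tx.id)
            if hit.consequence == consequence_wanted:
                return av
    raise AssertionError(f"no {consequence_wanted} SNV found")


class TestFilters:
    def test_high_impact_and_absent_maf_pass_defaults(self, toy_world):
        av = _annotated(toy_world, "stop_gained")
        assert apply_filters(av, FilterConfig()).passed_filters

    def test_synonymous_only_excluded_at_moderate(self, toy_world):
        av = _annotated(toy_world, "synonymous_variant")
        out = apply_filters(av, FilterConfig(min_impact="MODERATE"))
        assert not out.passed_filters
        assert any("impact" in r for r in out.filter_reasons)
        assert apply_filters(av, FilterConfig(min_impact="LOW")).passed_filters

    def test_maf_above_threshold_excluded(self, toy_world):
        av = _annotated(toy_world, "missense_variant")
        av.maf = 0.05
        out = apply_filters(av, FilterConfig(max_maf=0.01))
        assert not out.passed_filters
        assert any("MAF" in r for r in out.filter_reasons)

    def test_filter_monotonicity(self, toy_world):
        """Lowering min_impact or raising max_maf never shrinks the pass set."""
        tx = _toy_world_gene(toy_world, "+")
        rg = toy_world["ref_genome"]
        avs = []
        for pos in tx.cds_positions()[:18]:
            ref = rg.base(tx.chrom, pos)
            for alt in "ACGT":
                if alt != ref:
                    av = annotate_variant(
                        Variant(rg.assembly, tx.chrom, pos, ref, alt),
                        toy_world["models"], rg,
                    )
                    av.maf = 0.02 if pos % 3 == 0 else None
                    avs.append(av)

        def passing(cfg):
            return {
                str(av.variant) for av in avs if apply_filters(av, cfg).passed_filters
            }

        ladder = ["HIGH", "MODERATE", "LOW", "MODIFIER"]
        for stricter, looser in zip(ladder, ladder[1:]):
            assert passing(FilterConfig(min_impact=stricter)) <= passing(
                FilterConfig(min_impact=looser)
            )
        assert passing(FilterConfig(max_maf=0.01)) <= passing(FilterConfig(max_maf=0.5))

    def test_canonical_only_gate(self, toy_world):
        av = _annotated(toy_world, "missense_variant")
        assert apply_filters(av, FilterConfig(canonical_only=True)).passed_filters
        # forge the hits as non-canonical and the gate must close
        av.transcript_hits = [
            type(h)(**{**h.__dict__, "canonical": False}) for h in av.transcript_hits
        ]
        assert not apply_filters(av, FilterConfig(canonical_only=True)).passed_filters
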