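import random
import textwrap

import pytest
from hypothesis import assume, given, settings, strategies as st

from casewatch.variants import (
    BoundaryError,
    HgvsError,
    IdentityAssemblyMap,
    OffsetIntervalMap,
    ReferenceGenome,
    ReferenceMismatchError,
    UnmappableVariantError,
    UnsupportedConversionError,
    UnsupportedHgvsLevelError,
    Variant,
    apply_variant,
    convert_assembly,
    left_normalize,
    parse_hgvs_g,
    read_vcf,
    validate_submission,
    write_vcf,
)

from _oracles import equivalent_representations, leftmost_minimal
from conftest import TOY_SEQ, random_repeat_reference, random_variant


def write_test_vcf(tmp_path, body: str):
    path = tmp_path / "in.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chrT,length=11>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + textwrap.dedent(body)
    )
    return path


class TestVariantType:
    def test_chr_prefix_stripped_and_alleles_uppercased(self):
        v = Variant("A1", "chrT", 3, "gca", "g")
        assert (v.chrom, v.ref, v.alt) == ("T", "GCA", "G")

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pos=0, ref="A", alt="T"),
            dict(pos=3, ref="", alt="T"),
            dict(pos=3, ref="A", alt=""),
            dict(pos=3, ref="A", alt="A"),
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Variant("A1", "T", **kwargs)


class TestReadVcf:
    def test_direct_field_mapping(self, tmp_path):
        path = write_test_vcf(tmp_path, "chrT\t3\t.\tGCA\tG\t.\t.\t.\n")
        result = read_vcf(path, "ToyRef-1")
        assert result.variants == [Variant("ToyRef-1", "T", 3, "GCA", "G")]
        assert not result.rejected

    def test_multiallelic_rows_split_per_alt(self, tmp_path):
        path = write_test_vcf(tmp_path, "chrT\t5\t.\tA\tT,C\t.\t.\t.\n")
        result = read_vcf(path, "ToyRef-1")
        assert [v.alt for v in result.variants] == ["T", "C"]
        assert {(v.chrom, v.pos, v.ref) for v in result.variants} == {("T", 5, "A")}

    def test_symbolic_allele_rejected_with_reason(self, tmp_path):
        path = write_test_vcf(
            tmp_path, "chrT\t5\t.\tA\t<DEL>\t.\t.\t.\nchrT\t7\t.\tA\tC\t.\t.\t.\n"
        )
        result = read_vcf(path, "ToyRef-1")
        assert len(result.variants) == 1
        assert len(result.rejected) == 1
        assert "symbolic" in result.rejected[0][1]

    def test_round_trip_through_export(self, tmp_path, toy_ref):
        path = write_test_vcf(
            tmp_path, "chrT\t1\t.\tGGG\tGGT\t.\t.\t.\nchrT\t7\t.\tACA\tA\t.\t.\t.\n"
        )
        normalized = [
            left_normalize(v, toy_ref)
            for v in read_vcf(path, "ToyRef-1").variants
        ]
        out = tmp_path / "out.vcf"
        write_vcf(normalized, out, assembly="ToyRef-1")
        again = read_vcf(out, "ToyRef-1")
        assert sorted(v.key for v in again.variants) == sorted(
            v.key for v in normalized
        )


class TestParseHgvsG:
    def test_substitution(self, toy_ref):
        assert parse_hgvs_g("chrT:g.3G>T", toy_ref) == Variant(
            "ToyRef-1", "T", 3, "G", "T"
        )

    def test_deletion_anchored_and_normalizes_to_expected(self, toy_ref):
        v = parse_hgvs_g("chrT:g.4_5del", toy_ref)
        assert apply_variant(v, toy_ref) == TOY_SEQ[:3] + TOY_SEQ[5:]
        assert left_normalize(v, toy_ref) == Variant("ToyRef-1", "T", 3, "GCA", "G")

    def test_insertion_uses_left_anchor_base(self, toy_ref):
        v = parse_hgvs_g("chrT:g.3_4insTT", toy_ref)
        assert v == Variant("ToyRef-1", "T", 3, "G", "GTT")
        assert apply_variant(v, toy_ref) == TOY_SEQ[:3] + "TT" + TOY_SEQ[3:]

    def test_duplication_equals_insertion_of_unit(self, toy_ref):
        v = parse_hgvs_g("chrT:g.4_5dup", toy_ref)
        assert apply_variant(v, toy_ref) == TOY_SEQ[:5] + "CA" + TOY_SEQ[5:]

    def test_delins(self, toy_ref):
        v = parse_hgvs_g("chrT:g.4_6delinsTT", toy_ref)
        assert v == Variant("ToyRef-1", "T", 4, "CAC", "TT")

    def test_contig_map_translates_accessions(self, toy_ref):
        v = parse_hgvs_g("NC_TEST.1:g.3G>T", toy_ref, contig_map={"NC_TEST.1": "chrT"})
        assert v.chrom == "T"

    def test_non_genomic_levels_unsupported(self, toy_ref):
        with pytest.raises(UnsupportedHgvsLevelError):
            parse_hgvs_g("NM_0001.1:c.76A>T", toy_ref)

    def test_unknown_accession_and_ref_mismatch(self, toy_ref):
        with pytest.raises(HgvsError):
            parse_hgvs_g("chrZ:g.3G>T", toy_ref)
        with pytest.raises(ReferenceMismatchError):
            parse_hgvs_g("chrT:g.3A>T", toy_ref)


class TestLeftNormalize:
    def test_shared_prefix_trimmed_to_snv(self, toy_ref):
        v = Variant("ToyRef-1", "T", 1, "GGG", "GGT")
        n = left_normalize(v, toy_ref)
        assert n == Variant("ToyRef-1", "T", 3, "G", "T")
        assert apply_variant(n, toy_ref) == apply_variant(v, toy_ref)

    def test_repeat_deletion_shifts_left(self, toy_ref):
        v = Variant("ToyRef-1", "T", 7, "ACA", "A")
        n = left_normalize(v, toy_ref)
        assert n == Variant("ToyRef-1", "T", 3, "GCA", "G")
        assert apply_variant(n, toy_ref) == apply_variant(v, toy_ref)
        reps = equivalent_representations(v, toy_ref)
        assert n == leftmost_minimal(reps)

    def test_minimal_snv_is_fixed_point(self, toy_ref):
        v = Variant("ToyRef-1", "T", 5, "A", "T")
        assert left_normalize(v, toy_ref) == v

    def test_reference_mismatch_rejected(self, toy_ref):
        with pytest.raises(ReferenceMismatchError):
            left_normalize(Variant("ToyRef-1", "T", 3, "T", "A"), toy_ref)

    def test_walking_off_five_prime_end_is_boundary_error(self):
        genome = ReferenceGenome({"c": "AAAA"}, "A1")
        with pytest.raises(BoundaryError):
            left_normalize(Variant("A1", "c", 1, "AA", "A"), genome)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_random_variants_normalize_correctly(self, seed):
        """Equivalence, idempotence and left-most minimality on repeat-rich
        contigs, checked against exhaustive enumeration."""
        rng = random.Random(seed)
        genome = ReferenceGenome({"r": random_repeat_reference(rng)}, "A1")
        v = random_variant(rng, genome, "r")
        try:
            n = left_normalize(v, genome)
        except BoundaryError:
            # a repeat tract reaching the contig start: contractually an error
            assume(False)
        assert apply_variant(n, genome) == apply_variant(v, genome)
        assert left_normalize(n, genome) == n
        # minimality: no shared suffix; no prefix trimmable under len>=2 rule
        assert not (len(n.ref) > 1 or len(n.alt) > 1) or n.ref[-1] != n.alt[-1]
        assert not (
            len(n.ref) >= 2 and len(n.alt) >= 2 and n.ref[0] == n.alt[0]
        )
        assert n == leftmost_minimal(equivalent_representations(v, genome))


class TestConvertAssembly:
    def test_identity_when_assembly_matches_target(self, toy_ref):
        v = Variant("ToyRef-1", "T", 3, "G", "T")
        assert convert_assembly(v, IdentityAssemblyMap("ToyRef-1")) == v

    def test_offset_map_shifts_and_reverifies(self, tmp_path):
        target = ReferenceGenome({"c": "NNNNNNNNNN" + TOY_SEQ}, "B2")
        map_file = tmp_path / "map.txt"
        map_file.write_text("# src interval -> +10\nc\t1\t100\t10\n")
        mapping = OffsetIntervalMap.from_file(map_file, source="A1", target="B2")
        v = Variant("A1", "c", 3, "G", "T")
        out = convert_assembly(v, mapping, target)
        assert (out.assembly, out.pos) == ("B2", 13)

    def test_position_outside_intervals_unmappable(self):
        mapping = OffsetIntervalMap([("c", 1, 5, 10)], source="A1", target="B2")
        with pytest.raises(UnmappableVariantError):
            convert_assembly(Variant("A1", "c", 9, "G", "T"), mapping)

    def test_missing_provider_for_pair(self):
        mapping = OffsetIntervalMap([("c", 1, 5, 10)], source="A1", target="B2")
        with pytest.raises(UnsupportedConversionError):
            convert_assembly(Variant("XX", "c", 2, "G", "T"), mapping)


class TestValidateSubmission:
    def submission(self, **overrides):
        doc = {
            "owner": "lab-1",
            "assembly": "ToyRef-1",
            "variants": [
                {"chrom": "chrT", "pos": 3, "ref": "G", "alt": "T"},
                {"chrom": "chrT", "pos": 5, "ref": "A", "alt": "C"},
            ],
            "hgvs": ["NM_1:c.5A>T"],
            "hpo_terms": ["T:b"],
        }
        doc.update(overrides)
        return doc

    def test_partition_of_accepted_and_rejected(self, chain5):
        ont, _ = chain5
        result = validate_submission(self.submission(), ont, ["ToyRef-1"])
        assert len(result.accepted) == 2
        assert len(result.rejected) == 1  # the c.-level HGVS string
        assert result.profile_ok and result.assembly_ok and result.ok

    def test_missing_phenotype_rejects_submission(self, chain5):
        ont, _ = chain5
        result = validate_submission(
            self.submission(hpo_terms=[]), ont, ["ToyRef-1"]
        )
        assert not result.profile_ok and not result.ok

    def test_missing_assembly_rejects_submission(self, chain5):
        ont, _ = chain5
        result = validate_submission(
            self.submission(assembly=None), ont, ["ToyRef-1"]
        )
        assert not result.assembly_ok and not result.ok

    def test_unknown_terms_are_traced_not_fatal(self, chain5):
        ont, _ = chain5
        result = validate_submission(
            self.submission(hpo_terms=["T:b", "T:nonsense"]), ont, ["ToyRef-1"]
        )
        assert result.profile_ok
        assert ("T:nonsense", "unknown or obsolete phenotype term") in result.term_issues
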