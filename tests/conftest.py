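import io
import random

import pytest

from casewatch.annotation import read_gff3
from casewatch.fixtures import (
    GenomeSpec,
    OntologySpec,
    generate_mini_ontology,
    generate_toy_genome,
)
from casewatch.ontology import parse_obo, precompute_path_cache
from casewatch.variants import ReferenceGenome

# The toy contig used throughout the normalization examples: a CA-repeat
# tract embedded in G/C context, where deletions famously have several
# equivalent right-shifted representations.
TOY_SEQ = "GGGCACACACG"


def obo_from_edges(edges: dict[str, list[str]], extra: str = "") -> str:
    """Build OBO text from a term -> parents mapping."""
    lines = ["format-version: 1.2", "ontology: test-fixture", ""]
    for term in sorted(edges):
        lines += ["[Term]", f"id: {term}", f"name: {term}"]
        lines += [f"is_a: {p}" for p in edges[term]]
        lines.append("")
    return "\n".join(lines) + "\n" + extra


@pytest.fixture(scope="session")
def toy_ref():
    return ReferenceGenome({"chrT": TOY_SEQ}, "ToyRef-1")


@pytest.fixture(scope="session")
def chain5():
    """r -> a -> b -> c -> d chain plus its path cache."""
    obo = obo_from_edges(
        {"T:r": [], "T:a": ["T:r"], "T:b": ["T:a"], "T:c": ["T:b"], "T:d": ["T:c"]}
    )
    ont = parse_obo(io.StringIO(obo))
    return ont, precompute_path_cache(ont)


@pytest.fixture(scope="session")
def chain_sibling():
    """Chain r -> a -> b with a second child b2 under a."""
    obo = obo_from_edges(
        {"T:r": [], "T:a": ["T:r"], "T:b": ["T:a"], "T:b2": ["T:a"]}
    )
    ont = parse_obo(io.StringIO(obo))
    return ont, precompute_path_cache(ont)


@pytest.fixture(scope="session")
def diamond():
    """c has two parents a and b, both children of the root."""
    obo = obo_from_edges(
        {"T:r": [], "T:a": ["T:r"], "T:b": ["T:r"], "T:c": ["T:a", "T:b"]}
    )
    ont = parse_obo(io.StringIO(obo))
    return ont, precompute_path_cache(ont)


@pytest.fixture(scope="session")
def toy_world(tmp_path_factory):
    """A parsed synthetic world: ontology + cache + genome + gene models."""
    base = tmp_path_factory.mktemp("world")
    obo, _ = generate_mini_ontology(
        OntologySpec(depth=4, branching=2, multi_parent_fraction=0.15), seed=42
    )
    fasta, gff = generate_toy_genome(
        GenomeSpec(n_chroms=2, chrom_length=5000, n_genes=16), seed=42
    )
    (base / "ontology.obo").write_text(obo)
    (base / "genome.fa").write_text(fasta)
    (base / "models.gff3").write_text(gff)
    ontology = parse_obo(str(base / "ontology.obo"))
    cache = precompute_path_cache(ontology)
    ref_genome = ReferenceGenome.from_fasta(base / "genome.fa", "ToyRef-1")
    models = read_gff3(base / "models.gff3")
    return {
        "dir": base,
        "ontology": ontology,
        "cache": cache,
        "ref_genome": ref_genome,
        "models": models,
    }


def make_watchlist(world, **kwargs):
    from casewatch.watchlist import LogicalClock, WatchList

    kwargs.setdefault("clock", LogicalClock())
    return WatchList(
        world["ontology"],
        world["cache"],
        world["ref_genome"],
        world["models"],
        **kwargs,
    )


def random_repeat_reference(rng: random.Random, length: int = 120) -> str:
    """A repeat-rich toy contig: random bases with interleaved short tandem
    repeat tracts, the worst case for indel normalization."""
    pieces = []
    while sum(len(p) for p in pieces) < length:
        if rng.random() < 0.5:
            unit = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
            pieces.append(unit * rng.randint(3, 6))
        else:
            pieces.append("".join(rng.choice("ACGT") for _ in range(rng.randint(3, 8))))
    return "".join(pieces)[:length]


def random_variant(rng: random.Random, genome: ReferenceGenome, chrom: str):
    """A random SNV/insertion/deletion placed somewhere on the contig."""
    from casewatch.variants import Variant

    seq = genome.sequences[chrom]
    kind = rng.choice(["snv", "ins", "del", "delins"])
    pos = rng.randint(2, len(seq) - 12)
    if kind == "snv":
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
    elif kind == "ins":
        ref = seq[pos - 1]
        alt = ref + "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
    elif kind == "del":
        n = rng.randint(1, 5)
        ref = seq[pos - 1 : pos + n]
        alt = ref[0]
    else:
        n = rng.randint(1, 4)
        ref = seq[pos - 1 : pos - 1 + n]
        alt = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
        if alt == ref:
            alt = ref + "T"
    return Variant(genome.assembly, chrom, pos, ref, alt)
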