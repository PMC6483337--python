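"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
path enumeration via networkx simple-path search, similarity by exhaustive
pairwise Jaccard over those paths, normalization by enumerating every
equivalent variant representation in a window, and coding consequences by
physically splicing and translating the CDS.
"""

from __future__ import annotations

import networkx as nx
from Bio.Seq import Seq

from casewatch.variants import ReferenceGenome, Variant


def brute_force_root_paths(ontology, term_id: str) -> set[frozenset[str]]:
    g = nx.DiGraph()
    for t in ontology.live_terms():
        g.add_node(t.id)
        for p in t.parent_ids:
            g.add_edge(t.id, p)
    if term_id == ontology.root_id:
        return {frozenset({term_id})}
    return {
        frozenset(path)
        for path in nx.all_simple_paths(g, term_id, ontology.root_id)
    }


def brute_force_term_similarity(ontology, c: str, c2: str) -> float:
    paths_c = brute_force_root_paths(ontology, c)
    paths_c2 = brute_force_root_paths(ontology, c2)
    return max(
        len(p & p2) / len(p | p2) for p in paths_c for p2 in paths_c2
    )


def equivalent_representations(v: Variant, genome: ReferenceGenome) -> list[Variant]:
    """Every valid VCF-style representation of the same edit, exhaustively.

    A representation (pos, ref, alt) is equivalent iff applying it to the
    reference yields the same mutated sequence.  Any such representation
    must leave the sequence before ``pos`` untouched, so candidate positions
    are bounded by the first base where reference and mutated sequence
    diverge; ref lengths run to the end of the contig.  Alleles must be
    non-empty and distinct.
    """
    seq = genome.sequences[v.chrom]
    mutated = seq[: v.pos - 1] + v.alt + seq[v.end :]
    delta = len(mutated) - len(seq)
    first_diff = 0
    limit = min(len(seq), len(mutated))
    while first_diff < limit and seq[first_diff] == mutated[first_diff]:
        first_diff += 1
    out = []
    for pos in range(1, min(first_diff + 1, len(seq)) + 1):
        for ref_len in range(1, len(seq) - pos + 2):
            alt_len = ref_len + delta
            if alt_len < 1:
                continue
            ref = seq[pos - 1 : pos - 1 + ref_len]
            alt = mutated[pos - 1 : pos - 1 + alt_len]
            if ref == alt:
                continue
            if mutated == seq[: pos - 1] + alt + seq[pos - 1 + ref_len :]:
                out.append(Variant(v.assembly, v.chrom, pos, ref, alt))
    return out


def leftmost_minimal(representations: list[Variant]) -> Variant:
    """The shortest representation; among equally short ones, the left-most."""
    return min(representations, key=lambda r: (len(r.ref) + len(r.alt), r.pos))


def spliced_consequence_oracle(tx, v: Variant, genome: ReferenceGenome) -> str:
    """Consequence of a CDS SNV by splicing and translating the whole CDS."""
    positions = tx.cds_positions()
    assert v.is_snv and v.pos in positions

    def fetch(mutate: bool) -> str:
        bases = []
        for p in positions:
            b = genome.base(tx.chrom, p)
            if mutate and p == v.pos:
                b = v.alt
            bases.append(b if tx.strand == "+" else str(Seq(b).complement()))
        return "".join(bases)

    aa_ref = str(Seq(fetch(False)).translate())
    aa_alt = str(Seq(fetch(True)).translate())
    idx = positions.index(v.pos) // 3
    if aa_ref[idx] == aa_alt[idx]:
        return "synonymous_variant"
    if idx == 0 and aa_ref[idx] == "M":
        return "start_lost"
    if aa_ref[idx] == "*":
        return "stop_lost"
    if aa_alt[idx] == "*":
        return "stop_gained"
    return "missense_variant"


def random_dag_obo(rng, n_nodes: int) -> str:
    """OBO text for a random rooted DAG: node i picks 1-2 parents among
    earlier nodes, so the graph is acyclic with node 0 the unique root."""
    lines = ["format-version: 1.2", "ontology: random-dag", ""]
    for i in range(n_nodes):
        lines += ["[Term]", f"id: D:{i:04d}", f"name: node {i}"]
        if i > 0:
            n_parents = 2 if (i > 1 and rng.random() < 0.25) else 1
            for p in rng.sample(range(i), n_parents):
                lines.append(f"is_a: D:{p:04d}")
        lines.append("")
    return "\n".join(lines)
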