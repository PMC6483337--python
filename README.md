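# casewatch

A local, offline **watch list** for rare-disease case matching. Diagnostic
labs sequencing patients with suspected monogenic disease routinely end up
with "in limbo" candidate variants — plausible but unconfirmed. The classic
way to firm up such a candidate is to find an independent patient with the
same (or a genomically close) variant and a similar phenotype. Public
matchmaking platforms do this at global scale, but consortia that cannot (or
may not) export genetic data need the same machinery under their own roof.

`casewatch` is that machinery as a library plus CLI: a persistent list of
cases (candidate variants + [HPO](https://hpo.jax.org/) phenotype terms)
that is never queried directly. Instead, every new submission is validated,
left-normalized, locally annotated, checked against a known-variant store
(beacon-style yes/no), filtered, and then matched against every earlier
case; both the submitter and the owners of the matching cases receive a
report ("give and take" — the list grows with every use).

## The matching model

**Genomic axis.** Candidate variant pairs are binned into four proximity
categories, ranked strongest first:

1. `IDENTICAL` — same (chrom, pos, ref, alt) after left normalization,
2. `SAME_POSITION` — same position, different allele,
3. `SAME_CODON` — a shared transcript assigns both variants the same codon ordinal,
4. `SAME_GENE` — overlapping gene annotation.

**Phenotype axis.** Within a category, matches are ordered by a path-based
HPO similarity. With P(c, r) the set of all directed `is_a` paths from term
c to the ontology root r (each path a node set including both endpoints):

```
sim(c, c')  =  max over p ∈ P(c,r), p' ∈ P(c',r)  of  |p ∩ p'| / |p ∪ p'|
```

and for two phenotype profiles d, d' (sets of terms), the symmetrised
best-match average:

```
sim(d, d')  =  1/(2|d|)  Σ_{c∈d}  max_{c'∈d'} sim(c, c')
            +  1/(2|d'|) Σ_{c'∈d'} max_{c∈d}  sim(c, c')
```

Because paths lengthen with depth, this rewards precise (deep-rooted)
annotations: on a 5-term chain, a parent/child pair at the bottom scores
4/5 while the root and its child score only 1/2. All root paths are
pre-computed once per ontology release and cached, so a similarity
evaluation is a handful of set operations.

The ranked candidate list is pruned to a configurable number of top hits
(default 5). Category always dominates: a same-gene hit with phenotype
similarity 0.99 never outranks an identical variant with similarity 0.10.

Everything runs locally: VCF / genomic HGVS / generic-JSON variant input,
FASTA reference, GFF3 gene models, OBO ontology, and a VCF known-variant
store standing in for the beacon network. No network access is required.

## Worked example

Generate a self-contained synthetic bundle (toy ontology, genome, gene
models and a 6-case cohort with one planted identical-variant pair),
initialize the store, and submit the planted pair:

```bash
casewatch fixtures --out demo --seed 11 --n-cases 6 --plant IDENTICAL > demo/manifest.json
casewatch init --config demo/config.yaml
# initialized: 35 root paths cached for 31 terms; 0 cases

casewatch submit --config demo/config.yaml demo/submissions/case000.json
# case_id  CW000001
# status   PROCESSED
# rank  category  similarity  query_variant  hit_variant  hit_case  owner  same_owner

casewatch submit --config demo/config.yaml demo/submissions/case004.json
# case_id  CW000002
# status   PROCESSED
# rank  category   similarity  query_variant  hit_variant  hit_case  owner    same_owner
# 1     IDENTICAL  1.000000    1:1061:G>T     1:1061:G>T   CW000001  user-00  no
```

The second submission carries the same missense variant (`chr1:1061 G>T`,
gene2) and an identical phenotype profile, so it matches the first case at
the strongest category with phenotype similarity 1.0 — and the owner of
`CW000001` receives the mirror-image report. `casewatch status` then shows
the first case's variant with `"match_count": 1`; `casewatch retract`
withdraws a case from all future matching, and `casewatch export` dumps the
store as JSON-lines (plus optionally a site-only VCF).

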