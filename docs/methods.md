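# Methods

## Case model

A *case* is one patient's set of candidate ("in limbo") variants plus a
phenotype profile of at least one HPO term; mode of inheritance and age of
onset are optional metadata. Variants are stored in a VCF-like minimal
representation (assembly label, chromosome, 1-based position, non-empty
uppercase ref/alt with a left anchor base for indels). All coordinates in
the package are 1-based inclusive — VCF, GFF3 and genomic HGVS all speak
that dialect, and keeping a single convention internally removes the most
common class of off-by-one bugs.

## Submission pipeline

Each submission passes a fixed stage sequence:
**validate → extract → convert assembly → left-normalize → annotate →
beacon-check → filter → match**. Only validation can fail a submission as a
whole (no resolvable phenotype term, no declared/accepted assembly, no valid
variant source); every later stage records per-variant failures in a
processing trace and carries on. The trace is the submitter's to-do list:
every input variant is either annotated-and-stored or traced with a reason.

Two ordering choices deserve a note:

* **Conversion before normalization.** Minimality is only meaningful
  against a specific reference, and the engine ships exactly one (the
  target assembly). Converting first means a single normalization pass
  against the target genome, with the ref allele re-verified after
  remapping. The end state is identical: all stored variants are minimal on
  the target assembly.
* **Multi-allelic VCF rows are split before normalization** (standard
  practice); each ALT allele becomes an independent variant.

Assembly conversion is a provider interface. Shipped providers are the
identity map and an interval+offset map loadable from 4-column text, which
covers fixture-scale conversions; a chain-file liftover can implement the
same two-method protocol without touching the pipeline.

HGVS support is deliberately genomic-only (`g.` substitution, del, dup, ins,
delins with explicit coordinates). Coding/protein descriptions require
transcript projection against a full annotation source; submissions carrying
them are traced as unsupported rather than guessed at.

## Left normalization

The normalizer implements the standard two-phase algorithm: repeatedly strip
identical terminal bases (re-anchoring one reference base to the left
whenever an allele would empty), then trim identical leading bases while
both alleles keep length ≥ 2. The result provably (a) applies to the
reference identically to the input, (b) is idempotent, and (c) is the
left-most among the shortest equivalent representations. The test suite
checks all three against an oracle that enumerates *every* equivalent
representation — candidate start positions are bounded by the first base at
which reference and mutated sequence diverge, which no valid representation
can start after, so the enumeration is exhaustive rather than windowed.
A variant whose normalization would walk past the 5′ end of the contig is a
boundary error (traced), not silently clamped.

## Local annotation

Annotation is a minimal deterministic effect caller over GFF3 gene models
and the reference FASTA, covering exactly what codon-level matching needs:

* region per overlapping transcript (CDS / UTR / intron / upstream /
  downstream within 1 kb / intergenic);
* for CDS substitutions, the affected codon is located by coding offset
  (ordinal = offset//3 + 1 counted 5′→3′ in transcript orientation, so
  minus-strand codon 1 sits at the genomic right), translated before and
  after with the standard genetic code, and classified as synonymous /
  missense / stop_gained / stop_lost / start_lost;
* CDS indels: frameshift if the length change is not a multiple of 3, else
  in-frame; the codon ordinal is attached only when the event lies fully
  inside one codon;
* impact classes: HIGH = {stop_gained, stop_lost, start_lost, frameshift},
  MODERATE = {missense, inframe indel}, LOW = {synonymous},
  MODIFIER = all non-coding.

Splice sites are deliberately not modeled (intronic positions are plain
MODIFIER), and there are no regulatory features or pathogenicity scores —
this annotator exists to make matching decidable, not to replace a full
effect predictor. Canonical transcripts are read from a `canonical=1`-style
attribute, defaulting to the longest-CDS transcript per gene.

Correctness of the codon machinery is checked against an independent oracle
that physically splices the CDS, reverse-complements where needed, mutates
and translates — for every possible CDS substitution of a forward and a
reverse gene.

## Filters

A variant enters matching iff its population allele frequency is unknown or
≤ `max_maf` *and* at least one transcript hit has impact ≥ `min_impact`,
optionally restricted to protein-coding and/or canonical transcripts.
Defaults: `max_maf = 0.01`, `min_impact = MODERATE`,
`require_protein_coding = false`, `canonical_only = false`. The MODERATE
default encodes one reading of "predicted deleterious effect" (missense and
worse); it is a configuration choice, not a claim about ground truth, and
filters are monotone by construction (lowering `min_impact` or raising
`max_maf` never removes a passing variant — property-tested). An unknown
MAF passes: absence of evidence does not exclude a candidate. Failing
variants stay on the case (visible in status output) but are dropped from
matching consideration, with the reason traced.

The beacon check is an exact-tuple membership test against a local
known-variant store (a VCF normalized with the same normalizer at load
time). A hit flags the variant and informs the submitter that the allele
has been publicized before, but does **not** remove it from matching — the
flag is information, policy is the operator's.

## Phenotype similarity

Root paths are enumerated per term by memoized DFS over `is_a` edges only
(`part_of` and other relationships are ignored, as is conventional for HPO
similarity); paths are node *sets* including both the term and the root, and
two paths equal as sets count once. The root's path set is {{root}}, which
together with the set semantics forces sim(c, c) = 1. Obsolete terms carry
no parents and are excluded; submitted obsolete/alias accessions are
redirected via `replaced_by`/`alt_id` when possible and otherwise rejected
into the trace at validation. A configurable per-term path cap (default
10,000) turns combinatorial blow-up in pathological DAGs into a loud error;
real phenotype ontologies sit orders of magnitude below it.

Term similarity is the best Jaccard index over all path pairs; case
similarity is the symmetrised best-match average over the two profiles
(equations in the README). Both are symmetric, identity-1 and bounded to
[0, 1]; the cached computation is tested for *exact* equality against
brute-force path enumeration (via networkx simple-path search) on random
DAGs. The cache serializes to JSON deterministically and is rebuilt per
ontology release (`casewatch init`).

## Matching and reporting

Candidates are all filter-passing variant pairs between the query case and
every other PROCESSED, non-retracted case. Category is computed per pair;
"same codon" means *some transcript hit by both variants assigns equal
codon ordinals* (the source material does not fix which transcript; any
shared one is accepted). At most one record survives per (query variant,
hit case) — the lowest category rank — so a single case cannot monopolize
the top hits with many weak pairs. Case-level phenotype similarity is
computed once per case pair and attached to all of that pair's records.

The global sort key is (category rank ↑, phenotype similarity ↓, hit-case
submission time ↑, hit-case id ↑) — fully deterministic — and the list is
truncated to `top_n` (default 5) *after* the global sort; there are no
per-category quotas. Reports fan out to both sides: the submitter gets all
matches, each distinct hit-case owner gets the records involving their
cases with the roles swapped. Self-matches are excluded at case level;
matches between two cases of the same submitter are allowed and flagged
`same_owner` (useful as internal quality control).

## Persistence, determinism, identifiers

The store is a JSON-lines file (one case per line, sorted keys), suitable
for the single-operator deployment this engine targets; concurrent writers
are out of scope. Matching triggers on submission; `rescan` re-runs it
after configuration or ontology changes. Case ids are sequential
zero-padded (`CW000001`): sortable, unique, and — unlike time/randomness
based ids — replay-stable, which makes "same submission script ⇒
byte-identical store and reports" a testable guarantee. Timestamps come
from an injectable clock (wall clock by default, a deterministic logical
clock in tests and the acceptance script).

## Synthetic fixtures: what they do and do not show

The generators produce, deterministically from a seed:

* **Ontologies** — a complete tree of configurable depth/branching (default
  depth 4, branching 2 → 31 terms) with a configurable fraction of terms
  receiving a second, strictly shallower parent (default 0.15 in tests),
  creating genuine multi-path structure.
* **Genomes** — 1–3-exon genes with ATG-initiated, stop-free,
  stop-terminated CDS (10–16 codons), short UTRs, mixed strands,
  non-overlapping slots, plus a CA tandem-repeat tract on chromosome 1 for
  normalization stress.
* **Cohorts** — case pairs planted to realize an exact proximity category
  (variant alleles chosen by scanning the codon table for filter-passing
  missense/nonsense changes) and a phenotype-overlap bracket: *high* =
  identical profiles, *medium* = siblings under the deepest shared parent,
  *low* = deep terms with minimal shared ancestry. Overlap brackets are
  validated as an ordering (high > medium > low), never as exact values.
  Each planted pair and each filler case gets a private gene, so fillers
  are category-`none` against everything by construction.

Cohorts in the acceptance checks use 20–30 cases over 16–26 genes on 2
chromosomes of 4–8 kb — sizes chosen so every check is exhaustive and runs
in seconds. What passing shows: the pipeline's bookkeeping, the matching
algebra, ranking, pruning, reporting symmetry and determinism are correct.
What it does not show: behavior on realistic allele-frequency spectra,
splice-mediated effects, annotation ambiguity of overlapping real genes, or
phenotype noise in clinical HPO coding — fixtures are structural, not
biological.

## Known limitations

* No coding/protein HGVS projection, no structural variants, no VCF
  genotype columns (site fields only).
* No splice-site consequences; intronic = MODIFIER.
* The known-variant store is a local stand-in for a beacon network; a real
  beacon client can implement the same provider interface.
* Single-operator trust model: no authentication, no multi-tenant user
  management, no notification delivery.
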