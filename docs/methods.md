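# Methods

## Problem and model

`metlink` asks a single statistical question: do the genes whose protein
products interact with a study's enriched metabolites overlap the genes
implicated by published GWAS for a phenotype more than chance would allow?
Because the metabolomics cohort and the GWAS cohorts are independent, no
subject-level model is possible; the unit of inference is the gene set,
and the only distributional assumption is the hypergeometric one — that
under the null the metabolite-interacting genes are an exchangeable draw
from the shared background.

That background (the *discoverable gene universe*) is the restriction of
all catalog genes to those with annotated metabolite interactions. Using
it on **both** sides is what makes the test coherent: genes that could
never appear in a metabolite mapping are excluded from the population, so
they cannot dilute or inflate the overlap.

## Study-trait nodes

Node identity is the triple (PubMed id, study title, reported trait)
rather than study+trait alone: one publication can report several
sub-studies under one PubMed id, and the triple is conservative about
keeping them distinct. A node's gene set is the union of its rows' mapped
genes. Gene fields are tokenised on the catalog's intergenic separator
`" - "` (with flanking spaces, so hyphenated symbols like `HLA-B`
survive) and on `,`/`;`; placeholder tokens (`NR`, `intergenic`) are
dropped and symbols uppercased, since HGNC symbols are case-insensitive
across the databases involved. Which column feeds the nodes
(`MAPPED_GENE` by default, `REPORTED GENE(S)` optionally) is a
`CatalogDialect` field, as is every separator and placeholder — the
catalog export format is a convention, not a standard.

## Edge statistics

For nodes with gene sets A, B ⊆ U:

- Jaccard coefficient J = |A∩B| / |A∪B| (0 when both empty);
- p-value = P[X ≥ |A∩B|], X ~ Hypergeom(N=|U|, K=|A|, n=|B|), the
  probability of the observed overlap if B were drawn uniformly without
  replacement from U. The statistic is symmetric in A and B, and the
  one-sided Fisher exact test on the same 2×2 table would give the same
  number.

Conditioning on the discoverable universe (rather than, say, |A∪B|) is a
modelling choice; the network JSON and every run report embed the
universe digest so a result always declares its convention.

Benjamini–Hochberg runs over the **full** vector of all C(m,2) pairwise
p-values, not only over pairs that pass the Jaccard threshold: the two
criteria are independent, and adjusting within a Jaccard-selected subset
would bias q-values toward significance. An edge is retained when
J ≥ `jaccard_min` (default 0.5) and q ≤ `q_max` (default 0.05). The
Jaccard default is deliberately strict — halving it quickly inflates the
network with weakly related studies, and every downstream gene count is
threshold-sensitive. Both retained-edge criteria are anti-monotone:
tightening either threshold can only remove edges.

## Keyword subnetworks

Primary nodes contain the keyword (or any member of an OR-list) as a
case-insensitive literal substring of the study title or the trait; no
stemming or synonym expansion is attempted. Neighbour expansion is
strictly first-degree across retained edges — neighbours of neighbours do
not join — and a node that both matches the keyword and neighbours
another primary node counts as primary, keeping the two sets disjoint.
An empty match is a warned-about empty subnetwork, not an error. The
subnetwork's gene set is the union over primary and neighbour nodes.

## The over-representation test

Roles in the 2×2 layout: population N = discoverable universe; successes
K = subnetwork genes; draw n = metabolite-interacting genes; observed
successes k = the overlap. The p-value is the inclusive upper tail
P[X ≥ k], computed through `scipy.stats.hypergeom.sf` (log-space stable,
exact to double precision at these counts). A single (pathway, keyword)
pair is a single test and carries no correction; batch runs over several
pathways or keywords report each test independently and the caller owns
any multiplicity adjustment. Symbols outside the universe are dropped
with a loud log rather than raised on: symbol vintages drift between
metabolite-annotation and catalog snapshots, and mixed vintages are the
common case, but silent drops would corrupt counts — hence the warning.
Because the test statistic is discrete, the test is conservative:
P(p ≤ α) ≤ α under the null, which the test suite verifies empirically.

## Mapping providers

Pathway→metabolites, metabolite→proteins and protein→gene lookups sit
behind a three-method provider interface. The default
`TableMappingProvider` reads two-column snapshot TSVs; correctness never
depends on network access, and unknown identifiers resolve to empty sets
by contract. Proteins without a current human gene symbol are dropped and
counted (only human genes are meaningful against a human GWAS catalog).
`restrict_to_study` defaults to on: a pathway's gene set is built from
the pathway members the study actually measured, with the all-members
reading one flag away.

## Synthetic benchmark

The generator emulates the statistical structure the method relies on,
at desk scale. Defaults (the benchmark conditions): a 300-symbol
universe; a planted cluster of 5 studies, each with 12 genes of which
⌈0.8·12⌉ = 10 are a shared core (pairwise J = 10/14 ≈ 0.71); 20
background studies drawing 12 genes from a pool disjoint from the
cluster; the anchor keyword planted in exactly one cluster study's
trait; and an enriched pathway (FDR 0.01, against a null pathway at 0.5)
whose metabolites map to 9 cluster-core genes plus 3 filler genes seen
nowhere else. `genes_per_node = 12` is the smallest round value whose
0.8-overlap core can hold the 9 planted genes. The universe is
partitioned into disjoint blocks (core, per-study private, filler,
background pool), which makes the end-to-end identity exact: the
pipeline must report k = `planted_metabolite_gene_overlap`, and does, at
every seed. Each emitter consumes its own stream split from the master
seed, so changing the background never perturbs the cluster, and all
emitters are pure functions of the spec.

What the benchmark does *not* emulate: realistic trait vocabularies
(keyword matching is exercised only by the planted term), overlapping
background studies, SNP coordinates or p-value columns, gene-symbol
drift between sources, and the heavy-tailed size distribution of real
catalog studies. Passing tests therefore establish the pipeline's
mechanics and statistics, not recall on real catalog data; reproducing
the published case studies additionally needs the pinned December-2019
catalog snapshot and matching metabolite-mapping tables, which are too
large to ship here (the corresponding test states exactly which files it
expects under `data/dec2019_snapshot/`).

## Numerical and degenerate-input choices

- Hypergeometric tails via the survival function; k = 0 short-circuits
  to exactly 1.0.
- `jaccard(∅, ∅) = 0`, and a network with fewer than two nodes has an
  empty edge set — both are defined results, not errors; parameter-bound
  violations in the tail function raise naming the offending parameter.
- Deterministic ordering everywhere: nodes by id (a hash of the identity
  triple), edges by endpoint pair, ORA overlaps sorted — reruns on
  identical inputs are byte-identical.
- Row-level oddities are dropped-and-counted, never fatal: catalog rows
  without a PubMed id, name_map rows without any identifier, proteins
  without a gene symbol, symbols outside the universe.

## Problem sizes used in the checks

The shipped verification runs at desk scale: enumeration oracles cover
every hypergeometric instance with N ≤ 12 and Jaccard over all subset
pairs of a 6-element universe; the null calibration uses 10,000 draws
from a 60-gene universe; planted-cluster recovery runs the full pipeline
at 21 seeds of the default 25-node benchmark. The acceptance script
re-runs the default benchmark and a 5,000-replicate calibration.

## Known limitations

- Substring keyword matching confounds phenotypes that contain other
  phenotypes' names; choose keywords accordingly.
- The all-pairs edge computation is O(m²) in nodes; a full catalog build
  is a one-time cost whose product should be serialised and reused.
- Gene-level analysis cannot see regulatory variants acting on genes
  whose products do not touch the metabolite, nor distinguish direction
  of effect; up- and down-regulated metabolite sets should be run
  separately if that distinction matters.
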