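# Methods

`variantkg` turns per-patient variant calls into a queryable RDF
knowledge graph and then into homogeneous graphs for node
classification. This note records the models, the defaults that matter,
the synthetic benchmark's design, and the numerical choices — in the
order data flows through the tool.

## Knowledge-graph model

Each patient is identified by an SRA/ENA-style run accession and owns
one RDF **named graph** `sg://<accession>`. Within it, every VCF data
line becomes a subject IRI `origin://<md5>@<k>`, where the digest is
the MD5 of the source VCF's bytes and `k` is the 0-based data-line
index (after multi-allelic splitting, one record per alternate allele;
INFO values are not re-apportioned per allele). Genomic position uses
the FALDO vocabulary (`faldo:reference`, `faldo:position`); alleles are
IRIs in a sequence namespace; INFO keys map to canonical predicate
names (`AF → ALLELE_FREQUENCY`, `MQ → RMS_MAPPING_QUALITY`, …, unknown
keys pass through upper-cased) under `sg://0.99.11/vcf2rdf/info/`. The
version segment `0.99.11` is frozen: the downstream extraction query
hard-codes it. Patient metadata attaches to the same named graph with
Wikidata predicates (age is Q11904283; the other field mappings are
editable placeholders in `rdfize.DEFAULT_PREDICATE_MAP`).

CADD deleteriousness scores live in the **default graph** as Turtle:
one `http://sg.org/<accession>/<chrom>/variant<k>` node per score row
(`k` counts rows per chromosome within an accession, 1-based) with
`has_pos` / `has_ref_genome` / `has_alt_genome` and a child `…/cadd`
node carrying `has_raw_score` and `has_phred`. We use the
`has_raw_score` / `has_phred` property names the extraction query
consumes (an alternative naming without the `has_` prefix exists for
the same concepts; the query is the consumer, so it wins).

The store is an embedded rdflib `Dataset` rather than a graph-database
server: identical query contract, no deployment, set semantics on
reload. Feature extraction evaluates the extraction query's plan
directly over the dataset (mandatory patterns: chromosome, position,
REF, ALT, QUAL, ANN — a variant without an ANN annotation is not a
row; OPTIONAL bindings become empty strings; `variant_id` is the
string `"None"` when the VCF had `.`). The CADD join matches on
(accession, position, ref base, alt base), with the sequence-namespace
prefix stripped from allele IRIs, scoped to the row's own accession —
cross-patient score reuse is deliberately not assumed. A SPARQL-text
path over the same dataset exists for cross-checking on small inputs;
the direct plan is the production path. Rows are ordered by
`variant_id` with `(accession_id, origin)` as deterministic tiebreaks,
since `variant_id` alone is almost always the constant `"None"`.

Numeric cells keep their literal lexical forms (decimal strings) end to
end; typing happens only in graph construction. One caveat: rdflib
normalizes `xsd:float` lexical forms (`"108"` → `"108.0"`), so
float-typed columns (QUAL, the CADD scores) are value-preserving, not
byte-preserving; string columns are bit-exact.

## Learning graph

Nodes are feature-table rows — the same genomic variant observed in two
patients is two nodes. Default edges connect every unordered pair of
nodes sharing a gene name (taken from the 4th field of the first ANN
annotation), i.e. a clique per gene, oriented low-id→high-id with the
reverse edge added when bidirectional (the default); the alternative is
a fully connected graph. Cliques connect across patients — gene
membership, not patient identity, is the relation. Edge weights:
constant 1 (default), the in-degree of the destination, or a
user-supplied value. Self-loops are appended (weight 1) by default;
they stabilize degree normalization in graph convolution.

Categorical columns are integer-coded by first appearance ("None" for
missing) with the code books saved alongside the graph; numeric columns
are parsed as floats (missing → 0.0) and z-standardized by default —
raw genomic positions (~1e8) otherwise dominate every dot product and
destabilize full-batch training. Means and scales are stored, so
encoding is invertible. The raw comma-separated ANN text is never a
feature, and the label's source column is rejected as a feature
(`putative_impact` forbids `ann_split_1`; `cadd_category` forbids
`phred_score`).

Labels: `putative_impact` reads the impact tier (HIGH / MODERATE / LOW
/ MODIFIER) from the first annotation; `cadd_category` bins the PHRED
score at edges (10, 20, 30) — the conventional deleteriousness tiers,
configurable since no canonical binning exists. Rows lacking the label
source are dropped, not imputed. Splits come from a seeded uniform
permutation, default 80:10:10 (train:validation:test), sizes by floor.

## Architectures and training

All three models are implemented on a small reverse-mode automatic
differentiation engine over numpy (float32 working precision, the deep
learning default), with edge-list message passing expressed as
gather/segment-sum primitives backed by sparse-matrix products:

- **GCN** — stacked graph convolutions with symmetric degree
  normalization `1/√(d_src·d_dst)`, ReLU and dropout between layers.
- **GraphSAGE** — per layer `h' = ReLU(W_self·h + W_neigh·mean_N(h))`
  with a (weighted) mean neighbor aggregator.
- **Graph transformer** — multi-head dot-product attention restricted
  to graph neighbors (per-edge scores, softmax over each destination's
  incoming edges), residual connections, layer normalization, and a
  ReLU feed-forward block; edge weights multiply the unnormalized
  attention, acting as a soft adjacency.

Defaults: 2 message-passing layers, hidden width 16, 2 attention heads,
dropout 0.1, Adam with learning rate 0.001, 500 epochs, seeded Glorot
initialization. A `init="ones"` flag reproduces constant-1
initialization for fidelity experiments; it is not the default because
constant initialization cannot break symmetry between hidden units.
Training is full-batch (desk-scale graphs need no neighbor sampling),
with no early stopping; cross-entropy on train-mask nodes, per-epoch
validation loss/accuracy recorded, peak process memory logged as
information only. When no edge mask is being learned, GCN and GraphSAGE
aggregate through a constant sparse adjacency matrix — the
differentiable per-edge path is only engaged by the explainer.

Evaluation reports accuracy, per-class and macro/weighted precision,
recall, F1, support, and the confusion matrix (computed via
scikit-learn; the test suite checks them against a hand-counting
oracle).

## Explainer

For one node, the explainer extracts the k-hop subgraph (edges treated
as undirected for reachability, matching message flow on bidirectional
graphs) and learns sigmoid-parameterized masks over subgraph edges and
feature columns by Adam, minimizing cross-entropy between the model's
original prediction and its prediction under masking, plus L1 size
penalties and an entropy penalty pushing masks toward binary. Defaults:
200 epochs, learning rate 0.02, edge size penalty 0.005, feature size
penalty 0.3, entropy penalty 0.1. The feature size penalty is
deliberately strong, and the feature mask starts uniform (no random
jitter): with weak pressure all masks drift down together and the final
ranking just echoes initialization noise, whereas strong pressure
prunes every feature the prediction can survive without, leaving the
load-bearing ones ranked by mask weight. Global rankings average mask
weights across explained nodes.

Two properties of soft feature masking are worth knowing. First, a
sparsity-seeking explainer keeps a *minimal sufficient* feature set: if
two features encode the same signal (e.g. the CADD PHRED score and an
INFO field that both track deleteriousness), one of them is correctly
pruned as redundant — recovery benchmarks must plant a unique signal.
Second, soft-masking integer category codes creates values between
categories that the model never saw, which inflates those features'
apparent importance; the explainer is therefore most trustworthy on
continuous features, and the recovery benchmark uses numeric columns
only.

## Synthetic cohort generator

The generator emulates the output of an upstream variant-calling and
annotation pipeline for a multi-patient cohort: per patient one
annotated VCF (ANN in INFO), one CADD table aligned to it, plus one
shared metadata CSV. Defaults are the benchmark conditions used
throughout: 20 patients × 200 variants, 24 genes, impact priors
HIGH 0.15 / MODERATE 0.35 / LOW 0.25 / MODIFIER 0.25, signal strength
0.9, ages uniform on [20, 90] years, fixed seed ⇒ byte-identical files.

`signal_strength` s ∈ [0, 1] controls three planted effects, each
interpolating between "no information" (s = 0) and full separation
(s = 1):

- **PHRED scores** are class-conditional normals (sd 3) whose means
  spread over the 0–40 range (MODIFIER 4, LOW 13, MODERATE 23,
  HIGH 33) as s grows; the raw score is an affine function of PHRED
  plus noise.
- **One designated INFO feature** — QD, quality by depth — is
  class-informative the same way (means 4/12/22/30, sd 2.5). All other
  INFO fields are class-independent noise in plausible ranges.
- **Gene choice is class-tilted**: each impact class prefers its own
  quarter of the gene pool with probability s (uniform otherwise).
  This is the realistic analogue of deleterious variants clustering in
  disease genes, and it is what makes the *graph* informative: gene
  cliques average ~170 nodes, so a degree-normalized convolution
  dilutes any single node's own features to ~1/170 — without
  label-correlated structure, clique averaging would erase the planted
  per-node signal and no convolutional architecture could beat the
  majority class, leaving the graph stages untestable.

What the generator does **not** emulate: linkage structure, realistic
mutation spectra, the real CADD model, indels/MNPs, multi-sample VCFs,
or missing genotypes. Passing tests therefore demonstrate that the
pipeline machinery is correct and that planted statistical signal of a
known form is recovered — not that any particular accuracy is
attainable on real patient cohorts.

## Benchmark problem sizes

The shipped benchmark (acceptance script and end-to-end tests) uses the
20 × 200 cohort (4,000 nodes, ~700k directed edges after clique
construction), trains GCN and GraphSAGE for 200 epochs and the graph
transformer for 80 — enough for validation accuracy to plateau on this
cohort at a fraction of the 500-epoch default budget — and probes the
explainer on 15 correctly classified test nodes with 1-hop subgraphs.
The explainer benchmark's model is trained on continuous features
excluding the two CADD score columns, for the identifiability reasons
above.

## Degenerate inputs and tie-breaks

- A VCF line with `ALT = A,T` is an error unless multi-allelic
  splitting is enabled; splitting copies the full INFO map per allele.
- VCF `.` values: ID → absent (rendered `"None"` downstream), QUAL →
  absent.
- Age cells like `"65 (Age)"` parse by leading number.
- Variants sharing no gene are isolated nodes (self-loop only, if
  enabled); explaining an isolated node warns and returns a
  single-node explanation.
- Empty split masks (tiny n or extreme fractions) raise rather than
  silently producing an untestable graph.
- Attention softmax subtracts a detached per-destination maximum;
  means/variances in layer norm use ε = 1e-5; the mean aggregator
  guards empty neighborhoods with ε = 1e-9.

## Known limitations

- The quad store is desk-scale (in-memory rdflib); billion-statement
  cohorts need a real graph database behind the same contract.
- The SPARQL text path is slow on large datasets (rdflib's OPTIONAL
  chains); it exists as a cross-check, not a production path.
- Full-batch float32 training on CPU: graphs beyond ~10⁶ edges will
  want minibatching or hardware acceleration.
- Feature-mask explanations on categorical codes are qualitative at
  best (see above).
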