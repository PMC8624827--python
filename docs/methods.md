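# Methods

This note records the model behind `homolineage`, the parameters that
matter, what the simulator does and does not emulate, and the numerical
and design choices made where the design was genuinely open.

## The homology index

Each pairwise alignment is scored

    HI = min(1, 2 · (pident/100) · aln_len / (qlen + slen)) ∈ [0, 1]

— the count of identical aligned columns divided by the mean of the two
full sequence lengths. The normalisation makes HI coverage-aware: a
perfect alignment of a single shared domain in otherwise unrelated
proteins scores well below 1, while a full-length identical match
scores exactly 1. The `min` clamp guards the rare case of a gappy
alignment whose column count exceeds the mean length. The index is
deliberately computable from one `-outfmt '6 std qlen slen'` tabular
line so that precomputed BLAST output and the internal aligner are
interchangeable inputs.

Asymmetric or duplicated hits for one gene pair (both search
directions, multiple HSPs) collapse to the **maximum** HI: it keeps the
strongest homology evidence and is monotone under adding hits. Self-hits
are accepted on input (useful for validating external files) but never
stored in the graph.

The internal aligner is Biopython's `PairwiseAligner` with BLOSUM62 and
affine gap cost 11 + k for a gap of length k — the classical
protein-search defaults — in local mode by default, with a global mode
for data known to be free of indels and trimming artefacts. Pairs are
aligned in a canonical argument order so the HI is exactly symmetric
even when co-optimal alignments would tie-break differently. A local
alignment with no positive-scoring pair yields HI 0 and no tabular line,
like a search reporting no hit.

## Groups, charts, events

Grouping at threshold *t* means connected components of the HI ≥ *t*
subgraph — single linkage. No other linkage makes "grouping at a
threshold" and a nested lineage simultaneously well-defined: complete
or average linkage clusters are not unions of threshold components, and
nestedness across thresholds would fail. Sweeps evaluate **exact change
points** (the sorted distinct edge HIs plus the endpoints 0 and 1)
rather than a fixed grid, so no event can fall between grid lines; ties
in edge HI are absorbed automatically because a component at *t* uses
all edges with HI ≥ *t* at once.

Event classification applies the count rule literally to adjacent chart
points with a gene-count drop: species count down ⇒ orthologous,
species count flat ⇒ paralogous. An orthologous interval that loses
more genes than species is flagged `mixed` — paralog loss may have
co-occurred and the interval deserves inspection. The major/minor
magnitude split is not quantified by the count rule itself; here an
event is **major** when the departing genes are ≥ 25 % of the group
(`major_frac`, configurable), separating "two main groups" from "a few
genes split off". The species/strain granularity is whatever the
sidecar map provides; strains are never merged.

`duplication_signature` reports, per elementary HI interval, the
fraction of a species' gene lineages showing a paralogous event there;
intervals at or above `flag_frac` (default 0.5) are genome-level
duplication candidates, the rest point to localized duplication.

## Trees and discordance

Dendrograms are built by Kruskal-style agglomeration on edges sorted by
descending HI, not by generic hierarchical-clustering code, so merge
heights are the **exact** edge HI values and cutting the dendrogram at
*t* reproduces the threshold groups bit-for-bit (converting to
d = 1 − HI and back would already lose exactness in floating point).
Edge lengths are stored on the distance scale d = 1 − HI, internal node
labels carry the merge HI.

The orthology tree takes, per species, the gene with maximum HI to the
focal gene (ties: lexicographically smallest gene id; the focal gene
always represents its own species because self-HI is 1), then builds
the dendrogram over the representatives and relabels leaves by species.

The taxonomy tree is induced from a parent/child table (NCBI
`nodes.dmp` dialect or plain TSV): prune to the kept species, suppress
unary nodes, and **preserve polytomies** — no resolution is invented.

Robinson–Foulds is the symmetric difference of non-trivial bipartitions
under the unrooted convention; a multifurcating tree contributes only
the bipartitions it resolves, so polytomies are scored conservatively.
Splits are canonicalised by the side not containing a fixed reference
leaf, making rooted and unrooted representations agree. The RF
implementation is native (dendropy's `treecompare` serves as the
independent oracle in the tests) because the Monte-Carlo percentile
evaluates thousands of random topologies per call.

The percentile null is **uniform over labeled binary topologies**,
sampled by sequential random edge addition (each topology has
probability 1/(2n−5)!!), with a mandatory seed. The percentile counts
random trees with RF ≥ observed, so high percentile = high similarity
and the value is comparable across leaf counts. With fewer than four
leaves there are no non-trivial bipartitions and the percentile is
undefined (a domain error, not a silent 100).

## The CI network

CI = 2·N_S/(N_C + N_D). N_S is defined as the number of
**reciprocal-best-match** gene pairs with HI ≥ a network threshold
(default 0.3): under that definition CI is exactly the F-measure of a
one-to-one correspondence between the genomes, which is the property
the index is named for. A looser reading — genes with at least one
qualifying hit, averaged over the two directions — is available as
`method="shared"` for sensitivity analysis. Edge exports hide CI < 0.05
by default for readability; the full edge map stays on the object.
Node highlighting (species carrying a gene with HI ≥ *t* to the focal
gene, own species always included) uses *t* = 0.8 by default and is
monotone: raising *t* never adds a species.

## The simulator

`simulate_family` emulates a single protein family evolving over a
species tree:

* **Species tree** — random topology from uniformly random sequential
  lineage joins. Merge *times* are placed so that the **expected
  pairwise identities** at successive speciations are evenly spaced
  from `top_identity` (default 0.95) down to the identity implied by
  the root age (`species_tree_height`, default 0.41 expected
  substitutions per site, giving a root-level identity of ≈ 0.45 —
  family-level divergence). Spacing uniformly on the identity (= HI)
  axis rather than the time axis gives every event the same resolution
  to downstream inference; with eight species the designed inter-event
  HI gap is ≈ 0.08.
* **Duplications** — grafted at `(branch, relative_time)` points; the
  copy follows the same speciation history below the graft, so a
  duplication separates gene copies but never species, exactly the
  signature the event rule keys on. The default places one duplication
  halfway up the terminal branch of S1.
* **Sequences** — a uniform random root protein of 300 residues evolves
  along each branch under an i.i.d. 20-state model: per-site Poisson
  substitution counts, each substitution uniform over the other 19
  residues. Expected identity at divergence d (substitutions/site along
  the connecting path) has the closed form
  p(d) = 1/20 + (19/20)·exp(−(20/19)·d), used both to place speciation
  times and to convert true event ages into expected chart HIs. No
  indels are introduced, so alignment length equals sequence length and
  HI reduces to percent identity — which is why the simulation pipeline
  is aligned in global mode.
* **Families** — species are binned by cutting the species tree at
  `family_cut_frac` (default 0.5) of the root age, exercising the
  family-count line of the chart.

Everything derives from one `numpy.random.default_rng(seed)`; identical
configurations give byte-identical FASTA/TSV/newick outputs.

**What the simulator does not emulate:** rate heterogeneity across
sites or lineages, indels, selection, domain shuffling, gene loss,
horizontal transfer, and search-tool artefacts (E-value cutoffs,
hit-count truncation). Passing recovery tests therefore demonstrates
that the inference chain is correct under its own model assumptions —
clock-like divergence and full-length homology — not that it is robust
to every failure mode of real data. On real families, rate variation
can reorder merges relative to speciation order; that discordance is
precisely what the RF/percentile comparison is designed to surface
rather than an error to be eliminated.

## Scoring recovered events against truth

A focal gene's chart should show one event per ancestor of that gene in
the true gene tree, at the expected identity of that ancestor's age.
Recovered events are placed at their observed single-linkage merge HI
(the strongest edge between the departing and staying sets) and matched
one-to-one to expected events by an order-preserving alignment that
minimises total |ΔHI| with a skip penalty of 0.08 per unmatched event —
the designed inter-event spacing, so an event is dropped from the
matching rather than pulled more than one spacing away. Precision and
recall count kind-correct matches over recovered and expected events
respectively.

## Problem sizes and numerical choices

Validation runs use 50 simulated families of 8 species (one duplication
for event recovery, none for tree recovery), 100 random HI graphs of up
to 30 genes for the duality and nestedness checks, 200 random pairs for
the aligner/tabular HI round trip, the exhaustive 105-topology 6-leaf
null (5000 Monte-Carlo samples) for percentile calibration, and 1000
random triples for the CI identity. At these sizes the full suite and
the acceptance script each complete in well under a minute of compute
per block. Measured at these conditions, event-kind precision and
recall are ≈ 0.99 and species-tree recovery is 94–100 % across seed
ranges, with the recovered trees scoring a percentile of exactly 100.

Tie-breaks are deterministic everywhere (lexicographic gene ids,
canonical pair ordering before alignment, sorted edge processing), all
randomness flows from explicit seeds, and TSV exports write floats with
`repr` so re-reading reproduces values exactly. Degenerate inputs have
defined behaviour: an empty hit list gives an empty graph, a focal gene
with no homologous species raises an empty-tree signal, charts that
violate nestedness (impossible from the sweep, possible from hand-built
input) raise a contract error, and trees with unequal leaf sets are
rejected with the offending labels listed.

## Known limitations

* Single linkage chains: one spurious strong edge (e.g. a shared
  low-complexity segment) can bridge unrelated groups; the HI's
  coverage normalisation mitigates but does not eliminate this.
* The percentile null is topology-uniform; an empirical null (gene
  trees with the same leaf count drawn from the same dataset) could be
  more faithful for database-scale use but needs a corpus this tool
  does not assume.
* External tabular input may be truncated by search-tool hit ceilings;
  the reader exposes per-query hit counts so users can detect it, but
  the package cannot repair membership of groups larger than the
  ceiling.
* The internal aligner is quadratic per pair and intended for
  desk-scale inputs (hundreds of sequences); corpus-scale all-vs-all
  search should be done externally and supplied as tabular input.
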