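# homolineage

Homology-index lineage tracking for protein families: threshold-sweep
homologous gene groups, ortholog/paralog event classification, orthology
vs. taxonomy tree discordance, and species similarity networks.

## The problem

A gene family's history mixes two processes: **speciation**, which
separates lineages of different species, and **gene duplication**, which
multiplies copies within one genome. Databases built around precise
phylogenies report orthologous groups, but they do not show the *bias*
between how a gene mutated and how its carriers speciated — the very
signal that reveals genome duplications, unusual conservation, or a
gene's suitability as a barcode marker. `homolineage` makes that bias
measurable for any protein family a user supplies, from an all-vs-all
similarity search (or its internal aligner at desk scale) through to a
quantitative tree comparison.

## The method

Every pairwise protein alignment is reduced to a **homology index**

    HI = min(1, 2 · (pident/100) · aln_len / (qlen + slen))

i.e. the identical aligned columns normalised by the mean sequence
length — 1 for a full-length identical match, 0 for no similarity,
computable from a single line of BLAST tabular output
(`-outfmt '6 std qlen slen'`).

With all genes as nodes and HIs as edge weights:

* **Groups.** At threshold *t*, homologous groups are the connected
  components of the subgraph with HI ≥ *t* (single linkage). Sweeping
  *t* over all distinct edge values gives a nested hierarchy of groups.
* **Lineage chart.** For a focal gene, the ordered sequence of groups
  containing it, summarised as gene / species / family counts per
  threshold.
* **Events.** Reading the chart toward higher thresholds, each drop in
  the gene count is a homologous event: **orthologous** if the species
  count dropped too, **paralogous** if it is unchanged. Paralogous
  events co-occurring across many genes of one species in the same HI
  interval point to genome-level rather than localized duplication.
* **Trees.** The single-linkage dendrogram on d = 1 − HI puts merge
  heights on the HI scale; the **orthology tree** is the dendrogram
  over one representative per species (the gene most homologous to the
  focal gene). The **taxonomy tree** is induced from an NCBI-style
  parent/child node table (polytomies preserved). Their discordance is
  the Robinson–Foulds distance RF(T₁, T₂) = |Σ(T₁) Δ Σ(T₂)| over
  non-trivial bipartitions, plus a Monte-Carlo **percentile**: the
  fraction of uniformly random binary topologies at least as distant
  from the taxonomy tree as the observed orthology tree (high
  percentile = high similarity, comparable across leaf counts).
* **Network.** Species pairs are weighted by the correspondence index
  CI = 2·N_S/(N_C + N_D) — the F-measure of a reciprocal-best-match
  gene correspondence between genomes of N_C and N_D genes — with the
  species carrying a homolog of the focal gene above a chosen HI
  (default 0.8) highlighted.

A seeded simulator of gene-family evolution (random species tree,
grafted duplications, i.i.d. 20-state substitution with a closed-form
identity-decay curve) provides ground truth for validating every stage.

## Worked example

Simulate an eight-species family with one duplication on the terminal
branch of S1, then run the full analysis for the gene `S1_p1`:

```sh
homolineage simulate --n-species 8 --seed 1 --out-dir sim
homolineage pipeline --fasta sim/family.faa --map sim/family.tsv \
    --taxonomy sim/species_tree.nwk --gene S1_p1 --mode global \
    --out-dir run --seed 42
```

`run/chart.tsv` holds the lineage chart (counts per threshold):

```
threshold           n_genes  n_species  n_families
0.0                 9        8          4
0.4866666666666667  7        6          2
...
```

`run/events.tsv` classifies the six drops along the chart — five
orthologous events (species count falls with the gene count) and, at
the top of the chart, the duplication:

```
t_high              t_low               kind         delta_genes  delta_species
0.4866666666666667  0.0                 orthologous  2            2
0.7033333333333333  0.4866666666666667  orthologous  1            1
0.8                 0.7033333333333333  orthologous  1            1
0.86                0.8                 orthologous  2            2
0.93                0.86                orthologous  1            1
1.0                 0.93                paralogous   1            0
```

The paralogous event between HI 0.93 and 1.0 is the simulated
duplication (one gene leaves the group, no species does). `run/rf.json`
compares the orthology tree with the true species tree:

```json
{"rf": 0, "max_rf": 10, "percentile": 100.0, "n_random": 1000, "seed": 42}
```

`rf = 0` means the gene's divergence order matches the speciation order
exactly, and the percentile of 100 says no random topology is that
close. `run/network_edges.tsv` and `run/network.graphml` carry the
CI-weighted species network with the ortholog-bearing species flagged.

Real data enters the same way: a protein FASTA, a
`gene<TAB>species[<TAB>family]` map, and optionally a precomputed
`-outfmt '6 std qlen slen'` BLAST tabular file (`--blast`), which is
used instead of the internal aligner.

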