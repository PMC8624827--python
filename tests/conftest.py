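"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force
(transitive closure, naive agglomeration, exhaustive topology
enumeration) so they stay independent of the code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from homolineage.pairscore import HIGraph, ProteinRecord, build_hi_graph

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def random_graph_factory():
    """Factory of random connected HI graphs with species/family maps."""

    def make(rng, n_genes=12, extra_edge_p=0.3, n_species=None):
        genes = [f"g{i:02d}" for i in range(n_genes)]
        graph = HIGraph()
        for g in genes:
            graph.add_gene(g)
        # random spanning tree keeps the graph connected
        order = list(rng.permutation(n_genes))
        for idx in range(1, n_genes):
            a = genes[order[idx]]
            b = genes[order[int(rng.integers(idx))]]
            graph.add_edge(a, b, float(rng.uniform(0.05, 0.99)))
        for a, b in combinations(genes, 2):
            if rng.random() < extra_edge_p:
                graph.add_edge(a, b, float(rng.uniform(0.05, 0.99)))
        n_species = n_species or max(2, n_genes // 2)
        species_map = {
            g: (f"sp{int(rng.integers(n_species))}", f"fam{int(rng.integers(3))}")
            for g in genes
        }
        # families must partition species
        fam_of_species = {}
        for g, (sp, fam) in species_map.items():
            fam_of_species.setdefault(sp, fam)
        species_map = {g: (sp, fam_of_species[sp]) for g, (sp, _) in species_map.items()}
        return graph, species_map

    return make


@pytest.fixture
def toy_records():
    """Six short related proteins in three species, two families."""
    base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
    mut1 = base[:20] + "W" + base[21:]
    mut5 = base[:10] + "WWWWW" + base[15:]
    far = base[:30] + "GGGGGGGGGGGGGGGGGG" + base[48:]
    return [
        ProteinRecord("a1", "spA", base, "famX"),
        ProteinRecord("a2", "spA", mut1, "famX"),
        ProteinRecord("b1", "spB", mut5, "famX"),
        ProteinRecord("c1", "spC", far, "famY"),
        ProteinRecord("c2", "spC", base[::-1], "famY"),
        ProteinRecord("b2", "spB", mut1[:50], "famX"),
    ]


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_components(graph: HIGraph, t: float) -> set[frozenset[str]]:
    """Connected components at hi >= t by repeated set merging
    (transitive closure), independent of the BFS in the package."""
    comps = [{g} for g in graph.genes]
    changed = True
    while changed:
        changed = False
        for a, b, hi in graph.edges():
            if hi < t:
                continue
            ca = next(c for c in comps if a in c)
            cb = next(c for c in comps if b in c)
            if ca is not cb:
                ca |= cb
                comps.remove(cb)
                changed = True
    return {frozenset(c) for c in comps}


def naive_single_linkage(graph: HIGraph, members) -> list[tuple[float, frozenset[str]]]:
    """O(n^3) agglomeration: repeatedly merge the cluster pair with the
    highest single-link similarity (max cross-pair HI).  Returns the
    merge list as (similarity, merged member set)."""
    clusters = [frozenset([m]) for m in sorted(members)]
    merges: list[tuple[float, frozenset[str]]] = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            sim = max(
                (graph.hi(x, y) for x in clusters[i] for y in clusters[j]),
                default=0.0,
            )
            if best is None or sim > best[0]:
                best = (sim, i, j)
        sim, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((sim, merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def _subtree_spans(newick: str) -> list[tuple[int, int]]:
    spans = []
    for i, ch in enumerate(newick):
        if ch in "(,":
            j = i + 1
            depth = 0
            k = j
            while k < len(newick):
                c = newick[k]
                if c == "(":
                    depth += 1
                elif c == ")":
                    if depth == 0:
                        break
                    depth -= 1
                elif c == "," and depth == 0:
                    break
                k += 1
            if j < k:
                spans.append((j, k))
    return [(a, b) for a, b in spans if not (a == 1 and b == len(newick) - 1)]


def enumerate_topologies(labels: list[str]) -> list[str]:
    """All unrooted binary topologies on ``labels`` as newick strings
    (without the trailing ';'), built by attaching each new leaf to
    every edge of every smaller topology — (2n-5)!! in total."""
    if len(labels) == 3:
        return ["(%s,%s,%s)" % tuple(labels)]
    out = []
    for smaller in enumerate_topologies(labels[:-1]):
        for i, j in _subtree_spans(smaller):
            out.append(
                smaller[:i] + "(" + smaller[i:j] + "," + labels[-1] + ")" + smaller[j:]
            )
    return out


def oracle_rf(newick_a: str, newick_b: str) -> int:
    """RF via dendropy's bipartition machinery — independent of the
    package's split computation."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    return treecompare.symmetric_difference(t1, t2)
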