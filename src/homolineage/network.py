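"""Species–species similarity network weighted by the CI index.

For two genomes with ``n_c`` and ``n_d`` genes sharing ``n_shared``
matched genes, the correspondence index is

    CI = 2 * n_shared / (n_c + n_d)

which is exactly the F-measure (harmonic mean of the two coverage
ratios ``n_shared/n_c`` and ``n_shared/n_d``).  By default
``n_shared`` counts reciprocal-best-match gene pairs at or above a
network-level HI threshold, making CI the F-measure of a one-to-one
gene correspondence; a looser reading (genes with any hit, averaged
over the two directions) is available via ``method="shared"``.

A network can additionally highlight the species carrying a homolog of
a focal gene at or above a user threshold (default 0.8) — the red
nodes of the species-network figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import DomainError, LabelingError
from .pairscore import HIGraph

SpeciesMap = Mapping[str, tuple[str, str]]


def ci_index(n_shared: float, n_c: int, n_d: int) -> float:
    """Correspondence index 2·n_shared/(n_c + n_d) in [0, 1]."""
    if n_c < 1 or n_d < 1:
        raise DomainError(f"genome sizes must be >= 1, got {n_c}, {n_d}")
    if not (0 <= n_shared <= min(n_c, n_d)):
        raise DomainError(
            f"n_shared {n_shared} outside [0, min({n_c}, {n_d})]"
        )
    return 2.0 * n_shared / (n_c + n_d)


@dataclass
class SpeciesNetwork:
    """Species nodes with genome sizes, CI-weighted edges, and an
    optional highlight set of species carrying orthologs of a focal
    gene at ``hi_threshold``."""

    gene_counts: dict[str, int]
    edges: dict[frozenset[str], float] = field(default_factory=dict)
    highlight: frozenset[str] = frozenset()
    hi_threshold: float | None = None
    focal_gene: str | None = None
    species_map: SpeciesMap = field(default_factory=dict, repr=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.gene_counts)

    def ci(self, a: str, b: str) -> float:
        return self.edges.get(frozenset((a, b)), 0.0)

    def to_networkx(self, min_ci: float = 0.0) -> nx.Graph:
        g = nx.Graph()
        for sp in sorted(self.gene_counts):
            g.add_node(sp, n_genes=self.gene_counts[sp],
                       highlight=sp in self.highlight)
        for pair, ci in sorted(self.edges.items(), key=lambda kv: sorted(kv[0])):
            if ci >= min_ci:
                a, b = sorted(pair)
                g.add_edge(a, b, ci=ci)
        if self.hi_threshold is not None:
            g.graph["hi_threshold"] = self.hi_threshold
        if self.focal_gene is not None:
            g.graph["focal_gene"] = self.focal_gene
        return g


def _best_match(
    graph: HIGraph, gene: str, targets: set[str]
) -> tuple[str, float] | None:
    """Best target for ``gene`` (max HI, ties to the smallest id);
    a gene contained in ``targets`` best-matches itself at HI 1."""
    if gene in targets:
        return gene, 1.0
    best: tuple[float, str] | None = None
    for nb, hi in graph.neighbors(gene).items():
        if nb in targets:
            if best is None or hi > best[0] or (hi == best[0] and nb < best[1]):
                best = (hi, nb)
    if best is None:
        return None
    return best[1], best[0]


def reciprocal_best_pairs(
    graph: HIGraph, genes_c: Iterable[str], genes_d: Iterable[str], t: float
) -> list[tuple[str, str, float]]:
    """Reciprocal best matches between two gene sets with hi >= t."""
    set_c, set_d = set(genes_c), set(genes_d)
    pairs = []
    for g in sorted(set_c):
        fwd = _best_match(graph, g, set_d)
        if fwd is None or fwd[1] < t:
            continue
        h, hi = fwd
        back = _best_match(graph, h, set_c)
        if back is not None and back[0] == g:
            pairs.append((g, h, hi))
    return pairs


def build_network(
    graph: HIGraph,
    species_map: SpeciesMap,
    edge_hi_threshold: float = 0.3,
    method: str = "rbh",
) -> SpeciesNetwork:
    """CI-weighted network over all species in the map of the graph.

    ``method="rbh"`` (default) counts reciprocal best matches at
    hi >= ``edge_hi_threshold``; ``method="shared"`` counts genes with
    at least one qualifying hit, averaged over the two directions.
    Zero-weight edges are omitted.
    """
    if method not in ("rbh", "shared"):
        raise DomainError(f"unknown N_S method {method!r}")
    genes_by_species: dict[str, set[str]] = {}
    for gene in sorted(graph.genes):
        if gene not in species_map:
            raise LabelingError(f"gene {gene!r} absent from species map")
        genes_by_species.setdefault(species_map[gene][0], set()).add(gene)
    net = SpeciesNetwork(
        gene_counts={sp: len(gs) for sp, gs in genes_by_species.items()},
        species_map=dict(species_map),
    )
    species = sorted(genes_by_species)
    for i, c in enumerate(species):
        for d in species[i + 1 :]:
            gc, gd = genes_by_species[c], genes_by_species[d]
            if method == "rbh":
                n_shared: float = len(
                    reciprocal_best_pairs(graph, gc, gd, edge_hi_threshold)
                )
            else:
                fwd = sum(
                    1 for g in gc
                    if (m := _best_match(graph, g, gd)) and m[1] >= edge_hi_threshold
                )
                rev = sum(
                    1 for g in gd
                    if (m := _best_match(graph, g, gc)) and m[1] >= edge_hi_threshold
                )
                n_shared = 0.5 * (fwd + rev)
            if n_shared > 0:
                net.edges[frozenset((c, d))] = ci_index(n_shared, len(gc), len(gd))
    return net


def highlight_orthologs(
    net: SpeciesNetwork, graph: HIGraph, focal: str, t: float
) -> SpeciesNetwork:
    """Network copy with the highlight set of species owning a gene at
    hi(focal, ·) >= t; the focal gene's own species is always included.
    Raising ``t`` never adds species (nested highlight sets).
    """
    if focal not in graph:
        raise DomainError(f"focal gene {focal!r} not in graph")
    if not (0.0 <= t <= 1.0):
        raise DomainError(f"threshold {t} outside [0, 1]")
    if focal not in net.species_map:
        raise LabelingError(f"focal gene {focal!r} absent from species map")
    highlighted = {net.species_map[focal][0]}
    for gene, hi in graph.neighbors(focal).items():
        if hi >= t:
            if gene not in net.species_map:
                raise LabelingError(f"gene {gene!r} absent from species map")
            highlighted.add(net.species_map[gene][0])
    return replace(
        net, highlight=frozenset(highlighted), hi_threshold=t, focal_gene=focal
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_edges_tsv(
    net: SpeciesNetwork,
    path: str | Path,
    min_ci: float = 0.05,
    header_lines: Iterable[str] = (),
) -> None:
    """Edge list ``species_a<TAB>species_b<TAB>ci``; edges below
    ``min_ci`` are omitted to keep toy networks readable (the full
    matrix remains available on the object)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("species_a\tspecies_b\tci\n")
        for pair, ci in sorted(net.edges.items(), key=lambda kv: sorted(kv[0])):
            if ci >= min_ci:
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{repr(ci)}\n")


def write_graphml(net: SpeciesNetwork, path: str | Path, min_ci: float = 0.0) -> None:
    nx.write_graphml(net.to_networkx(min_ci=min_ci), str(path))
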