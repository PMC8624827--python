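"""Trees on the HI scale and gene-tree/species-tree discordance.

Three tree constructions:

* :func:`hi_dendrogram` — single-linkage agglomeration of a gene set
  with distance ``d = 1 - HI``; merge heights are recorded as exact HI
  values, so cutting the dendrogram at height ``t`` reproduces the
  threshold groups exactly.
* :func:`orthology_tree` — per species, the gene most homologous to a
  focal gene represents that species; the dendrogram over the
  representatives, relabeled by species, approximates the speciation
  history as seen by that gene family.
* :func:`taxonomy_tree` — the induced (possibly multifurcating) tree
  on a species subset from an NCBI-style parent/child node table.

Discordance between an orthology tree and the taxonomy tree is
quantified by the Robinson–Foulds metric (symmetric difference of
non-trivial bipartitions, unrooted convention; a multifurcating tree
contributes only the bipartitions it resolves).  Because RF grows with
the leaf count, :func:`rf_percentile` situates an observed RF within a
Monte-Carlo null of uniformly random binary topologies on the same
leaf set: the percentile is the fraction of random trees at least as
distant as the observed one, so *high percentile = high similarity*.

Trees are :class:`dendropy.Tree` objects throughout; newick I/O and
pruning go through dendropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import (
    ContractError,
    DomainError,
    EmptyTreeError,
    ParseError,
    TaxonomyLookupError,
    ValidationError,
)
from .pairscore import HIGraph

LabeledTree = dendropy.Tree

SpeciesMap = Mapping[str, tuple[str, str]]


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> LabeledTree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def newick_from_string(text: str) -> LabeledTree:
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def write_newick(tree: LabeledTree, path: str | Path, comment: str | None = None) -> None:
    """Write newick; an optional bracket comment (provenance) precedes
    the tree and survives a round-trip through :func:`read_newick`."""
    text = tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"[{comment}]\n")
        fh.write(text)


def leaf_labels(tree: LabeledTree) -> frozenset[str]:
    labels = [lf.taxon.label if lf.taxon else (lf.label or "")
              for lf in tree.leaf_node_iter()]
    if "" in labels:
        raise ValidationError("tree has an unlabeled leaf")
    if len(set(labels)) != len(labels):
        raise ValidationError("tree leaf labels are not unique")
    return frozenset(labels)


# ---------------------------------------------------------------------------
# single-linkage dendrogram on the HI scale
# ---------------------------------------------------------------------------

def _new_tree(root: dendropy.Node, labels: Iterable[str]) -> LabeledTree:
    tns = dendropy.TaxonNamespace(sorted(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tns.get_taxon(leaf.label)
        leaf.label = None
    tree.is_rooted = True
    return tree


def hi_dendrogram(
    graph: HIGraph,
    members: Iterable[str],
    label_map: Mapping[str, str] | None = None,
) -> LabeledTree:
    """Single-linkage dendrogram over ``members`` with d = 1 - HI.

    Edges are processed in descending HI order (Kruskal); each union
    creates an internal node carrying the merge HI in ``merge_hi`` (and
    as its label), with child edge lengths on the distance scale.
    Members must be connected at some positive threshold.  With
    ``label_map``, leaves are relabeled (e.g. gene -> species).
    """
    members = sorted(set(members))
    missing = [m for m in members if m not in graph]
    if missing:
        raise DomainError(f"members not in graph: {missing[:5]}")
    if label_map is not None:
        members_out = [label_map[m] for m in members]
        if len(set(members_out)) != len(members_out):
            raise ValidationError("label_map collapses members onto a duplicate label")
    nodes: dict[str, dendropy.Node] = {}
    for m in members:
        node = dendropy.Node(label=(label_map[m] if label_map else m))
        node.merge_hi = 1.0
        nodes[m] = node
    parent = {m: m for m in members}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    member_set = set(members)
    edges = sorted(
        ((a, b, hi) for a, b, hi in graph.edges()
         if a in member_set and b in member_set),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    n_comp = len(members)
    for a, b, hi in edges:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        ra, rb = sorted((ra, rb))
        merged = dendropy.Node()
        merged.merge_hi = hi
        merged.label = f"{hi:.12g}"
        for child_root in (ra, rb):
            child = nodes[child_root]
            # edge length on the distance scale d = 1 - HI
            child.edge.length = child.merge_hi - hi
            merged.add_child(child)
        nodes[ra] = merged
        parent[rb] = ra
        n_comp -= 1
        if n_comp == 1:
            break
    if n_comp != 1:
        raise DomainError(
            f"members are not connected at any positive threshold "
            f"({n_comp} components remain)"
        )
    root = nodes[find(members[0])]
    root.edge.length = None
    return _new_tree(root, [label_map[m] for m in members] if label_map else members)


def cut_dendrogram(tree: LabeledTree, t: float) -> list[frozenset[str]]:
    """Partition of the leaves obtained by cutting at HI threshold ``t``.

    A maximal subtree whose root merged at ``merge_hi >= t`` forms one
    cluster (leaves carry ``merge_hi == 1``), exactly mirroring the
    hi >= t rule of the threshold groups.
    """
    clusters: list[frozenset[str]] = []

    def descend(node: dendropy.Node) -> None:
        if getattr(node, "merge_hi", 1.0) >= t:
            clusters.append(
                frozenset(lf.taxon.label for lf in node.leaf_iter())
            )
        else:
            for child in node.child_nodes():
                descend(child)

    descend(tree.seed_node)
    return sorted(clusters, key=min)


# ---------------------------------------------------------------------------
# orthology tree
# ---------------------------------------------------------------------------

def species_representatives(
    graph: HIGraph, focal: str, species_map: SpeciesMap
) -> dict[str, str]:
    """Per species, the gene most homologous to ``focal``.

    Ties break on the lexicographically smallest gene_id; the focal
    gene always represents its own species (self HI = 1 dominates).
    Only species with at least one positive-HI gene appear.
    """
    if focal not in graph:
        raise DomainError(f"focal gene {focal!r} not in graph")
    best: dict[str, tuple[float, str]] = {}
    for gene in [focal, *graph.neighbors(focal)]:
        if gene not in species_map:
            raise DomainError(f"gene {gene!r} absent from species map")
        hi = graph.hi(focal, gene)
        if hi <= 0.0:
            continue
        sp = species_map[gene][0]
        cur = best.get(sp)
        if cur is None or (hi, _neg_lex(gene)) > (cur[0], _neg_lex(cur[1])):
            best[sp] = (hi, gene)
    return {sp: gene for sp, (hi, gene) in best.items()}


class _neg_lex(str):
    """Orders strings descending under max-comparison (so that the
    *smallest* gene_id wins a tie on HI)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def orthology_tree(
    graph: HIGraph, focal: str, species_map: SpeciesMap
) -> LabeledTree:
    """Dendrogram over one representative gene per species, leaves
    relabeled by species_id.

    Raises :class:`EmptyTreeError` when no species besides the focal
    gene's own has a homolog.
    """
    reps = species_representatives(graph, focal, species_map)
    if len(reps) < 2:
        raise EmptyTreeError(
            f"no species shares a homolog with {focal!r}; orthology tree is empty"
        )
    gene_to_species = {gene: sp for sp, gene in reps.items()}
    return hi_dendrogram(graph, reps.values(), label_map=gene_to_species)


# ---------------------------------------------------------------------------
# taxonomy table and induced taxonomy tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRecord:
    child: str
    parent: str
    rank: str = ""
    name: str = ""


@dataclass
class TaxonomyTable:
    """Parent/child taxon records with exactly one root and no cycles."""

    records: list[TaxonRecord]

    def __post_init__(self) -> None:
        self.parent_of: dict[str, str] = {}
        self.children_of: dict[str, list[str]] = {}
        roots = []
        for rec in self.records:
            if rec.child in self.parent_of:
                raise ValidationError(f"taxon {rec.child!r} listed twice")
            if rec.parent == rec.child or not rec.parent:
                roots.append(rec.child)
            else:
                self.parent_of[rec.child] = rec.parent
                self.children_of.setdefault(rec.parent, []).append(rec.child)
        known = {r.child for r in self.records}
        implicit_roots = {r.parent for r in self.records
                          if r.parent and r.parent != r.child and r.parent not in known}
        roots.extend(sorted(implicit_roots))
        if len(roots) != 1:
            raise ValidationError(
                f"taxonomy must have exactly one root, found {sorted(roots)!r}"
            )
        self.root = roots[0]
        # cycle check: every node must reach the root
        for node in known:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise ValidationError(f"taxonomy contains a cycle through {cur!r}")
                seen.add(cur)
                if cur not in self.parent_of:
                    raise ValidationError(f"taxon {cur!r} does not reach the root")
                cur = self.parent_of[cur]
        self.by_name: dict[str, str] = {}
        for rec in self.records:
            if rec.name:
                self.by_name.setdefault(rec.name, rec.child)


def read_nodes_dmp(path: str | Path) -> TaxonomyTable:
    """Read the NCBI ``nodes.dmp`` dialect: fields separated by
    ``\\t|\\t`` and records terminated by ``\\t|``.  Only the first
    three fields (taxid, parent taxid, rank) are used."""
    records: list[TaxonRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            fields = line.split("\t|\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: not a nodes.dmp record")
            child, parent = fields[0].strip(), fields[1].strip()
            rank = fields[2].strip() if len(fields) > 2 else ""
            records.append(TaxonRecord(child=child, parent=parent, rank=rank, name=child))
    return TaxonomyTable(records)


def read_taxonomy_tsv(path: str | Path) -> TaxonomyTable:
    """Read a plain TSV alternative: ``parent<TAB>child[<TAB>rank[<TAB>name]]``."""
    records: list[TaxonRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected parent<TAB>child")
            parent, child = fields[0], fields[1]
            rank = fields[2] if len(fields) > 2 else ""
            name = fields[3] if len(fields) > 3 else child
            records.append(TaxonRecord(child=child, parent=parent, rank=rank, name=name))
    return TaxonomyTable(records)


def read_taxonomy_table(path: str | Path) -> TaxonomyTable:
    """Auto-detect the nodes.dmp dialect vs. the plain TSV."""
    with open(path) as fh:
        head = fh.readline()
    if "\t|" in head:
        return read_nodes_dmp(path)
    return read_taxonomy_tsv(path)


def taxonomy_tree(table: TaxonomyTable, keep: Iterable[str]) -> LabeledTree:
    """Induced tree on ``keep``, unary nodes suppressed, polytomies
    preserved (no resolution is invented).

    Labels resolve against taxids first, then names; unresolvable
    labels raise :class:`TaxonomyLookupError` listing all offenders.
    """
    keep = sorted(set(keep))
    known = {r.child for r in table.records} | {table.root}
    resolved: dict[str, str] = {}
    missing = []
    for label in keep:
        if label in known:
            resolved[label] = label
        elif label in table.by_name:
            resolved[label] = table.by_name[label]
        else:
            missing.append(label)
    if missing:
        raise TaxonomyLookupError(f"labels not in taxonomy: {missing}")
    if len(set(resolved.values())) != len(resolved):
        raise ValidationError("keep labels resolve to duplicate taxa")
    if len(keep) < 2:
        raise DomainError("need at least 2 species to induce a tree")
    taxid_to_label = {tid: lab for lab, tid in resolved.items()}
    keep_ids = set(taxid_to_label)

    def build(taxid: str) -> dendropy.Node | None:
        sub = [build(c) for c in sorted(table.children_of.get(taxid, []))]
        sub = [s for s in sub if s is not None]
        if taxid in keep_ids:
            node = dendropy.Node(label=taxid_to_label[taxid])
            # a kept internal taxon keeps its kept descendants as siblings
            for s in sub:
                node.add_child(s)
            return node
        if not sub:
            return None
        if len(sub) == 1:
            return sub[0]
        node = dendropy.Node()
        for s in sub:
            node.add_child(s)
        return node

    root = build(table.root)
    assert root is not None
    return _new_tree(root, keep)


# ---------------------------------------------------------------------------
# Robinson–Foulds distance and its Monte-Carlo percentile
# ---------------------------------------------------------------------------

def splits(tree: LabeledTree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the (unrooted) tree.

    Each split is canonicalised as the side *not* containing a fixed
    reference leaf, so rooted and unrooted representations of the same
    topology yield identical sets; a multifurcating tree contributes
    only the bipartitions it resolves.
    """
    labels = leaf_labels(tree)
    n = len(labels)
    ref = min(labels)
    out: set[frozenset[str]] = set()
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        side = below[node]
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(labels - side) if ref in side else side)
    return out


def rf_distance(a: LabeledTree, b: LabeledTree) -> int:
    """Robinson–Foulds distance: |splits(a) Δ splits(b)|.

    Both trees must carry the same leaf label set (prune first);
    otherwise :class:`ContractError` lists the difference.
    ``rf(a, a) == 0``; for binary trees the maximum is ``2(n-3)``.
    """
    la, lb = leaf_labels(a), leaf_labels(b)
    if la != lb:
        raise ContractError(
            f"leaf sets differ: only in first {sorted(la - lb)[:5]}, "
            f"only in second {sorted(lb - la)[:5]}"
        )
    return len(splits(a) ^ splits(b))


@dataclass(frozen=True)
class RFResult:
    """An RF value with its Monte-Carlo percentile against random
    binary topologies (high percentile = high similarity)."""

    rf: int
    max_rf: int
    percentile: float
    n_random: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.rf <= self.max_rf):
            raise ValidationError(f"rf {self.rf} outside [0, {self.max_rf}]")

    def to_json(self, **extra) -> str:
        payload = {
            "rf": self.rf,
            "max_rf": self.max_rf,
            "percentile": self.percentile,
            "n_random": self.n_random,
            "seed": self.seed,
        }
        payload.update(extra)
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def random_binary_topology(
    labels: Sequence[str], rng: np.random.Generator
) -> LabeledTree:
    """Uniformly random unrooted binary topology on ``labels``.

    Sequential random edge addition: leaves are attached one at a time
    to a uniformly chosen existing edge, which yields each of the
    (2n-5)!! topologies with equal probability.
    """
    labels = sorted(set(labels))
    if len(labels) < 3:
        raise DomainError("need at least 3 labels for a topology")
    root = dendropy.Node()
    edge_nodes: list[dendropy.Node] = []
    for lab in labels[:3]:
        leaf = dendropy.Node(label=lab)
        root.add_child(leaf)
        edge_nodes.append(leaf)
    for lab in labels[3:]:
        target = edge_nodes[int(rng.integers(len(edge_nodes)))]
        up = target.parent_node
        up.remove_child(target)
        mid = dendropy.Node()
        up.add_child(mid)
        mid.add_child(target)
        leaf = dendropy.Node(label=lab)
        mid.add_child(leaf)
        edge_nodes.extend([mid, leaf])
    return _new_tree(root, labels)


def rf_percentile(
    obs: int,
    reference: LabeledTree,
    n_random: int = 1000,
    seed: int = 0,
) -> RFResult:
    """Percentile of an observed RF within the random-topology null.

    Samples ``n_random`` seeded uniform binary topologies on the
    reference's leaf set, and returns
    ``100 * |{rf_random >= obs}| / n_random`` — an observed tree more
    similar to the reference than random scores high.  Requires at
    least 4 leaves (no non-trivial bipartitions below that).
    """
    labels = sorted(leaf_labels(reference))
    n = len(labels)
    if n < 4:
        raise DomainError(f"need >= 4 leaves for a percentile, got {n}")
    if n_random < 1:
        raise DomainError("n_random must be >= 1")
    ref_splits = splits(reference)
    max_rf = len(ref_splits) + (n - 3)
    if not (0 <= obs <= max_rf):
        raise DomainError(f"observed rf {obs} outside [0, {max_rf}]")
    rng = np.random.default_rng(seed)
    at_least = 0
    for _ in range(n_random):
        rand = random_binary_topology(labels, rng)
        if len(ref_splits ^ splits(rand)) >= obs:
            at_least += 1
    return RFResult(
        rf=obs,
        max_rf=max_rf,
        percentile=100.0 * at_least / n_random,
        n_random=n_random,
        seed=seed,
    )
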