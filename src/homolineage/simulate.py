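"""Synthetic protein families with a known speciation/duplication history.

The generator provides the ground truth against which grouping, event
classification, tree recovery and the CI network are testable without
external data:

* a random binary species tree over ``n_species`` leaves is grown
  coalescent-style (uniformly random sequential lineage joins);
* merge *times* are placed so that the **expected sequence identities**
  at successive speciations are evenly spaced between a shallow level
  (default 0.95) and the level implied by the configured tree height —
  the event spacing on the HI axis, not the time axis, is what limits
  how finely downstream inference can resolve events, so the spacing
  is made uniform there;
* duplications are grafted at configured points of the species tree;
  both copies then follow the same speciation history below the graft,
  so a duplication separates gene copies without separating species;
* a root protein evolves down the gene tree under an i.i.d. 20-state
  model (exponential waiting times, uniform replacement over the other
  19 residues), whose identity-vs-divergence curve has the closed form

      p(d) = 1/20 + (19/20) * exp(-(20/19) * d)

  with ``d`` the expected substitutions per site separating two
  sequences.  No indels are introduced, so the alignment length equals
  the sequence length and the HI reduces to percent identity.

Everything is driven by one integer seed; identical configurations
yield byte-identical outputs.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import ConfigError, DomainError
from .events import ORTHOLOGOUS, PARALOGOUS, HomologyEvent
from .grouping import LineageChart
from .pairscore import HIGraph, ProteinRecord, write_fasta, write_species_map
from .trees import LabeledTree, _new_tree, write_newick

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# identity-decay curve of the substitution model
# ---------------------------------------------------------------------------

def expected_identity(d: float) -> float:
    """Expected fraction of identical sites at divergence ``d``
    (expected substitutions per site along the connecting path)."""
    if d < 0:
        raise DomainError(f"divergence must be >= 0, got {d}")
    return 1.0 / 20.0 + (19.0 / 20.0) * math.exp(-(20.0 / 19.0) * d)


def divergence_for_identity(p: float) -> float:
    """Inverse of :func:`expected_identity` on (1/20, 1]."""
    if not (1.0 / 20.0 < p <= 1.0):
        raise DomainError(f"identity {p} outside (0.05, 1]")
    return -(19.0 / 20.0) * math.log((p - 1.0 / 20.0) / (19.0 / 20.0))


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated gene family.

    ``species_tree_height`` is the root age in expected substitutions
    per site (per unit rate); ``duplication_events`` lists
    ``(branch, relative_time)`` pairs where ``branch`` names a species
    tree node (``S*`` leaf or ``N*`` internal) and the duplication sits
    at that fraction of the way up the branch above it.
    ``top_identity`` fixes the expected identity of the shallowest
    speciation; deeper speciations are evenly spaced in expected
    identity down to the root.
    """

    n_species: int = 8
    species_tree_height: float = 0.41
    duplication_events: tuple[tuple[str, float], ...] = (("S1", 0.5),)
    seq_length: int = 300
    substitution_rate: float = 1.0
    seed: int = 0
    top_identity: float = 0.95
    family_cut_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if self.seq_length < 50:
            raise ConfigError("seq_length must be >= 50")
        if self.substitution_rate <= 0 or self.species_tree_height <= 0:
            raise ConfigError("rates and heights must be positive")
        if not (0.0 < self.top_identity < 1.0):
            raise ConfigError(f"top_identity {self.top_identity} outside (0, 1)")
        for branch, rel in self.duplication_events:
            if not (0.0 <= rel <= 1.0):
                raise ConfigError(f"relative time {rel} outside [0, 1]")


class _SimNode:
    """Lightweight tree node used during simulation."""

    __slots__ = ("name", "age", "children", "kind", "species", "gene_id", "sequence")

    def __init__(self, name: str, age: float, kind: str, species: str | None = None):
        self.name = name
        self.age = age            # time before present
        self.kind = kind          # leaf | speciation | duplication
        self.species = species
        self.children: list[_SimNode] = []
        self.gene_id: str | None = None
        self.sequence: np.ndarray | None = None

    def clone(self) -> "_SimNode":
        dup = _SimNode(self.name, self.age, self.kind, self.species)
        dup.children = [c.clone() for c in self.children]
        return dup

    def leaves(self) -> list["_SimNode"]:
        if not self.children:
            return [self]
        out: list[_SimNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class SimEvent:
    """A true event in the simulated history."""

    time: float                 # age (before present)
    kind: str                   # speciation | duplication
    node_name: str
    species_affected: frozenset[str]


@dataclass
class GroundTruth:
    """Full truth of one simulated family."""

    config: SimConfig
    species_tree: LabeledTree
    gene_tree: LabeledTree
    events: list[SimEvent]
    sequences: list[ProteinRecord]
    species_root: _SimNode = field(repr=False, default=None)
    gene_root: _SimNode = field(repr=False, default=None)

    def genes_of(self, species: str) -> list[str]:
        return sorted(r.gene_id for r in self.sequences if r.species_id == species)

    @property
    def species_map(self) -> dict[str, tuple[str, str]]:
        return {r.gene_id: (r.species_id, r.family_id) for r in self.sequences}


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _build_species_tree(cfg: SimConfig, rng: np.random.Generator) -> _SimNode:
    n = cfg.n_species
    lineages = [_SimNode(f"S{i + 1}", 0.0, "leaf", species=f"S{i + 1}")
                for i in range(n)]
    root_p = expected_identity(2.0 * cfg.species_tree_height * cfg.substitution_rate)
    if n == 2 or root_p >= cfg.top_identity:
        # degenerate identity spacing (e.g. near-zero rate): space ages
        # evenly in time instead
        ages = list(np.linspace(cfg.species_tree_height / (n - 1),
                                cfg.species_tree_height, n - 1))
    else:
        levels = np.linspace(cfg.top_identity, root_p, n - 1)
        ages = [divergence_for_identity(p) / (2.0 * cfg.substitution_rate)
                for p in levels]
    for k, age in enumerate(ages, start=1):
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        node = _SimNode(f"N{k}", age, "speciation")
        node.children = [lineages[i], lineages[j]]
        lineages = [ln for idx, ln in enumerate(lineages) if idx not in (i, j)]
        lineages.append(node)
    return lineages[0]


def _graft_duplications(root: _SimNode, cfg: SimConfig) -> _SimNode:
    gene_root = root.clone()
    for branch, rel in cfg.duplication_events:
        target_parent: _SimNode | None = None
        target: _SimNode | None = None
        # graft onto the first (pre-order) non-duplicated copy of the branch
        for node in gene_root.walk():
            for child in node.children:
                if child.name == branch:
                    target_parent, target = node, child
                    break
            if target is not None:
                break
        if target is None:
            if gene_root.name == branch:
                raise ConfigError("cannot place a duplication above the root")
            raise ConfigError(f"duplication branch {branch!r} not in species tree")
        dup_age = target.age + rel * (target_parent.age - target.age)
        dup = _SimNode(f"D_{branch}", dup_age, "duplication")
        copy_sub = target.clone()
        for nd in copy_sub.walk():
            nd.name = nd.name + "'"
        dup.children = [target, copy_sub]
        idx = target_parent.children.index(target)
        target_parent.children[idx] = dup
    return gene_root


def _evolve(root: _SimNode, cfg: SimConfig, rng: np.random.Generator) -> None:
    L = cfg.seq_length
    root.sequence = rng.integers(0, 20, size=L).astype(np.int8)
    for node in root.walk():
        for child in node.children:
            dt = node.age - child.age
            seq = node.sequence.copy()
            n_events = rng.poisson(cfg.substitution_rate * dt, size=L)
            for site in np.nonzero(n_events)[0]:
                state = seq[site]
                for _ in range(n_events[site]):
                    step = int(rng.integers(1, 20))
                    state = (state + step) % 20
                seq[site] = state
            child.sequence = seq


def _assign_families(root: _SimNode, cfg: SimConfig) -> dict[str, str]:
    cut = cfg.family_cut_frac * root.age
    clades: list[list[str]] = []

    def descend(node: _SimNode) -> None:
        if node.age <= cut:
            clades.append(sorted(lf.species for lf in node.leaves()))
        else:
            for c in node.children:
                descend(c)

    descend(root)
    clades.sort(key=lambda c: c[0])
    fam_of: dict[str, str] = {}
    for i, clade in enumerate(clades, start=1):
        for sp in clade:
            fam_of[sp] = f"F{i}"
    return fam_of


def _to_dendropy(root: _SimNode, leaf_attr: str) -> LabeledTree:
    def convert(node: _SimNode) -> dendropy.Node:
        out = dendropy.Node(label=getattr(node, leaf_attr) if not node.children
                            else node.name)
        for c in node.children:
            cn = convert(c)
            cn.edge.length = node.age - c.age
            out.add_child(cn)
        return out

    droot = convert(root)
    labels = [getattr(lf, leaf_attr) for lf in root.leaves()]
    return _new_tree(droot, labels)


def simulate_family(cfg: SimConfig) -> GroundTruth:
    """Generate one family: species tree, gene tree with duplications,
    sequences, and the true event list.  Deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    sp_root = _build_species_tree(cfg, rng)
    gene_root = _graft_duplications(sp_root, cfg)

    # deterministic gene naming: per species, copies in pre-order
    counter: dict[str, int] = {}
    for leaf in gene_root.leaves():
        counter[leaf.species] = counter.get(leaf.species, 0) + 1
        leaf.gene_id = f"{leaf.species}_p{counter[leaf.species]}"

    _evolve(gene_root, cfg, rng)
    fam_of = _assign_families(sp_root, cfg)
    sequences = [
        ProteinRecord(
            gene_id=leaf.gene_id,
            species_id=leaf.species,
            sequence="".join(AA20[i] for i in leaf.sequence),
            family_id=fam_of[leaf.species],
        )
        for leaf in gene_root.leaves()
    ]
    sequences.sort(key=lambda r: r.gene_id)

    events = [
        SimEvent(
            time=node.age,
            kind=node.kind,
            node_name=node.name,
            species_affected=frozenset(lf.species for lf in node.leaves()),
        )
        for node in gene_root.walk()
        if node.children
    ]
    events.sort(key=lambda e: (e.time, e.node_name))
    return GroundTruth(
        config=cfg,
        species_tree=_to_dendropy(sp_root, "species"),
        gene_tree=_to_dendropy(gene_root, "gene_id"),
        events=events,
        sequences=sequences,
        species_root=sp_root,
        gene_root=gene_root,
    )


# ---------------------------------------------------------------------------
# truth -> expectations for the inference modules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpectedEvent:
    """An event as it should appear on a focal gene's lineage chart."""

    hi: float                   # expected identity (= HI, no indels)
    kind: str                   # orthologous | paralogous
    node_name: str
    age: float


_KIND_MAP = {"speciation": ORTHOLOGOUS, "duplication": PARALOGOUS}


@dataclass
class Expectations:
    """Expected chart events per focal gene, plus the expected trees."""

    by_focal: dict[str, list[ExpectedEvent]]
    species_tree: LabeledTree
    all_events: list[ExpectedEvent]

    @property
    def hi_resolution(self) -> float:
        """Smallest expected HI gap between distinct events — events
        closer than this cannot be told apart reliably."""
        his = sorted({e.hi for e in self.all_events})
        if len(his) < 2:
            return 1.0
        return min(b - a for a, b in zip(his, his[1:]))


def truth_to_expectations(gt: GroundTruth) -> Expectations:
    """Map true event times onto expected HI values per focal gene.

    A focal gene's chart shows one event per ancestor of that gene in
    the gene tree (the departure of the other side of the ancestor);
    its expected HI is the identity-decay curve at twice the ancestor's
    age, and its kind follows the node type (speciation -> orthologous,
    duplication -> paralogous).
    """
    rate = gt.config.substitution_rate
    by_focal: dict[str, list[ExpectedEvent]] = {}

    def descend(node: _SimNode, ancestors: list[_SimNode]) -> None:
        if not node.children:
            evts = [
                ExpectedEvent(
                    hi=expected_identity(2.0 * rate * anc.age),
                    kind=_KIND_MAP[anc.kind],
                    node_name=anc.name,
                    age=anc.age,
                )
                for anc in ancestors
            ]
            evts.sort(key=lambda e: e.hi)
            by_focal[node.gene_id] = evts
        else:
            for c in node.children:
                descend(c, ancestors + [node])

    descend(gt.gene_root, [])
    all_events = [
        ExpectedEvent(
            hi=expected_identity(2.0 * rate * e.time),
            kind=_KIND_MAP[e.kind],
            node_name=e.node_name,
            age=e.time,
        )
        for e in gt.events
    ]
    return Expectations(
        by_focal=by_focal, species_tree=gt.species_tree, all_events=all_events
    )


# ---------------------------------------------------------------------------
# scoring recovered events against the truth
# ---------------------------------------------------------------------------

def observed_event_positions(
    chart: LineageChart, graph: HIGraph, events: Sequence[HomologyEvent]
) -> list[float]:
    """The HI at which each recovered event actually happened: the
    strongest edge between the departing and the staying genes (the
    single-linkage merge height), one value per event in order."""
    positions: list[float] = []
    drops = [
        (lo.members - hi.members, hi.members)
        for (t_lo, lo), (t_hi, hi) in zip(chart.points, chart.points[1:])
        if lo.n_genes > hi.n_genes
    ]
    if len(drops) != len(events):
        raise DomainError("events do not correspond to this chart")
    for departing, staying in drops:
        best = max(
            (graph.hi(x, y) for x in departing for y in staying), default=0.0
        )
        positions.append(best)
    return positions


def match_ordered(
    expected_his: Sequence[float],
    recovered_his: Sequence[float],
    skip_penalty: float = 0.08,
) -> list[tuple[int, int]]:
    """Order-preserving one-to-one matching of two descending HI lists.

    Needleman-style alignment minimising the total |ΔHI| of matched
    pairs plus ``skip_penalty`` per unmatched event; the penalty equals
    the designed inter-event spacing, so an event is left unmatched
    rather than pulled more than one spacing away.
    """
    ne, nr = len(expected_his), len(recovered_his)
    INF = float("inf")
    cost = [[INF] * (nr + 1) for _ in range(ne + 1)]
    back = [[None] * (nr + 1) for _ in range(ne + 1)]
    cost[0][0] = 0.0
    for i in range(ne + 1):
        for j in range(nr + 1):
            c = cost[i][j]
            if c == INF:
                continue
            if i < ne and j < nr:
                step = c + abs(expected_his[i] - recovered_his[j])
                if step < cost[i + 1][j + 1]:
                    cost[i + 1][j + 1] = step
                    back[i + 1][j + 1] = "match"
            if i < ne and c + skip_penalty < cost[i + 1][j]:
                cost[i + 1][j] = c + skip_penalty
                back[i + 1][j] = "skip_e"
            if j < nr and c + skip_penalty < cost[i][j + 1]:
                cost[i][j + 1] = c + skip_penalty
                back[i][j + 1] = "skip_r"
    pairs: list[tuple[int, int]] = []
    i, j = ne, nr
    while i > 0 or j > 0:
        move = back[i][j]
        if move == "match":
            i, j = i - 1, j - 1
            pairs.append((i, j))
        elif move == "skip_e":
            i -= 1
        else:
            j -= 1
    return sorted(pairs)


@dataclass
class RecoveryScore:
    """Aggregated kind precision/recall of recovered events."""

    n_correct: int = 0
    n_recovered: int = 0
    n_expected: int = 0

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_recovered if self.n_recovered else 0.0

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_expected if self.n_expected else 0.0

    def add(self, other: "RecoveryScore") -> None:
        self.n_correct += other.n_correct
        self.n_recovered += other.n_recovered
        self.n_expected += other.n_expected


def score_event_recovery(
    expected: Sequence[ExpectedEvent],
    recovered: Sequence[HomologyEvent],
    chart: LineageChart,
    graph: HIGraph,
    skip_penalty: float = 0.08,
) -> RecoveryScore:
    """Kind precision/recall of one chart's recovered events.

    Recovered events are placed at their single-linkage merge HI,
    matched one-to-one (order-preserving) to expected events, and a
    match counts as correct when the kinds agree.
    """
    exp_sorted = sorted(expected, key=lambda e: -e.hi)
    rec_positions = observed_event_positions(chart, graph, recovered)
    order = sorted(range(len(recovered)), key=lambda k: -rec_positions[k])
    rec_sorted = [recovered[k] for k in order]
    rec_his = [rec_positions[k] for k in order]
    pairs = match_ordered([e.hi for e in exp_sorted], rec_his, skip_penalty)
    n_correct = sum(
        1 for i, j in pairs if exp_sorted[i].kind == rec_sorted[j].kind
    )
    return RecoveryScore(
        n_correct=n_correct, n_recovered=len(recovered), n_expected=len(expected)
    )


# ---------------------------------------------------------------------------
# file outputs
# ---------------------------------------------------------------------------

def write_truth(gt: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated bundle: FASTA, sidecar map, truth trees and
    the true event table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = [f"homolineage simulate seed={gt.config.seed}"]
    paths = {
        "fasta": out / "family.faa",
        "map": out / "family.tsv",
        "species_tree": out / "species_tree.nwk",
        "gene_tree": out / "gene_tree.nwk",
        "events": out / "true_events.tsv",
    }
    write_fasta(gt.sequences, paths["fasta"], header_lines=prov)
    write_species_map(gt.sequences, paths["map"], header_lines=prov)
    write_newick(gt.species_tree, paths["species_tree"], comment=prov[0])
    write_newick(gt.gene_tree, paths["gene_tree"], comment=prov[0])
    with open(paths["events"], "w") as fh:
        fh.write(f"# {prov[0]}\n")
        fh.write("time\tkind\tnode\tspecies_affected\n")
        for e in gt.events:
            fh.write(
                f"{repr(e.time)}\t{e.kind}\t{e.node_name}\t"
                f"{';'.join(sorted(e.species_affected))}\n"
            )
    return paths
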