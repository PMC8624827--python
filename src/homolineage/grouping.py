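"""Threshold-sweep homologous gene groups and lineage charts.

A homologous group at threshold ``t`` is a connected component of the
HI graph restricted to edges with ``hi >= t`` (single linkage: this is
the only clustering rule under which "grouping at a threshold" and a
nested lineage are simultaneously well-defined).  Sweeping ``t`` over
the distinct edge HI values yields, for a focal gene, an ordered chart
of the groups that contain it — the gene/species/family count lines of
the lineage figure.  Counts are non-increasing with the threshold
(nestedness), and the chart retains change points only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DomainError, LabelingError, ParseError
from .pairscore import HIGraph

SpeciesMap = Mapping[str, tuple[str, str]]


@dataclass(frozen=True)
class GFHGroup:
    """A homologous gene group at one HI threshold.

    ``n_species <= n_genes`` and ``n_families <= n_species`` hold by
    construction (families partition species).  A family label may be
    empty, in which case each species with an empty label counts as its
    own family.
    """

    threshold: float
    members: frozenset[str]
    n_species: int
    n_families: int

    @property
    def n_genes(self) -> int:
        return len(self.members)


@dataclass
class LineageChart:
    """Ordered lineage of the groups containing a focal gene.

    ``points`` holds ``(threshold, group)`` pairs with strictly
    increasing thresholds, one per change in group membership.
    """

    focal_gene: str
    points: list[tuple[float, GFHGroup]] = field(default_factory=list)

    @property
    def thresholds(self) -> list[float]:
        return [t for t, _ in self.points]

    @property
    def groups(self) -> list[GFHGroup]:
        return [g for _, g in self.points]


def _count_labels(members: Iterable[str], species_map: SpeciesMap) -> tuple[int, int]:
    species: set[str] = set()
    families: set[str] = set()
    for g in members:
        if g not in species_map:
            raise LabelingError(f"gene {g!r} absent from species map")
        sp, fam = species_map[g]
        species.add(sp)
        # unlabeled family -> each species is its own family
        families.add(fam if fam else f"__species__{sp}")
    return len(species), len(families)


def _make_group(members: Iterable[str], t: float, species_map: SpeciesMap) -> GFHGroup:
    members = frozenset(members)
    n_sp, n_fam = _count_labels(members, species_map)
    return GFHGroup(threshold=t, members=members, n_species=n_sp, n_families=n_fam)


def _component(graph: HIGraph, seed: str, t: float) -> set[str]:
    """Connected component of ``seed`` using edges with hi >= t."""
    comp = {seed}
    stack = [seed]
    while stack:
        g = stack.pop()
        for nb, hi in graph.neighbors(g).items():
            if hi >= t and nb not in comp:
                comp.add(nb)
                stack.append(nb)
    return comp


def groups_at_threshold(
    graph: HIGraph, t: float, species_map: SpeciesMap
) -> list[GFHGroup]:
    """All groups (connected components at hi >= t), singletons included.

    Groups are returned sorted by their lexicographically smallest
    member for determinism.
    """
    if not (0.0 <= t <= 1.0):
        raise DomainError(f"threshold {t} outside [0, 1]")
    unseen = set(graph.genes)
    groups: list[GFHGroup] = []
    while unseen:
        seed = unseen.pop()
        comp = _component(graph, seed, t)
        unseen -= comp
        groups.append(_make_group(comp, t, species_map))
    groups.sort(key=lambda g: min(g.members))
    return groups


def sweep_thresholds(
    graph: HIGraph, focal: str, species_map: SpeciesMap
) -> LineageChart:
    """Lineage chart of ``focal`` across all distinct edge HI values.

    Candidate thresholds are 0, 1 and every distinct edge HI (exact
    change points — nothing can happen between two consecutive edge
    values).  Only thresholds at which the membership of the focal
    group changes are retained.
    """
    if focal not in graph:
        raise DomainError(f"focal gene {focal!r} not in graph")
    candidates = sorted({0.0, 1.0} | set(graph.distinct_his()))
    chart = LineageChart(focal_gene=focal)
    prev: frozenset[str] | None = None
    for t in candidates:
        comp = frozenset(_component(graph, focal, t))
        if comp != prev:
            chart.points.append((t, _make_group(comp, t, species_map)))
            prev = comp
    return chart


@dataclass
class GroupCensus:
    """Distinct multi-gene groups formed across the full threshold sweep.

    ``per_threshold`` maps each candidate threshold to the number of
    groups of size >= 2 present at it; ``distinct_groups`` holds each
    distinct member set once, regardless of how many thresholds it
    persists through.
    """

    per_threshold: dict[float, int] = field(default_factory=dict)
    distinct_groups: set[frozenset[str]] = field(default_factory=set)

    @property
    def n_distinct(self) -> int:
        return len(self.distinct_groups)


def group_census(graph: HIGraph) -> GroupCensus:
    """Census of multi-gene groups over the sweep (deduplicated by
    member set).  An empty graph yields an empty census."""
    census = GroupCensus()
    if graph.n_edges == 0:
        return census
    candidates = sorted({0.0} | set(graph.distinct_his()))
    for t in candidates:
        unseen = set(graph.genes)
        n_multi = 0
        while unseen:
            seed = unseen.pop()
            comp = _component(graph, seed, t)
            unseen -= comp
            if len(comp) >= 2:
                n_multi += 1
                census.distinct_groups.add(frozenset(comp))
        census.per_threshold[t] = n_multi
    return census


# ---------------------------------------------------------------------------
# chart TSV export (the data behind the lineage line chart)
# ---------------------------------------------------------------------------

_CHART_COLUMNS = ["threshold", "n_genes", "n_species", "n_families", "member_ids"]


def write_chart_tsv(
    chart: LineageChart, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# focal_gene={chart.focal_gene}\n")
        fh.write("\t".join(_CHART_COLUMNS) + "\n")
        for t, grp in chart.points:
            fh.write(
                "\t".join(
                    [
                        repr(t),
                        str(grp.n_genes),
                        str(grp.n_species),
                        str(grp.n_families),
                        ";".join(sorted(grp.members)),
                    ]
                )
                + "\n"
            )


def read_chart_tsv(path: str | Path) -> LineageChart:
    """Re-read a chart written by :func:`write_chart_tsv`.

    Counts are taken from the file (no species map needed), so a chart
    round-trips exactly.
    """
    focal = ""
    points: list[tuple[float, GFHGroup]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("# focal_gene="):
                focal = line.split("=", 1)[1]
                continue
            if not line.strip() or line.startswith("#"):
                continue
            if line.split("\t")[0] == "threshold":
                continue
            fields = line.split("\t")
            if len(fields) != len(_CHART_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_CHART_COLUMNS)} columns")
            try:
                t = float(fields[0])
                n_genes = int(fields[1])
                n_species = int(fields[2])
                n_families = int(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            members = frozenset(fields[4].split(";")) if fields[4] else frozenset()
            if len(members) != n_genes:
                raise ParseError(
                    f"{path}:{lineno}: n_genes={n_genes} but {len(members)} member ids"
                )
            points.append(
                (t, GFHGroup(threshold=t, members=members, n_species=n_species,
                             n_families=n_families))
            )
    if not focal:
        raise ParseError(f"{path}: missing '# focal_gene=' header")
    return LineageChart(focal_gene=focal, points=points)
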