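"""Ortholog/paralog event classification along a lineage chart.

Reading a lineage chart from low to high threshold (recent history
last), every drop in the gene count marks a homologous event in that
threshold interval.  If the species count dropped too, lineages of
different species separated — an orthologous event (speciation); if the
species count is unchanged, copies within the same genomes separated —
a paralogous event (duplication).  The rule is applied literally to
each adjacent pair of chart points; an orthologous interval in which
more genes than species departed is flagged as *mixed* (paralog loss
may have co-occurred).

When paralogous events co-occur across many genes of one species in
the same HI interval, that is the signature of a whole- or
partial-genome duplication rather than a localized (e.g.
transposition-driven) one; :func:`duplication_signature` quantifies
this fraction per interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ContractError, DomainError
from .grouping import LineageChart

ORTHOLOGOUS = "orthologous"
PARALOGOUS = "paralogous"


@dataclass(frozen=True)
class HomologyEvent:
    """One inferred divergence event in the interval (t_low, t_high].

    ``delta_genes`` genes (and ``delta_species`` species) left the
    focal group as the threshold rose past the interval.  ``magnitude``
    is "major" when the departing set held at least ``major_frac`` of
    the group's genes, else "minor".  ``mixed`` marks orthologous
    events whose gene loss exceeds the species loss.
    """

    t_low: float
    t_high: float
    kind: str
    delta_genes: int
    delta_species: int
    magnitude: str
    mixed: bool = False

    def __post_init__(self) -> None:
        if self.t_low >= self.t_high:
            raise ContractError(f"t_low {self.t_low} must be < t_high {self.t_high}")
        if self.delta_genes < 1:
            raise ContractError("an event requires delta_genes >= 1")
        if self.kind == PARALOGOUS and self.delta_species != 0:
            raise ContractError("paralogous event must have delta_species == 0")
        if self.kind == ORTHOLOGOUS and self.delta_species < 1:
            raise ContractError("orthologous event must have delta_species >= 1")


def _check_chart(chart: LineageChart) -> None:
    prev_t = -1.0
    prev_members = None
    for t, grp in chart.points:
        if t <= prev_t:
            raise ContractError(f"chart thresholds not strictly increasing at {t}")
        if chart.focal_gene not in grp.members:
            raise ContractError(f"focal gene missing from group at threshold {t}")
        if prev_members is not None and not grp.members <= prev_members:
            raise ContractError(f"chart not nested at threshold {t}")
        prev_t, prev_members = t, grp.members


def classify_events(chart: LineageChart, major_frac: float = 0.25) -> list[HomologyEvent]:
    """Classify every gene-count drop along the chart.

    One event per adjacent point pair with strictly decreasing
    ``n_genes``; flat segments emit nothing.  Raises
    :class:`ContractError` for a chart violating nestedness.
    """
    if not (0.0 < major_frac <= 1.0):
        raise DomainError(f"major_frac {major_frac} outside (0, 1]")
    _check_chart(chart)
    events: list[HomologyEvent] = []
    for (t_lo, g_lo), (t_hi, g_hi) in zip(chart.points, chart.points[1:]):
        dg = g_lo.n_genes - g_hi.n_genes
        if dg < 1:
            continue
        ds = g_lo.n_species - g_hi.n_species
        kind = ORTHOLOGOUS if ds >= 1 else PARALOGOUS
        magnitude = "major" if dg >= major_frac * g_lo.n_genes else "minor"
        events.append(
            HomologyEvent(
                t_low=t_lo,
                t_high=t_hi,
                kind=kind,
                delta_genes=dg,
                delta_species=ds,
                magnitude=magnitude,
                mixed=(kind == ORTHOLOGOUS and dg > ds),
            )
        )
    return events


# ---------------------------------------------------------------------------
# genome-level vs. localized duplication signature
# ---------------------------------------------------------------------------

@dataclass
class DuplicationReport:
    """Per-interval fraction of a species' genes with a paralogous event.

    ``intervals`` lists ``(t_low, t_high, fraction)`` over the
    elementary intervals spanned by any paralogous event;
    ``flagged`` repeats those whose fraction reaches the configured
    genome-duplication candidate threshold.
    """

    species_id: str
    n_charts: int
    intervals: list[tuple[float, float, float]] = field(default_factory=list)
    flagged: list[tuple[float, float, float]] = field(default_factory=list)


def duplication_signature(
    charts: Sequence[LineageChart],
    species: str,
    species_map: Mapping[str, tuple[str, str]],
    flag_frac: float = 0.5,
    major_frac: float = 0.25,
) -> DuplicationReport:
    """Fraction of the species' gene lineages showing a paralogous
    event per HI interval; intervals at or above ``flag_frac`` are
    genome-level-duplication candidates.

    All charts must come from the same HI graph; only charts whose
    focal gene belongs to ``species`` contribute.
    """
    own = [c for c in charts if c.focal_gene in species_map
           and species_map[c.focal_gene][0] == species]
    if not own:
        raise DomainError(f"species {species!r} absent from all charts")
    para_intervals: list[list[tuple[float, float]]] = []
    for chart in own:
        para_intervals.append(
            [(e.t_low, e.t_high) for e in classify_events(chart, major_frac=major_frac)
             if e.kind == PARALOGOUS]
        )
    report = DuplicationReport(species_id=species, n_charts=len(own))
    bounds = sorted({b for ivs in para_intervals for iv in ivs for b in iv})
    for lo, hi in zip(bounds, bounds[1:]):
        covered = sum(
            1 for ivs in para_intervals
            if any(a <= lo and hi <= b for a, b in ivs)
        )
        if covered == 0:
            continue
        frac = covered / len(own)
        report.intervals.append((lo, hi, frac))
        if frac >= flag_frac:
            report.flagged.append((lo, hi, frac))
    return report


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["t_high", "t_low", "kind", "delta_genes", "delta_species",
                  "magnitude", "mixed"]


def write_events_tsv(
    events: Iterable[HomologyEvent], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for e in events:
            fh.write(
                "\t".join(
                    [repr(e.t_high), repr(e.t_low), e.kind, str(e.delta_genes),
                     str(e.delta_species), e.magnitude, str(int(e.mixed))]
                )
                + "\n"
            )
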