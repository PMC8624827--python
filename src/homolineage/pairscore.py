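"""Pairwise protein similarity and the homology index (HI).

The homology index maps one pairwise protein alignment onto ``[0, 1]``:

    HI = min(1, 2 * (pident / 100) * aln_len / (qlen + slen))

i.e. the number of identical aligned columns normalised by the mean of
the two sequence lengths.  A full-length identical match scores exactly
1, unrelated sequences score 0, and the index is computable from a
single line of BLAST tabular output produced with
``-outfmt '6 std qlen slen'`` (12 standard columns plus query and
subject length).

This module covers three routes to an HI:

* :func:`read_blast_tabular` — parse precomputed search output in the
  14-column tabular dialect (authoritative when supplied);
* :func:`align_pair` / :func:`all_vs_all_hits` — an internal
  Smith-Waterman / Needleman-Wunsch aligner (BLOSUM62, affine gaps
  11/1) for desk-scale inputs with no external search tool;
* :func:`build_hi_graph` — assemble hits into the symmetric
  :class:`HIGraph` that every downstream module consumes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import DomainError, LabelingError, ParseError, ValidationError

# IUPAC one-letter amino-acid codes (incl. ambiguity codes B/Z/J and X).
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZJUOX*-")

#: columns of ``-outfmt '6 std qlen slen'``
BLAST_TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen slen"
).split()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species (and optional family) label.

    ``gene_id`` must be unique within a dataset; ``sequence`` is a
    non-empty IUPAC amino-acid string (``X`` permitted).
    """

    gene_id: str
    species_id: str
    sequence: str
    family_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.gene_id}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.gene_id}: non-amino-acid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairHit:
    """One pairwise alignment record and its derived homology index.

    ``aln_len == 0`` is permitted only for the degenerate "no positive-
    scoring local alignment" case, in which ``pident`` and ``hi`` are 0.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    qlen: int
    slen: int
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: pident {self.pident} "
                "outside [0, 100]"
            )
        if self.qlen < 1 or self.slen < 1:
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: sequence lengths must be >= 1"
            )
        if self.aln_len < 0 or (self.aln_len == 0 and self.hi != 0.0):
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: empty alignment must have hi == 0"
            )
        if not (0.0 <= self.hi <= 1.0):
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: hi {self.hi} outside [0, 1]"
            )

    @property
    def is_self(self) -> bool:
        """True for a self-hit (query and subject are the same gene)."""
        return self.query_id == self.subject_id


# ---------------------------------------------------------------------------
# the homology index
# ---------------------------------------------------------------------------

def compute_hi(pident: float, aln_len: int, qlen: int, slen: int) -> float:
    """Homology index of one alignment line.

    Parameters mirror the BLAST tabular columns: percent identity in
    ``[0, 100]``, alignment length in columns, and the two full
    sequence lengths.  Deterministic; raises :class:`DomainError` for
    non-positive lengths and :class:`ValidationError` for an
    out-of-range identity.
    """
    if aln_len < 1 or qlen < 1 or slen < 1:
        raise DomainError(
            f"alignment/sequence lengths must be positive, got "
            f"aln_len={aln_len} qlen={qlen} slen={slen}"
        )
    if not (0.0 <= pident <= 100.0):
        raise ValidationError(f"pident {pident} outside [0, 100]")
    return min(1.0, 2.0 * (pident / 100.0) * aln_len / (qlen + slen))


# ---------------------------------------------------------------------------
# BLAST tabular I/O ('6 std qlen slen' dialect; '#' comment lines ignored)
# ---------------------------------------------------------------------------

def read_blast_tabular(path: str | Path) -> list[PairHit]:
    """Read hits from 14-column BLAST tabular output.

    Every line yields one :class:`PairHit` with its HI computed by
    :func:`compute_hi`.  Self-hits are retained (flagged via
    :attr:`PairHit.is_self`) so callers can validate inputs;
    :func:`build_hi_graph` drops them.  Malformed lines raise
    :class:`ParseError` naming the line number.
    """
    hits: list[PairHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST_TABULAR_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(BLAST_TABULAR_COLUMNS)} "
                    f"tab-separated columns, found {len(fields)}"
                )
            try:
                pident = float(fields[2])
                aln_len = int(fields[3])
                qlen = int(fields[12])
                slen = int(fields[13])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if not (0.0 <= pident <= 100.0):
                raise ValidationError(
                    f"{path}:{lineno}: pident {pident} outside [0, 100]"
                )
            hits.append(
                PairHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pident=pident,
                    aln_len=aln_len,
                    qlen=qlen,
                    slen=slen,
                    hi=compute_hi(pident, aln_len, qlen, slen),
                )
            )
    return hits


def write_blast_tabular(
    hits: Iterable[PairHit], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write hits in the 14-column dialect.

    ``pident`` is written with full precision (``repr``) so that
    re-reading reproduces the HI exactly; the standard columns that a
    :class:`PairHit` does not model (mismatch, gapopen, coordinates,
    evalue, bitscore) are filled with neutral placeholders.  Degenerate
    no-alignment hits (``aln_len == 0``) are skipped — as in a real
    search, a pair without an alignment has no tabular line.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for h in hits:
            if h.aln_len == 0:
                continue
            mism = max(0, h.aln_len - round(h.aln_len * h.pident / 100.0))
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        repr(h.pident),
                        str(h.aln_len),
                        str(mism),
                        "0",
                        "1",
                        str(max(1, h.aln_len)),
                        "1",
                        str(max(1, h.aln_len)),
                        "0.0",
                        "0",
                        str(h.qlen),
                        str(h.slen),
                    ]
                )
                + "\n"
            )


def per_query_hit_counts(hits: Iterable[PairHit]) -> dict[str, int]:
    """Hit count per query — lets users spot externally truncated
    searches (e.g. a ``-max_target_seqs`` ceiling)."""
    return dict(Counter(h.query_id for h in hits))


# ---------------------------------------------------------------------------
# internal aligner
# ---------------------------------------------------------------------------

def make_aligner(
    mode: str = "local",
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> PairwiseAligner:
    """Aligner with classical protein-search scoring.

    Affine gap cost ``open + k * extend`` for a gap of length ``k``
    (hence Biopython's first-position score is ``-(open + extend)``).
    """
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    mode: str = "local",
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> PairHit:
    """Align two proteins and derive their HI.

    Symmetric by construction: the pair is aligned in a canonical
    (lexicographic) order, so ``align_pair(a, b).hi ==
    align_pair(b, a).hi`` even when co-optimal alignments exist.  A
    local alignment with no positive-scoring pair yields ``hi == 0``.
    """
    if not a.sequence or not b.sequence:
        raise DomainError("cannot align empty sequences")
    aligner = make_aligner(mode=mode, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)

    first, second = (a, b) if a.gene_id <= b.gene_id else (b, a)
    score = aligner.score(first.sequence, second.sequence)
    if mode == "local" and score <= 0:
        return PairHit(a.gene_id, b.gene_id, 0.0, 0, len(a), len(b), 0.0)
    aln = aligner.align(first.sequence, second.sequence)[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / aln_len
    return PairHit(
        query_id=a.gene_id,
        subject_id=b.gene_id,
        pident=pident,
        aln_len=aln_len,
        qlen=len(a),
        slen=len(b),
        hi=compute_hi(pident, aln_len, len(a), len(b)),
    )


def all_vs_all_hits(records: Iterable[ProteinRecord], **aligner_kwargs) -> list[PairHit]:
    """Exhaustive all-vs-all hits over a record set (self-pairs skipped).

    Unlike an external search there is no hit-count truncation; one hit
    per unordered pair.
    """
    recs = list(records)
    seen = Counter(r.gene_id for r in recs)
    dupes = [g for g, n in seen.items() if n > 1]
    if dupes:
        raise ValidationError(f"duplicate gene_id(s): {sorted(dupes)[:5]}")
    return [align_pair(x, y, **aligner_kwargs) for x, y in combinations(recs, 2)]


# ---------------------------------------------------------------------------
# the HI graph
# ---------------------------------------------------------------------------

class HIGraph:
    """Symmetric gene-gene graph weighted by HI.

    Edges are stored under unordered keys, self-edges are rejected, and
    only ``hi > 0`` is stored, so the invariants of the type hold by
    construction.  Repeated insertion of a pair keeps the maximum HI.
    """

    __slots__ = ("_adj",)

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}

    # -- construction ------------------------------------------------------
    def add_gene(self, gene_id: str) -> None:
        self._adj.setdefault(gene_id, {})

    def add_edge(self, a: str, b: str, hi: float) -> None:
        """Insert an undirected edge, collapsing duplicates by max HI."""
        if not (0.0 <= hi <= 1.0):
            raise ValidationError(f"hi {hi} outside [0, 1] for pair ({a}, {b})")
        self.add_gene(a)
        self.add_gene(b)
        if a == b or hi == 0.0:
            return
        cur = self._adj[a].get(b, 0.0)
        if hi > cur:
            self._adj[a][b] = hi
            self._adj[b][a] = hi

    # -- queries -----------------------------------------------------------
    @property
    def genes(self) -> set[str]:
        return set(self._adj)

    @property
    def n_genes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._adj

    def hi(self, a: str, b: str) -> float:
        """HI of a pair; 1.0 for a gene with itself, 0.0 if unlinked."""
        if a == b and a in self._adj:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, gene_id: str) -> Mapping[str, float]:
        if gene_id not in self._adj:
            raise DomainError(f"unknown gene {gene_id!r}")
        return dict(self._adj[gene_id])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Each undirected edge once, with endpoints in sorted order."""
        for a in self._adj:
            for b, hi in self._adj[a].items():
                if a < b:
                    yield a, b, hi

    def distinct_his(self) -> list[float]:
        """Sorted distinct edge HI values (ascending)."""
        return sorted({hi for _, _, hi in self.edges()})

    def subgraph(self, members: Iterable[str]) -> "HIGraph":
        keep = set(members)
        missing = keep - self.genes
        if missing:
            raise DomainError(f"genes not in graph: {sorted(missing)[:5]}")
        sub = HIGraph()
        for g in keep:
            sub.add_gene(g)
        for a, b, hi in self.edges():
            if a in keep and b in keep:
                sub.add_edge(a, b, hi)
        return sub


def build_hi_graph(hits: Iterable[PairHit]) -> HIGraph:
    """Assemble hits into an :class:`HIGraph`.

    Self-hits are dropped; duplicate/bidirectional hits collapse to the
    maximum HI; genes appearing only in zero-HI hits are kept as
    isolated nodes.  An empty hit list yields an empty graph.
    """
    graph = HIGraph()
    for h in hits:
        graph.add_edge(h.query_id, h.subject_id, h.hi)
    return graph


# ---------------------------------------------------------------------------
# FASTA + sidecar species/family map
# ---------------------------------------------------------------------------

def read_species_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the sidecar TSV ``gene_id<TAB>species_id[<TAB>family_id]``.

    Returns ``{gene_id: (species_id, family_id)}``; a missing family
    column yields an empty family string.  '#' comment lines ignored.
    """
    mapping: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns"
                )
            gene, species = fields[0], fields[1]
            family = fields[2] if len(fields) > 2 else ""
            if gene in mapping:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene!r}")
            mapping[gene] = (species, family)
    return mapping


def read_fasta(
    path: str | Path, species_map: Mapping[str, tuple[str, str]] | None = None
) -> list[ProteinRecord]:
    """Read protein FASTA; the first whitespace-delimited token of each
    header is the gene ID.  With a species map, every record must be
    mapped (else :class:`LabelingError`)."""
    records: list[ProteinRecord] = []
    # fasta-pearson tolerates the ';' provenance comments our writer emits
    for rec in SeqIO.parse(str(path), "fasta-pearson"):
        gene_id = rec.id
        species_id, family_id = "", ""
        if species_map is not None:
            if gene_id not in species_map:
                raise LabelingError(f"gene {gene_id!r} absent from species map")
            species_id, family_id = species_map[gene_id]
        records.append(ProteinRecord(gene_id, species_id, str(rec.seq), family_id))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[ProteinRecord], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write records as FASTA (60-column wrap); optional ';' comment
    header lines precede the first record."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"; {line}\n")
        for rec in records:
            fh.write(f">{rec.gene_id} {rec.species_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_species_map(
    records: Iterable[ProteinRecord], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.species_id}\t{rec.family_id}\n")
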