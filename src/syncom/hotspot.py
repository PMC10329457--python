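"""Clade-specific genomic hotspot discovery from orthogroup prevalence.

Orthogroups present in every focal-clade genome but rare (< ``max_bg_prev``
fraction) in the background are selected; on a chosen reference genome,
selected genes are assembled into hotspots by merging neighbours whose
intervening distance is below a gap threshold, and runs with enough
distinct orthogroups are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """One gene on one scaffold; coordinates 1-based inclusive."""

    gene_id: str
    genome_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    orthogroup_id: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"gene {self.gene_id}: need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class OrthogroupTable:
    """Orthogroup id -> set of (genome id, gene id) memberships."""

    members: dict[str, set[tuple[str, str]]]
    genome_universe: set[str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og, pairs in self.members.items():
            for genome, gene in pairs:
                if gene in seen and seen[gene] != og:
                    raise ValueError(f"gene {gene} mapped to multiple orthogroups")
                seen[gene] = og
        referenced = {g for pairs in self.members.values() for g, _ in pairs}
        if not referenced <= self.genome_universe:
            raise ValueError("genome universe must contain all referenced genomes")

    def genomes_with(self, og: str) -> set[str]:
        return {genome for genome, _ in self.members.get(og, set())}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthogroupTable":
        """Build from a (gene_id, genome_id, orthogroup_id) table."""
        members: dict[str, set[tuple[str, str]]] = {}
        for row in df.itertuples(index=False):
            members.setdefault(str(row.orthogroup_id), set()).add(
                (str(row.genome_id), str(row.gene_id))
            )
        return cls(members=members, genome_universe=set(df["genome_id"].astype(str)))


@dataclass
class CladeSpecificSelection:
    selected: set[str]
    focal: set[str]
    background: set[str]
    focal_prevalence: dict[str, float]
    background_prevalence: dict[str, float]
    max_bg_prev: float


@dataclass
class Hotspot:
    hotspot_id: int
    scaffold_id: str
    start: int
    end: int
    genes: list[GeneRecord] = field(default_factory=list)

    @property
    def orthogroup_ids(self) -> list[str]:
        seen: list[str] = []
        for g in self.genes:
            if g.orthogroup_id is not None and g.orthogroup_id not in seen:
                seen.append(g.orthogroup_id)
        return seen

    @property
    def gene_count(self) -> int:
        return len(self.genes)


def select_clade_specific(
    og: OrthogroupTable,
    focal: set[str],
    background: set[str],
    max_bg_prev: float = 0.05,
) -> CladeSpecificSelection:
    """Orthogroups core to the focal clade and rare in the background.

    Selected iff present (>= 1 member gene) in 100% of focal genomes and in
    strictly fewer than ``max_bg_prev`` fraction of background genomes.
    Prevalence counts genomes, not gene copies.
    """
    focal, background = set(focal), set(background)
    if not focal:
        raise ValueError("focal genome set must be non-empty")
    if focal & background:
        raise ValueError(f"focal and background overlap: {sorted(focal & background)}")
    n_bg = len(background)
    focal_prev: dict[str, float] = {}
    bg_prev: dict[str, float] = {}
    selected: set[str] = set()
    for og_id in og.members:
        carriers = og.genomes_with(og_id)
        fp = len(carriers & focal) / len(focal)
        bp = len(carriers & background) / n_bg if n_bg else 0.0
        focal_prev[og_id] = fp
        bg_prev[og_id] = bp
        if fp == 1.0 and bp < max_bg_prev:
            selected.add(og_id)
    return CladeSpecificSelection(
        selected=selected,
        focal=focal,
        background=background,
        focal_prevalence=focal_prev,
        background_prevalence=bg_prev,
        max_bg_prev=max_bg_prev,
    )


def assemble_hotspots(
    genes: list[GeneRecord],
    selection: CladeSpecificSelection,
    gap_bp: int = 10_000,
    min_genes: int = 10,
    count: str = "orthogroups",
    inclusive: bool = True,
) -> list[Hotspot]:
    """Greedy per-scaffold assembly of selected genes into hotspots.

    Genes whose orthogroup is in ``selection`` are sorted by start on each
    scaffold; a run extends while the intervening distance to the next gene
    (next.start - run.end - 1) is strictly below ``gap_bp``. Runs pass the
    size filter when their distinct-orthogroup count (``count="orthogroups"``,
    default) or gene count (``count="genes"``) is >= ``min_genes``
    (``inclusive=True``) or > ``min_genes`` otherwise. Hotspot ids are
    assigned in genome order over the reported runs.
    """
    if count not in ("orthogroups", "genes"):
        raise ValueError("count must be 'orthogroups' or 'genes'")
    genomes = {g.genome_id for g in genes}
    if len(genomes) > 1:
        raise ValueError(f"genes from multiple genomes: {sorted(genomes)}")
    picked = [g for g in genes if g.orthogroup_id in selection.selected]
    runs: list[Hotspot] = []
    for scaffold in sorted({g.scaffold_id for g in picked}):
        on_scaffold = sorted(
            (g for g in picked if g.scaffold_id == scaffold),
            key=lambda g: (g.start, g.end, g.gene_id),
        )
        current: list[GeneRecord] = []
        run_end = 0
        for g in on_scaffold:
            if current and (g.start - run_end - 1) >= gap_bp:
                runs.append(_make_run(scaffold, current))
                current = []
            current.append(g)
            run_end = max(run_end, g.end)
        if current:
            runs.append(_make_run(scaffold, current))
    reported = []
    for run in runs:
        size = len(run.orthogroup_ids) if count == "orthogroups" else run.gene_count
        if size >= min_genes if inclusive else size > min_genes:
            reported.append(run)
    reported.sort(key=lambda h: (h.scaffold_id, h.start))
    for i, h in enumerate(reported, start=1):
        h.hotspot_id = i
    return reported


def _make_run(scaffold: str, members: list[GeneRecord]) -> Hotspot:
    return Hotspot(
        hotspot_id=0,
        scaffold_id=scaffold,
        start=min(g.start for g in members),
        end=max(g.end for g in members),
        genes=list(members),
    )


def interval_length_kb(start: int, end: int) -> int:
    """Inclusive 1-based interval length in kb, rounded half-up."""
    if start < 1 or start > end:
        raise ValueError(f"need 1 <= start <= end, got {start}..{end}")
    length_bp = end - start + 1
    return int((length_bp + 500) // 1000)


def interval_intersect(
    a: tuple[int, int],
    b: tuple[int, int],
    scaffold_a: str | None = None,
    scaffold_b: str | None = None,
) -> tuple[int, int] | None:
    """Closed-interval intersection, or None when disjoint.

    When scaffold ids are supplied and differ, returns None with a warning.
    """
    for iv in (a, b):
        if iv[0] > iv[1]:
            raise ValueError(f"invalid interval {iv}")
    if scaffold_a is not None and scaffold_b is not None and scaffold_a != scaffold_b:
        logger.warning("intersecting intervals on different scaffolds: %s vs %s",
                       scaffold_a, scaffold_b)
        return None
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo <= hi else None


def genes_in_interval(
    genes: list[GeneRecord], scaffold_id: str, interval: tuple[int, int]
) -> list[GeneRecord]:
    """Genes fully contained in a closed interval on one scaffold."""
    lo, hi = interval
    return sorted(
        (g for g in genes
         if g.scaffold_id == scaffold_id and g.start >= lo and g.end <= hi),
        key=lambda g: g.start,
    )


def hotspot_report(
    hotspots: list[Hotspot],
    og: OrthogroupTable,
    selection: CladeSpecificSelection,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-hotspot summary and a genome x hotspot presence fraction matrix.

    A genome's presence value for a hotspot is the fraction of that
    hotspot's orthogroups for which the genome carries >= 1 member gene.
    """
    summary_cols = [
        "hotspot_id", "scaffold", "start", "end", "gene_count",
        "orthogroup_count", "orthogroups",
    ]
    genomes = sorted(selection.focal | selection.background)
    rows = []
    presence: dict[int, list[float]] = {}
    for h in hotspots:
        ogs = h.orthogroup_ids
        rows.append({
            "hotspot_id": h.hotspot_id,
            "scaffold": h.scaffold_id,
            "start": h.start,
            "end": h.end,
            "gene_count": h.gene_count,
            "orthogroup_count": len(ogs),
            "orthogroups": ",".join(ogs),
        })
        carriers = [og.genomes_with(o) for o in ogs]
        presence[h.hotspot_id] = [
            sum(genome in c for c in carriers) / len(ogs) if ogs else 0.0
            for genome in genomes
        ]
    summary = pd.DataFrame(rows, columns=summary_cols)
    matrix = pd.DataFrame(
        presence, index=pd.Index(genomes, name="genome_id"),
        columns=sorted(presence),
    )
    matrix.columns = [f"hotspot_{c}" for c in matrix.columns]
    return summary, matrix
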