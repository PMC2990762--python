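"""Mutual-Rank ranked-list analysis: per-bait co-expression lists, average
MR by geometric mean, multi-bait intersections and Pfam-group summaries.

Mutual Rank (MR) is a symmetric co-expression statistic: each gene's rank
in the other's correlation-ordered neighbor list, combined geometrically —
lower MR means tighter co-expression.  Ranked lists (typically the top 300
neighbors of a bait gene) are consumed as published; this module never
recomputes MR from expression data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._ids import normalize_gene_id, species_of
from .annotations import DomainAssignment, PfamLocalizationTable
from .predictor import call_localization, score_protein

#: Default average-MR cutoff for retaining a Pfam group (strictly below).
DEFAULT_GROUP_CUTOFF = 70.0


@dataclass
class RankedCoexpressionList:
    """One bait gene's neighbors ordered by increasing Mutual Rank."""

    bait_id: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: e[1])
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"duplicate gene(s) in list for {self.bait_id}: {dupes}")
        for g, mr in self.entries:
            if mr < 1.0:
                raise ValueError(f"mutual rank below 1 for {g}: {mr}")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def mr_of(self, gene_id: str) -> float | None:
        for g, mr in self.entries:
            if g == gene_id:
                return mr
        return None

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "rank": range(1, len(self.entries) + 1),
                "gene_id": [g for g, _ in self.entries],
                "mutual_rank": [mr for _, mr in self.entries],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def load_ranked_list(path: str | Path, bait_id: str) -> RankedCoexpressionList:
    """Read one bait's ranked list from TSV (columns gene_id, mutual_rank).

    Identifiers are normalized (AGI uppercased, RAP casing preserved); rows
    are re-sorted by MR; a duplicated gene raises a validation error naming
    the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = {"gene_id", "mutual_rank"} - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing column(s) {sorted(missing)}")
    entries = [
        (normalize_gene_id(g), float(mr))
        for g, mr in zip(df["gene_id"], df["mutual_rank"])
    ]
    return RankedCoexpressionList(bait_id=normalize_gene_id(bait_id), entries=entries)


def average_mutual_rank(mrs: Sequence[float]) -> float:
    """Geometric mean of per-bait Mutual Ranks: (prod mrs)^(1/n)."""
    if not mrs:
        raise ValueError("need at least one mutual rank")
    if any(m <= 0 for m in mrs):
        raise ValueError("mutual ranks must be positive")
    return math.exp(math.fsum(math.log(m) for m in mrs) / len(mrs))


def max_mr(ranked: RankedCoexpressionList) -> float:
    """The largest MR in the list — the MR of its last (e.g. 300th) gene.

    Measures the tightness of the bait's co-expression neighborhood: a low
    maximum MR means even the list's tail is strongly co-expressed.
    """
    if not ranked.entries:
        raise ValueError(f"ranked list for {ranked.bait_id} is empty")
    return ranked.entries[-1][1]


@dataclass
class GeneCoexpressionSummary:
    """One gene shared across every bait list, with its average MR."""

    gene_id: str
    mr_by_bait: dict[str, float]
    average_mr: float
    is_bait: bool = False


@dataclass
class IntersectionReport:
    """Pairwise and k-way overlaps across bait lists (the Venn counts)."""

    bait_ids: tuple[str, ...]
    pairwise_counts: dict[frozenset, int]
    kway_count: int
    shared_genes: list[GeneCoexpressionSummary]
    list_lengths: dict[str, int] = field(default_factory=dict)
    union_size: int = 0

    def __post_init__(self) -> None:
        if self.pairwise_counts and self.kway_count > min(self.pairwise_counts.values()):
            raise ValueError("k-way overlap exceeds a pairwise overlap")
        if self.kway_count != len(self.shared_genes):
            raise ValueError("kway_count must equal |shared_genes|")

    def shared_fraction(self, denominator: str = "list") -> float:
        """k-way overlap over the (smallest) list length or the union size.

        Published "ca. N%" shared-gene figures are ambiguous between the
        two denominators, so both are offered.
        """
        if denominator == "list":
            d = min(self.list_lengths.values()) if self.list_lengths else 0
        elif denominator == "union":
            d = self.union_size
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        return self.kway_count / d if d else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": s.gene_id,
                **{f"mr_{b}": s.mr_by_bait[b] for b in self.bait_ids},
                "average_mr": s.average_mr,
                "is_bait": s.is_bait,
            }
            for s in self.shared_genes
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_id", *(f"mr_{b}" for b in self.bait_ids), "average_mr", "is_bait"],
        )

    def venn_rows(self) -> list[dict]:
        rows = [
            {"baits": " & ".join(sorted(pair)), "shared": n}
            for pair, n in sorted(self.pairwise_counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        rows.append({"baits": " & ".join(self.bait_ids), "shared": self.kway_count})
        return rows


def intersect_ranked_lists(
    lists: Sequence[RankedCoexpressionList],
) -> IntersectionReport:
    """Venn analysis over >= 2 bait lists.

    Shared genes (present in every list) carry their per-bait MRs and the
    geometric-mean average MR, sorted by average MR.  Bait genes that are
    themselves shared are retained and flagged via ``is_bait``, so counts
    can be read with either convention.
    """
    if len(lists) < 2:
        raise ValueError("need at least two ranked lists to intersect")
    baits = tuple(l.bait_id for l in lists)
    if len(set(baits)) != len(baits):
        raise ValueError("bait ids must be distinct")
    sets = {l.bait_id: set(l.gene_ids) for l in lists}
    pairwise = {
        frozenset((a, b)): len(sets[a] & sets[b]) for a, b in combinations(baits, 2)
    }
    common = set.intersection(*sets.values())
    mr_maps = {l.bait_id: dict(l.entries) for l in lists}
    shared = [
        GeneCoexpressionSummary(
            gene_id=g,
            mr_by_bait={b: mr_maps[b][g] for b in baits},
            average_mr=average_mutual_rank([mr_maps[b][g] for b in baits]),
            is_bait=g in baits,
        )
        for g in common
    ]
    shared.sort(key=lambda s: (s.average_mr, s.gene_id))
    return IntersectionReport(
        bait_ids=baits,
        pairwise_counts=pairwise,
        kway_count=len(common),
        shared_genes=shared,
        list_lengths={b: len(sets[b]) for b in baits},
        union_size=len(set.union(*sets.values())),
    )


@dataclass
class PfamGroupSummary:
    """Genes from a shared set grouped by their joint Pfam-domain set."""

    pfam_id_set: frozenset[str]
    gene_ids: list[str]
    gene_counts_by_species: dict[str, int]
    min_average_mr: float
    predicted_location: str = ""
    predicted_score: float = float("nan")

    @property
    def label(self) -> str:
        return ", ".join(sorted(self.pfam_id_set)) if self.pfam_id_set else "unassigned"


def group_by_pfam(
    shared_genes: Sequence[GeneCoexpressionSummary],
    assignments: Sequence[DomainAssignment],
    cutoff: float = DEFAULT_GROUP_CUTOFF,
    *,
    table: PfamLocalizationTable | None = None,
) -> list[PfamGroupSummary]:
    """Group shared genes by their full joint Pfam set and filter by MR.

    A group survives iff at least one member gene has average MR strictly
    below ``cutoff``.  Genes without any Pfam assignment fall into an
    "unassigned" bucket (empty Pfam set).  When a trained ratio table is
    supplied, each group also carries the localization call obtained by
    scoring its Pfam set.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    gene_pfams: dict[str, set[str]] = {}
    for a in assignments:
        gene_pfams.setdefault(a.protein_id, set()).add(a.pfam_id)

    groups: dict[frozenset, list[GeneCoexpressionSummary]] = {}
    for s in shared_genes:
        key = frozenset(gene_pfams.get(s.gene_id, ()))
        groups.setdefault(key, []).append(s)

    out: list[PfamGroupSummary] = []
    for pfams, members in groups.items():
        min_mr = min(m.average_mr for m in members)
        if not min_mr < cutoff:
            continue
        by_species: dict[str, int] = {}
        for m in members:
            sp = species_of(m.gene_id)
            by_species[sp] = by_species.get(sp, 0) + 1
        location, score = "", float("nan")
        if table is not None and pfams:
            call = call_localization(score_protein(sorted(pfams), table))
            location, score = call.called_label, call.score
        out.append(
            PfamGroupSummary(
                pfam_id_set=pfams,
                gene_ids=sorted(m.gene_id for m in members),
                gene_counts_by_species=by_species,
                min_average_mr=min_mr,
                predicted_location=location,
                predicted_score=score,
            )
        )
    out.sort(key=lambda g: (g.min_average_mr, g.label))
    return out
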