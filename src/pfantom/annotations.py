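"""Training-side ingest: GO annotations, Pfam assignments and the
per-Pfam localization-ratio table.

The model trained here is a table of localization ratios: for each Pfam
domain, the fraction of experimentally localized proteins carrying that
domain that are annotated to each subcellular compartment.  Training
restricts GO annotations to experimental evidence (IDA by default), maps
cellular-component GO terms onto a fixed compartment vocabulary, counts
(Pfam, compartment) co-occurrences protein-wise, and normalizes each Pfam's
counts to ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._ids import GO_RE, PFAM_RE, normalize_gene_id

#: The eleven cellular-component GO terms of the default training vocabulary.
DEFAULT_COMPARTMENT_TERMS: tuple[tuple[str, str], ...] = (
    ("GO:0005634", "nucleus"),
    ("GO:0005739", "mitochondrion"),
    ("GO:0005773", "vacuole"),
    ("GO:0005777", "peroxisome"),
    ("GO:0005783", "endoplasmic reticulum"),
    ("GO:0005794", "Golgi apparatus"),
    ("GO:0005829", "cytosol"),
    ("GO:0005886", "plasma membrane"),
    ("GO:0009504", "cell plate"),
    ("GO:0009536", "plastid"),
    ("GO:0048046", "extracellular"),
)

#: Compartments reported in evaluation summaries; "cell plate" is kept for
#: training but too sparsely annotated to be a meaningful evaluation class.
DEFAULT_REPORTING_COMPARTMENTS: tuple[str, ...] = tuple(
    name for _, name in DEFAULT_COMPARTMENT_TERMS if name != "cell plate"
)


class MalformedLineWarning(UserWarning):
    """Raised (as a warning) when input lines are skipped during parsing."""


@dataclass(frozen=True)
class CompartmentVocabulary:
    """Ordered mapping from cellular-component GO terms to compartment names."""

    entries: tuple[tuple[str, str], ...] = DEFAULT_COMPARTMENT_TERMS

    def __post_init__(self) -> None:
        go_ids = [g for g, _ in self.entries]
        names = [n for _, n in self.entries]
        if len(set(go_ids)) != len(go_ids):
            raise ValueError("duplicate GO ids in compartment vocabulary")
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names in vocabulary")

    @property
    def go_to_name(self) -> dict[str, str]:
        return dict(self.entries)

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.entries)

    def expanded(self, expansion: Mapping[str, str]) -> "CompartmentVocabulary":
        """Add user-supplied term->term mappings (e.g. descendant closure).

        ``expansion`` maps extra GO ids onto GO ids already in the
        vocabulary; the extra terms inherit the target's compartment name.
        """
        base = self.go_to_name
        extra = []
        for src, dst in expansion.items():
            if dst not in base:
                raise ValueError(f"expansion target {dst} not in vocabulary")
            if src not in base:
                extra.append((src, base[dst]))
        # names may repeat across go_ids after expansion; bypass the
        # uniqueness check by storing a plain mapping wrapper
        vocab = object.__new__(CompartmentVocabulary)
        object.__setattr__(vocab, "entries", self.entries + tuple(extra))
        return vocab

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompartmentVocabulary":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["go_id", "compartment"], dtype=str)
        return cls(tuple(zip(df["go_id"], df["compartment"])))


@dataclass(frozen=True)
class AnnotationRecord:
    """One GO annotation: a protein, a GO term and its evidence code."""

    protein_id: str
    go_id: str
    evidence_code: str

    def __post_init__(self) -> None:
        if not (self.protein_id and self.go_id and self.evidence_code):
            raise ValueError("annotation fields must be non-empty")
        if not GO_RE.match(self.go_id):
            raise ValueError(f"malformed GO id: {self.go_id!r}")


@dataclass(frozen=True)
class DomainAssignment:
    """One Pfam domain assigned to a protein, optionally with coordinates."""

    protein_id: str
    pfam_id: str
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not PFAM_RE.match(self.pfam_id):
            raise ValueError(f"malformed Pfam accession: {self.pfam_id!r}")
        if self.start is not None:
            if self.end is None or not (1 <= self.start <= self.end):
                raise ValueError("require 1 <= start <= end")


def parse_annotation_file(path: str | Path, format: str = "tsv") -> list[AnnotationRecord]:
    """Read GO annotations from a GAF 2.x file or a 3-column TSV.

    GAF comment lines (leading ``!``) are skipped; rows with a ``NOT``
    qualifier are dropped; malformed lines are skipped with a single
    :class:`MalformedLineWarning` reporting how many were discarded.
    """
    path = Path(path)
    if format not in ("gaf", "tsv"):
        raise ValueError(f"unknown annotation format: {format!r}")
    records: list[AnnotationRecord] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if format == "gaf":
                    if len(cols) < 7:
                        raise ValueError("short GAF row")
                    qualifier = cols[3]
                    if "NOT" in qualifier.split("|"):
                        continue
                    rec = AnnotationRecord(
                        protein_id=normalize_gene_id(cols[1]),
                        go_id=cols[4],
                        evidence_code=cols[6],
                    )
                else:
                    if len(cols) < 3:
                        raise ValueError("short TSV row")
                    rec = AnnotationRecord(
                        protein_id=normalize_gene_id(cols[0]),
                        go_id=cols[1],
                        evidence_code=cols[2],
                    )
            except ValueError:
                n_bad += 1
                continue
            records.append(rec)
    if n_bad:
        warnings.warn(
            f"{path.name}: skipped {n_bad} malformed annotation line(s)",
            MalformedLineWarning,
            stacklevel=2,
        )
    return records


def filter_by_evidence(
    records: Sequence[AnnotationRecord],
    allowed: Iterable[str] = ("IDA",),
) -> list[AnnotationRecord]:
    """Keep annotations whose evidence code is in ``allowed`` (order preserved)."""
    allowed = set(allowed)
    if not allowed:
        raise ValueError("allowed evidence-code set must be non-empty")
    return [r for r in records if r.evidence_code in allowed]


class CompartmentMembership(dict):
    """protein_id -> set of compartment names, plus a dropped-record counter.

    ``n_dropped`` counts annotations whose GO term is absent from the
    vocabulary (they carry no localization signal for the model).
    """

    n_dropped: int = 0


def map_terms_to_compartments(
    records: Sequence[AnnotationRecord],
    vocabulary: CompartmentVocabulary | None = None,
) -> CompartmentMembership:
    """Collapse annotations to per-protein compartment sets (set semantics).

    A protein belongs to a compartment iff at least one of its records maps
    to it; annotation multiplicity is deliberately ignored so that heavily
    assayed proteins do not dominate the ratio table.
    """
    vocabulary = vocabulary or CompartmentVocabulary()
    go_to_name = vocabulary.go_to_name
    out = CompartmentMembership()
    dropped = 0
    for rec in records:
        name = go_to_name.get(rec.go_id)
        if name is None:
            dropped += 1
            continue
        out.setdefault(rec.protein_id, set()).add(name)
    out.n_dropped = dropped
    return out


def load_domain_assignments(path: str | Path) -> list[DomainAssignment]:
    """Read a Pfam assignment TSV (protein_id, pfam_id[, start, end]).

    Rows whose accession does not match ``PF\\d{5}`` are rejected with a
    warning; duplicate rows are kept (deduplication happens when counting).
    """
    path = Path(path)
    out: list[DomainAssignment] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2 or cols[0] in ("protein_id", "locus"):
                continue
            try:
                start = int(cols[2]) if len(cols) > 3 and cols[2] else None
                end = int(cols[3]) if len(cols) > 3 and cols[3] else None
                out.append(
                    DomainAssignment(
                        protein_id=normalize_gene_id(cols[0]),
                        pfam_id=cols[1].strip(),
                        start=start,
                        end=end,
                    )
                )
            except ValueError:
                n_bad += 1
    if n_bad:
        warnings.warn(
            f"{path.name}: rejected {n_bad} Pfam assignment row(s)",
            MalformedLineWarning,
            stacklevel=2,
        )
    return out


@dataclass
class PfamCountMatrix:
    """(pfam, compartment) -> protein count, with per-Pfam totals.

    A protein contributes one count per (distinct Pfam it carries,
    compartment it is annotated to); the total for a Pfam is the sum of its
    counts over compartments — i.e. the number of (protein, compartment)
    localization events the Pfam was seen in.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    pfam_totals: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        sums: dict[str, int] = {}
        for (pfam, _), n in self.counts.items():
            if n < 0:
                raise ValueError("negative count")
            sums[pfam] = sums.get(pfam, 0) + n
        if sums != {p: t for p, t in self.pfam_totals.items() if t}:
            raise ValueError("pfam totals inconsistent with counts")

    @property
    def pfams(self) -> list[str]:
        return sorted(self.pfam_totals)

    @property
    def n_domain_annotations(self) -> int:
        return sum(self.pfam_totals.values())


def build_count_matrix(
    protein_compartments: Mapping[str, set[str]],
    domain_assignments: Sequence[DomainAssignment],
) -> PfamCountMatrix:
    """Cross proteins' compartment sets with their distinct Pfam domains.

    Repeated copies of the same domain in one protein count once; proteins
    absent from either input contribute nothing.
    """
    protein_pfams: dict[str, set[str]] = {}
    for a in domain_assignments:
        protein_pfams.setdefault(a.protein_id, set()).add(a.pfam_id)

    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for protein, compartments in protein_compartments.items():
        for pfam in protein_pfams.get(protein, ()):
            for comp in compartments:
                counts[(pfam, comp)] = counts.get((pfam, comp), 0) + 1
                totals[pfam] = totals.get(pfam, 0) + 1
    m = PfamCountMatrix(counts=counts, pfam_totals=totals)
    m.validate()
    return m


@dataclass
class PfamLocalizationTable:
    """The trained model: per-Pfam localization ratios over the vocabulary.

    ``ratio(pfam, c)`` is the fraction of the Pfam's localization events
    seen in compartment ``c``; each Pfam's ratios sum to 1.  Pfams never
    seen in training are absent, not zero-filled.
    """

    ratios: dict[tuple[str, str], float]
    compartments: tuple[str, ...]
    provenance: PfamCountMatrix | None = None

    def __post_init__(self) -> None:
        sums: dict[str, float] = {}
        for (pfam, comp), r in self.ratios.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"ratio out of [0,1]: {r}")
            if comp not in self.compartments:
                raise ValueError(f"unknown compartment {comp!r}")
            sums[pfam] = sums.get(pfam, 0.0) + r
        for pfam, s in sums.items():
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"ratios for {pfam} sum to {s}, not 1")

    @property
    def pfams(self) -> list[str]:
        return sorted({p for p, _ in self.ratios})

    def __contains__(self, pfam: str) -> bool:
        return any(p == pfam for p, _ in self.ratios)

    def ratio(self, pfam: str, compartment: str) -> float:
        return self.ratios.get((pfam, compartment), 0.0)

    def ratio_vector(self, pfam: str) -> dict[str, float] | None:
        """All compartment ratios for one Pfam, or None if untrained."""
        if pfam not in self:
            return None
        return {c: self.ratios.get((pfam, c), 0.0) for c in self.compartments}

    def to_frame(self) -> pd.DataFrame:
        counts = self.provenance.counts if self.provenance else {}
        totals = self.provenance.pfam_totals if self.provenance else {}
        rows = []
        for pfam in self.pfams:
            for comp in self.compartments:
                r = self.ratios.get((pfam, comp), 0.0)
                rows.append(
                    {
                        "pfam_id": pfam,
                        "compartment": comp,
                        "count": counts.get((pfam, comp), 0),
                        "total": totals.get(pfam, 0),
                        "ratio": r,
                    }
                )
        return pd.DataFrame(rows, columns=["pfam_id", "compartment", "count", "total", "ratio"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PfamLocalizationTable":
        df = pd.read_csv(path, sep="\t", dtype={"pfam_id": str, "compartment": str})
        compartments = tuple(dict.fromkeys(df["compartment"]))
        ratios = {
            (r.pfam_id, r.compartment): float(r.ratio)
            for r in df.itertuples()
            if r.ratio != 0.0
        }
        counts = {
            (r.pfam_id, r.compartment): int(r.count)
            for r in df.itertuples()
            if r.count
        }
        totals = {}
        for r in df.itertuples():
            if r.total:
                totals[r.pfam_id] = int(r.total)
        prov = PfamCountMatrix(counts=counts, pfam_totals=totals)
        return cls(ratios=ratios, compartments=compartments, provenance=prov)


def compute_ratio_table(
    counts: PfamCountMatrix,
    compartments: Sequence[str] | None = None,
) -> PfamLocalizationTable:
    """Normalize a count matrix to per-Pfam localization ratios."""
    counts.validate()
    if compartments is None:
        seen = {c for _, c in counts.counts}
        default = [n for _, n in DEFAULT_COMPARTMENT_TERMS]
        compartments = tuple(default) if seen <= set(default) else tuple(sorted(seen))
    ratios = {
        (pfam, comp): n / counts.pfam_totals[pfam]
        for (pfam, comp), n in counts.counts.items()
        if counts.pfam_totals.get(pfam)
    }
    return PfamLocalizationTable(
        ratios=ratios, compartments=tuple(compartments), provenance=counts
    )


def train_table(
    annotation_path: str | Path,
    pfam_path: str | Path,
    *,
    format: str = "tsv",
    evidence: Iterable[str] = ("IDA",),
    vocabulary: CompartmentVocabulary | None = None,
) -> PfamLocalizationTable:
    """End-to-end training: parse, filter, map, count, normalize."""
    vocabulary = vocabulary or CompartmentVocabulary()
    records = parse_annotation_file(annotation_path, format=format)
    records = filter_by_evidence(records, evidence)
    membership = map_terms_to_compartments(records, vocabulary)
    assignments = load_domain_assignments(pfam_path)
    matrix = build_count_matrix(membership, assignments)
    return compute_ratio_table(matrix, vocabulary.compartments)
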