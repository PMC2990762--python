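"""Synthetic fixture generators with known ground truth.

Two generators make the whole pipeline testable without any database
snapshot:

* an annotation-corpus generator that draws proteins with Pfam domains and
  compartment labels from a known conditional distribution
  p(compartment | pfam), emitting a GAF annotation file, a Pfam assignment
  TSV and a truth table — so trained localization ratios can be checked
  against the generating parameters (parameter recovery), and predictions
  against the drawn truth;

* a Mutual-Rank list generator that constructs per-bait ranked lists whose
  pairwise and k-way overlaps equal a designed Venn layout exactly, so the
  intersection engine can be verified by construction.

All outputs are deterministic functions of (spec, seed): the same seed
yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .annotations import DEFAULT_COMPARTMENT_TERMS, CompartmentVocabulary
from .coexpression import RankedCoexpressionList

_NAME_TO_GO = {name: go for go, name in DEFAULT_COMPARTMENT_TERMS}


@dataclass
class CorpusSpec:
    """Parameters of a synthetic annotation corpus.

    ``conditional`` is the row-stochastic table p(compartment | pfam); each
    protein draws a domain count, that many distinct Pfams (uniformly), and
    one true compartment per Pfam from the conditional — so multi-domain
    proteins may be genuinely multi-localized, as real proteins are.
    """

    pfams: tuple[str, ...]
    conditional: dict[str, dict[str, float]]
    n_proteins: int = 1000
    domains_per_protein: dict[int, float] = field(
        default_factory=lambda: {0: 0.1, 1: 0.6, 2: 0.2, 3: 0.1}
    )
    evidence_mix: dict[str, float] = field(
        default_factory=lambda: {"IDA": 0.85, "ISS": 0.10, "IMP": 0.05}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        for pfam in self.pfams:
            row = self.conditional.get(pfam)
            if row is None:
                raise ValueError(f"no conditional row for {pfam}")
            s = sum(row.values())
            if abs(s - 1.0) > 1e-9 or any(p < 0 for p in row.values()):
                raise ValueError(f"conditional row for {pfam} is not a distribution (sum {s})")
        for name, dist in (("domains_per_protein", self.domains_per_protein),
                           ("evidence_mix", self.evidence_mix)):
            s = sum(dist.values())
            if abs(s - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} is not a distribution (sum {s})")

    @property
    def compartments(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for row in self.conditional.values():
            for c in row:
                seen.setdefault(c)
        return tuple(seen)

    def vocabulary(self) -> CompartmentVocabulary:
        """Vocabulary covering the spec's compartments (real GO ids where known)."""
        entries = []
        synthetic = 0
        for c in self.compartments:
            go = _NAME_TO_GO.get(c)
            if go is None:
                synthetic += 1
                go = f"GO:077{synthetic:04d}"
            entries.append((go, c))
        return CompartmentVocabulary(tuple(entries))


class SyntheticProtein(NamedTuple):
    protein_id: str
    pfams: tuple[str, ...]
    true_compartments: frozenset[str]
    annotations: tuple[tuple[str, str], ...]  # (go_id, evidence_code)


def draw_corpus(spec: CorpusSpec) -> list[SyntheticProtein]:
    """Draw the corpus in memory (one protein per spec.n_proteins)."""
    rng = np.random.default_rng(spec.seed)
    vocab = spec.vocabulary()
    name_to_go = {name: go for go, name in vocab.entries}
    dom_counts = sorted(spec.domains_per_protein)
    dom_probs = [spec.domains_per_protein[k] for k in dom_counts]
    codes = sorted(spec.evidence_mix)
    code_probs = [spec.evidence_mix[c] for c in codes]
    pfam_arr = list(spec.pfams)

    proteins = []
    for i in range(spec.n_proteins):
        k = int(rng.choice(dom_counts, p=dom_probs))
        k = min(k, len(pfam_arr))
        pfams = tuple(sorted(rng.choice(pfam_arr, size=k, replace=False))) if k else ()
        truth: set[str] = set()
        for pfam in pfams:
            row = spec.conditional[pfam]
            comps = sorted(row)
            truth.add(str(rng.choice(comps, p=[row[c] for c in comps])))
        annotations = tuple(
            (name_to_go[c], str(rng.choice(codes, p=code_probs)))
            for c in sorted(truth)
        )
        proteins.append(
            SyntheticProtein(f"SYNP{i:05d}", pfams, frozenset(truth), annotations)
        )
    return proteins


class CorpusFiles(NamedTuple):
    annotations: Path
    pfam: Path
    truth: Path
    vocabulary: Path


def generate_annotation_corpus(spec: CorpusSpec, out_dir: str | Path) -> CorpusFiles:
    """Write the synthetic corpus as GAF annotations, Pfam TSV and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins = draw_corpus(spec)
    vocab = spec.vocabulary()

    ann_path = out / "annotations.gaf"
    with open(ann_path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        fh.write("!generated-by: pfantom synthetic corpus generator\n")
        for p in proteins:
            for go, evidence in p.annotations:
                cols = [
                    "SYN", p.protein_id, p.protein_id, "located_in", go,
                    "SYN:0000001", evidence, "", "C", "", "", "protein",
                    "taxon:0", "20100101", "SYN", "", "",
                ]
                fh.write("\t".join(cols) + "\n")

    pfam_path = out / "pfam_assignments.tsv"
    with open(pfam_path, "w") as fh:
        fh.write("protein_id\tpfam_id\n")
        for p in proteins:
            for pfam in p.pfams:
                fh.write(f"{p.protein_id}\t{pfam}\n")

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("protein_id\tcompartments\n")
        for p in proteins:
            fh.write(f"{p.protein_id}\t{';'.join(sorted(p.true_compartments))}\n")

    vocab_path = out / "vocabulary.tsv"
    with open(vocab_path, "w") as fh:
        for go, name in vocab.entries:
            fh.write(f"{go}\t{name}\n")

    return CorpusFiles(ann_path, pfam_path, truth_path, vocab_path)


def load_truth_table(path: str | Path) -> dict[str, set[str]]:
    """Read a truth TSV back into protein -> compartment-set form."""
    truth: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError("truth table must start with a protein_id header")
        for line in fh:
            pid, _, comps = line.rstrip("\n").partition("\t")
            truth[pid] = set(comps.split(";")) if comps else set()
    return truth


def single_domain_bayes_rate(spec: CorpusSpec) -> float:
    """Best achievable top-1 accuracy on single-domain proteins.

    With one domain per protein the optimal call is the argmax of
    p(compartment | pfam); its success probability is max_c p(c | pfam),
    averaged over the (uniform) Pfam draw.
    """
    return float(
        np.mean([max(spec.conditional[p].values()) for p in spec.pfams])
    )


@dataclass
class MrListSpec:
    """Designed Venn layout for synthetic Mutual-Rank lists.

    ``pairwise_overlap[(i, j)]`` is the designed |list_i ∩ list_j| and
    ``kway_overlap`` the designed size of the all-baits intersection; the
    generator places genes so the realized Venn counts match exactly
    (overlap beyond the k-way core is confined to single pairs).  MR values
    are jittered ranks, re-sorted, so list order carries realistic noise.
    """

    bait_ids: tuple[str, ...]
    list_length: int
    pairwise_overlap: dict[tuple[str, str], int]
    kway_overlap: int
    mr_noise: float = 5.0
    include_baits: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        from itertools import combinations

        if len(self.bait_ids) < 2:
            raise ValueError("need at least two baits")
        self.pairwise_overlap = {
            tuple(sorted(k)): v for k, v in self.pairwise_overlap.items()
        }
        for pair in combinations(sorted(self.bait_ids), 2):
            if pair not in self.pairwise_overlap:
                raise ValueError(f"missing designed overlap for pair {pair}")
        for pair, p in self.pairwise_overlap.items():
            if not self.kway_overlap <= p:
                raise ValueError(
                    f"infeasible design: kway_overlap {self.kway_overlap} > "
                    f"pairwise overlap {p} for {pair}"
                )
            if not p <= self.list_length:
                raise ValueError(
                    f"infeasible design: pairwise overlap {p} for {pair} > "
                    f"list length {self.list_length}"
                )
        for bait in self.bait_ids:
            if self._n_unique(bait) < 0:
                raise ValueError(
                    f"infeasible design: designed overlaps for {bait} exceed "
                    f"list length {self.list_length}"
                )
        if self.include_baits and self.kway_overlap < len(self.bait_ids):
            raise ValueError(
                "include_baits needs kway_overlap >= number of baits"
            )

    def _n_unique(self, bait: str) -> int:
        pair_excess = sum(
            p - self.kway_overlap
            for pair, p in self.pairwise_overlap.items()
            if bait in pair
        )
        return self.list_length - self.kway_overlap - pair_excess


def make_mr_lists(spec: MrListSpec) -> list[RankedCoexpressionList]:
    """Construct the ranked lists in memory with exactly the designed Venn."""
    rng = np.random.default_rng(spec.seed)
    counter = 0

    def fresh(n: int) -> list[str]:
        nonlocal counter
        genes = [f"G{counter + i:06d}" for i in range(n)]
        counter += n
        return genes

    members: dict[str, list[str]] = {b: [] for b in spec.bait_ids}
    core = fresh(spec.kway_overlap)
    if spec.include_baits:
        core[: len(spec.bait_ids)] = spec.bait_ids
    for b in spec.bait_ids:
        members[b].extend(core)
    for pair, p in spec.pairwise_overlap.items():
        shared = fresh(p - spec.kway_overlap)
        for b in pair:
            members[b].extend(shared)
    for b in spec.bait_ids:
        members[b].extend(fresh(spec._n_unique(b)))

    lists = []
    for b in spec.bait_ids:
        genes = list(members[b])
        rng.shuffle(genes)
        ranks = np.arange(1, len(genes) + 1, dtype=float)
        mrs = np.sort(np.maximum(1.0, ranks + rng.normal(0.0, spec.mr_noise, len(genes))))
        lists.append(
            RankedCoexpressionList(
                bait_id=b,
                entries=[(g, round(float(m), 3)) for g, m in zip(genes, mrs)],
            )
        )
    return lists


def generate_mr_lists(spec: MrListSpec, out_dir: str | Path) -> list[Path]:
    """Write one ranked-list TSV per bait; returns the paths in bait order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for ranked in make_mr_lists(spec):
        path = out / f"mrlist_{ranked.bait_id}.tsv"
        ranked.to_tsv(path)
        paths.append(path)
    return paths


def uniform_corpus_spec(
    n_pfams: int = 20,
    compartments: Sequence[str] | None = None,
    purity: float = 0.8,
    n_proteins: int = 1000,
    seed: int = 0,
    **overrides,
) -> CorpusSpec:
    """Convenience spec: each Pfam favors one 'home' compartment.

    Each Pfam puts probability ``purity`` on a home compartment (assigned
    round-robin) and spreads the rest uniformly over the others; purity 1.0
    gives a compartment-pure corpus where perfect prediction is possible.
    """
    if compartments is None:
        compartments = [n for _, n in DEFAULT_COMPARTMENT_TERMS if n != "cell plate"]
    compartments = list(compartments)
    pfams = tuple(f"PF9{i:04d}" for i in range(n_pfams))
    conditional = {}
    for i, pfam in enumerate(pfams):
        home = compartments[i % len(compartments)]
        others = [c for c in compartments if c != home]
        row = {home: purity}
        if others and purity < 1.0:
            rest = (1.0 - purity) / len(others)
            row.update({c: rest for c in others})
        elif purity >= 1.0:
            row = {home: 1.0}
        conditional[pfam] = row
    return CorpusSpec(
        pfams=pfams,
        conditional=conditional,
        n_proteins=n_proteins,
        seed=seed,
        **overrides,
    )
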