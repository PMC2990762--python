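"""Geometric-mean localization scoring over a protein's Pfam domains.

For a protein carrying Pfam domains d1..dk with trained localization ratios
r(di, c), the score for compartment c is the geometric mean

    score(c) = (r(d1,c) * r(d2,c) * ... * r(dk,c)) ** (1/k)

over the domains present in the trained table.  The predicted compartment
is the argmax over c; exact ties produce a multi-compartment call (e.g. a
vacuole/plasma-membrane "50/50").  A single zero ratio annihilates a
compartment — the bare geometric mean is used, with no smoothing by
default.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotations import PfamLocalizationTable

logger = logging.getLogger(__name__)

#: Exact-tie tolerance: only numerically identical scores are co-called.
DEFAULT_TIE_TOLERANCE = 1e-9


@dataclass
class CompartmentScores:
    """Per-compartment scores for one protein, with domain bookkeeping."""

    protein_id: str
    scores: dict[str, float]
    domains_used: list[str] = field(default_factory=list)
    domains_skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.domains_used) & set(self.domains_skipped):
            raise ValueError("a domain cannot be both used and skipped")
        for c, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score out of [0,1] for {c}: {s}")


@dataclass
class PredictionCall:
    """The localization call for one protein.

    ``status`` is one of predicted / tie / no_pfam / no_data /
    below_threshold; ``called`` is empty exactly for the last three.
    """

    protein_id: str
    called: frozenset[str]
    score: float
    status: str

    def __post_init__(self) -> None:
        if (self.status == "tie") != (len(self.called) >= 2):
            raise ValueError("tie status iff >= 2 called compartments")
        if (self.status in ("no_pfam", "no_data", "below_threshold")) != (
            not self.called
        ):
            raise ValueError("empty call iff an abstaining status")

    @property
    def called_label(self) -> str:
        """Slash-joined compartment label, e.g. 'vacuole/plasma membrane'."""
        return "/".join(sorted(self.called)) if self.called else "-"

    @property
    def score_percent(self) -> str:
        """The human-readable score, percentage with one decimal (e.g. 80.9)."""
        return f"{100 * self.score:.1f}"


def score_protein(
    pfam_ids: Sequence[str],
    table: PfamLocalizationTable,
    *,
    protein_id: str = "",
    smoothing: float = 0.0,
) -> CompartmentScores:
    """Score one protein against the ratio table.

    Duplicate Pfam accessions collapse to one; domains absent from the
    table are excluded from the mean and recorded in ``domains_skipped``.
    ``smoothing`` > 0 adds a pseudo-ratio before the product (exploratory
    use only; zero factors then no longer annihilate compartments).
    """
    unique = list(dict.fromkeys(pfam_ids))
    used = [p for p in unique if p in table]
    skipped = [p for p in unique if p not in table]
    scores: dict[str, float] = {}
    if len(used) == 1 and smoothing == 0.0:
        # exact: a single-domain protein's scores are its Pfam's ratios
        scores = {c: table.ratio(used[0], c) for c in table.compartments}
    elif used:
        k = len(used)
        for comp in table.compartments:
            log_sum = 0.0
            zero = False
            for pfam in used:
                r = table.ratio(pfam, comp) + smoothing
                if r <= 0.0:
                    zero = True
                    break
                log_sum += math.log(r)
            scores[comp] = 0.0 if zero else min(1.0, math.exp(log_sum / k))
    else:
        scores = {comp: 0.0 for comp in table.compartments}
    return CompartmentScores(
        protein_id=protein_id,
        scores=scores,
        domains_used=used,
        domains_skipped=skipped,
    )


def call_localization(
    scores: CompartmentScores,
    threshold: float = 0.0,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> PredictionCall:
    """Turn compartment scores into a localization call.

    Proteins with no Pfam domains abstain with status ``no_pfam``; proteins
    whose every domain is untrained abstain with ``no_data``; otherwise the
    (tied) argmax is called unless it falls below ``threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not scores.domains_used:
        status = "no_data" if scores.domains_skipped else "no_pfam"
        return PredictionCall(scores.protein_id, frozenset(), 0.0, status)
    m = max(scores.scores.values())
    if m < threshold:
        return PredictionCall(scores.protein_id, frozenset(), m, "below_threshold")
    called = frozenset(c for c, s in scores.scores.items() if m - s <= tie_tolerance)
    status = "predicted" if len(called) == 1 else "tie"
    return PredictionCall(scores.protein_id, called, m, status)


def predict_batch(
    proteins: Mapping[str, Sequence[str]],
    table: PfamLocalizationTable,
    threshold: float = 0.0,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> list[PredictionCall]:
    """Call every protein in input order; proteins are independent."""
    calls = [
        call_localization(
            score_protein(pfams, table, protein_id=pid), threshold, tie_tolerance
        )
        for pid, pfams in proteins.items()
    ]
    by_status = Counter(c.status for c in calls)
    logger.info("predict_batch: %d proteins, status counts %s", len(calls), dict(by_status))
    return calls


def score_batch(
    proteins: Mapping[str, Sequence[str]],
    table: PfamLocalizationTable,
) -> list[CompartmentScores]:
    """Score every protein in input order (used by the ROC sweep)."""
    return [score_protein(pfams, table, protein_id=pid) for pid, pfams in proteins.items()]
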