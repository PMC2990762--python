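"""Shared fixtures: small trained tables and synthetic corpora."""

import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from pfantom import (
    PfamCountMatrix,
    PfamLocalizationTable,
    compute_ratio_table,
)

COMPARTMENTS = ("nucleus", "plasma membrane", "Golgi apparatus", "vacuole")


def table_from_counts(counts: dict, compartments=COMPARTMENTS) -> PfamLocalizationTable:
    totals: dict = {}
    for (pfam, _), n in counts.items():
        totals[pfam] = totals.get(pfam, 0) + n
    return compute_ratio_table(
        PfamCountMatrix(counts=dict(counts), pfam_totals=totals), compartments
    )


@pytest.fixture(scope="session")
def lrr_table() -> PfamLocalizationTable:
    """Ratio table reproducing the LRR worked example: three kinase/LRR
    domains whose plasma-membrane ratios are 0.824, 0.703 and 0.878."""
    counts = {
        ("PF00560", "plasma membrane"): 824,
        ("PF00560", "nucleus"): 176,
        ("PF00069", "plasma membrane"): 703,
        ("PF00069", "Golgi apparatus"): 297,
        ("PF08263", "plasma membrane"): 878,
        ("PF08263", "vacuole"): 122,
        # a nucleus-dominant bHLH domain and a pure-Golgi domain for variety
        ("PF00010", "nucleus"): 809,
        ("PF00010", "plasma membrane"): 191,
        ("PF03360", "Golgi apparatus"): 50,
    }
    return table_from_counts(counts)


@pytest.fixture(scope="session")
def tie_table() -> PfamLocalizationTable:
    """A DUF231-style domain split exactly 50/50 vacuole / plasma membrane."""
    return table_from_counts(
        {("PF03005", "vacuole"): 5, ("PF03005", "plasma membrane"): 5}
    )
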