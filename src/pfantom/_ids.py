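"""Locus-identifier normalization shared across modules.

Arabidopsis AGI loci (AT1G67510) are case-insensitive in the wild and often
carry splice-variant suffixes (AT1G67510.1); both are normalized away before
tables are joined.  Rice RAP loci (Os01g0926400) are case-sensitive by
convention and are kept as published, modulo canonical "Os"/"g" casing.
"""

from __future__ import annotations

import re

_AGI_RE = re.compile(r"^AT[1-5CM]G\d{5}(\.\d+)?$", re.IGNORECASE)
_RAP_RE = re.compile(r"^OS(\d{2})G(\d{7})$", re.IGNORECASE)

PFAM_RE = re.compile(r"^PF\d{5}$")
GO_RE = re.compile(r"^GO:\d{7}$")


def normalize_gene_id(raw: str) -> str:
    """Return the canonical form of a locus identifier.

    AGI identifiers are uppercased and stripped of ``.N`` splice suffixes;
    RAP identifiers are re-cased to the ``OsNNgNNNNNNN`` convention; anything
    else is passed through stripped of surrounding whitespace.
    """
    token = raw.strip()
    if _AGI_RE.match(token):
        return token.upper().split(".", 1)[0]
    m = _RAP_RE.match(token)
    if m:
        return f"Os{m.group(1)}g{m.group(2)}"
    return token


def species_of(gene_id: str) -> str:
    """Classify a normalized locus as 'arabidopsis', 'rice' or 'other'."""
    if _AGI_RE.match(gene_id):
        return "arabidopsis"
    if _RAP_RE.match(gene_id):
        return "rice"
    return "other"
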