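"""Mapping candidate genes onto the f element and testing for enrichment.

The f element is a fragment of a feminizing Wolbachia genome horizontally
transferred into the host nuclear genome.  Candidate proteins are searched
against the f element's (translated) protein set by local alignment; an
f-element protein counts as one copy of a candidate when the alignment
passes both an e-value ceiling and a percent-identity floor.  A 2x2
Fisher's exact test asks whether candidates are enriched in the f element
relative to a caller-supplied background gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .homology import HomologyHit, ProteinRecord, search_hits_between

DEFAULT_MAX_EVALUE = 1e-3
DEFAULT_MIN_IDENTITY = 0.90


class FElementError(ValueError):
    pass


@dataclass(frozen=True)
class FElementHit:
    gene: str
    copies: int
    identities: tuple[float, ...]  # percent identity per copy, descending

    @property
    def max_identity(self) -> float:
        return self.identities[0]


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 contingency table: candidate/background x in/out of f element."""

    a: int  # candidates in f element
    b: int  # candidates not in f element
    c: int  # background genes in f element
    d: int  # background genes not in f element

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise FElementError("contingency table cells must be nonnegative")


def search_felement(
    candidates: Sequence[ProteinRecord],
    felement: Sequence[ProteinRecord],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[FElementHit]:
    """Local-alignment search of candidates against f-element proteins.

    Each distinct f-element protein passing both thresholds counts as one
    copy; candidates with no passing hit are omitted from the result.
    """
    if not candidates:
        raise FElementError("empty candidate set")
    if not felement:
        raise FElementError("empty f element protein set")
    hits: list[HomologyHit] = search_hits_between(candidates, felement, mode="local")
    per_gene: dict[str, list[float]] = {}
    for hit in hits:
        if hit.evalue <= max_evalue and hit.identity >= min_identity:
            per_gene.setdefault(hit.query[1], []).append(100.0 * hit.identity)
    return [
        FElementHit(
            gene=gene,
            copies=len(identities),
            identities=tuple(sorted(identities, reverse=True)),
        )
        for gene, identities in sorted(per_gene.items())
    ]


def fisher_exact(table: EnrichmentTable) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 enrichment table.

    Defined as the sum of hypergeometric probabilities (margins fixed) of
    all tables at most as probable as the observed one.
    """
    result = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(min(1.0, result.pvalue))


def hits_table(hits: Sequence[FElementHit]):
    """Rows of (gene, copies, max_identity, identities) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": h.gene,
                "copies": h.copies,
                "max_identity": round(h.max_identity, 2),
                "identities": ";".join(f"{i:.2f}" for i in h.identities),
            }
            for h in hits
        ],
        columns=["gene", "copies", "max_identity", "identities"],
    )
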