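"""Ordered in-silico filter cascade producing the first candidate gene set.

Starting from the focal genome's annotation, genes are removed in a fixed
order — repeats, pseudogenes, short genes (< 150 bp), the smaller chunks of
split CDSs, members of the reference-panel core genome, and genes whose
protein is 100% identical to a homolog in the closely related
non-feminizing strain over at least 90% of their length.  A gene matching
several categories is counted only under the first matching filter, so the
removal counts partition the input exactly and the audit trail sums through
the funnel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .homology import HomologyHit, OrthologGroup

DEFAULT_MIN_LENGTH_BP = 150
DEFAULT_NONFEM_IDENTITY = 1.0
DEFAULT_NONFEM_COVERAGE = 0.90

ANNOTATION_COLUMNS = [
    "gene_id", "product", "length_bp", "is_repeat", "is_pseudogene",
    "is_split_chunk", "protein",
]


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    product: str
    length_bp: int
    is_repeat: bool
    is_pseudogene: bool
    is_split_chunk: bool
    protein: str

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise FilterError(f"{self.gene_id}: nonpositive length")
        # protein length must be consistent with the CDS length (+-1 codon)
        if abs(len(self.protein) - self.length_bp / 3) > 2:
            raise FilterError(
                f"{self.gene_id}: protein length {len(self.protein)} inconsistent "
                f"with {self.length_bp} bp"
            )


@dataclass
class FilterResult:
    survivors: list[str]
    removals: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {name: len(ids) for name, ids in self.removals}
        out["survivors"] = len(self.survivors)
        return out

    def check_partition(self, input_ids: Sequence[str]) -> None:
        parts = [set(self.survivors)] + [set(ids) for _, ids in self.removals]
        union: set[str] = set()
        total = 0
        for part in parts:
            union |= part
            total += len(part)
        if union != set(input_ids) or total != len(input_ids):
            raise FilterError("filter result does not partition the input gene set")


def filter_annotation(
    genes: Sequence[GeneRecord], min_length_bp: int = DEFAULT_MIN_LENGTH_BP
) -> FilterResult:
    """Annotation-level filters in precedence order:
    repeat -> pseudogene -> short (< min_length_bp) -> split chunk."""
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise FilterError("duplicate gene ids in annotation")
    removed = {"repeat": [], "pseudogene": [], "short": [], "split_chunk": []}
    survivors = []
    for gene in genes:
        if gene.is_repeat:
            removed["repeat"].append(gene.gene_id)
        elif gene.is_pseudogene:
            removed["pseudogene"].append(gene.gene_id)
        elif gene.length_bp < min_length_bp:
            removed["short"].append(gene.gene_id)
        elif gene.is_split_chunk:
            removed["split_chunk"].append(gene.gene_id)
        else:
            survivors.append(gene.gene_id)
    result = FilterResult(
        survivors=survivors, removals=[(k, v) for k, v in removed.items()]
    )
    result.check_partition(ids)
    return result


def filter_core(
    survivors: Sequence[str],
    core_groups: Iterable[OrthologGroup],
    focal_genome: str,
) -> FilterResult:
    """Remove focal-genome genes belonging to any core ortholog group."""
    core_members = {
        gene_id
        for group in core_groups
        for genome, gene_id in group.members
        if genome == focal_genome
    }
    removed = [g for g in survivors if g in core_members]
    kept = [g for g in survivors if g not in core_members]
    result = FilterResult(survivors=kept, removals=[("core_genome", removed)])
    result.check_partition(list(survivors))
    return result


def filter_conserved_vs_nonfeminizer(
    survivors: Sequence[str],
    hits: Iterable[HomologyHit],
    min_identity: float = DEFAULT_NONFEM_IDENTITY,
    min_coverage: float = DEFAULT_NONFEM_COVERAGE,
) -> FilterResult:
    """Remove genes with a 100%-identity hit over >= 90% of their length
    in the non-feminizing strain (local focal-vs-nonfeminizer alignments)."""
    conserved = {
        hit.query[1]
        for hit in hits
        if hit.identity >= min_identity and hit.query_coverage >= min_coverage
    }
    removed = [g for g in survivors if g in conserved]
    kept = [g for g in survivors if g not in conserved]
    result = FilterResult(
        survivors=kept, removals=[("identical_to_nonfeminizer", removed)]
    )
    result.check_partition(list(survivors))
    return result


def run_cascade(
    genes: Sequence[GeneRecord],
    core_groups: Iterable[OrthologGroup],
    nonfem_hits: Iterable[HomologyHit],
    focal_genome: str,
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
) -> FilterResult:
    """Chain the three filter stages and merge their audit trails."""
    stage1 = filter_annotation(genes, min_length_bp=min_length_bp)
    stage2 = filter_core(stage1.survivors, core_groups, focal_genome)
    stage3 = filter_conserved_vs_nonfeminizer(stage2.survivors, nonfem_hits)
    result = FilterResult(
        survivors=stage3.survivors,
        removals=stage1.removals + stage2.removals + stage3.removals,
    )
    result.check_partition([g.gene_id for g in genes])
    return result


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotation(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "product": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FilterError(f"annotation table missing columns: {missing}")
    return [
        GeneRecord(
            gene_id=row.gene_id,
            product=row.product,
            length_bp=int(row.length_bp),
            is_repeat=bool(row.is_repeat),
            is_pseudogene=bool(row.is_pseudogene),
            is_split_chunk=bool(row.is_split_chunk),
            protein=row.protein,
        )
        for row in df.itertuples()
    ]


def write_annotation(genes: Sequence[GeneRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "product": g.product,
                "length_bp": g.length_bp,
                "is_repeat": int(g.is_repeat),
                "is_pseudogene": int(g.is_pseudogene),
                "is_split_chunk": int(g.is_split_chunk),
                "protein": g.protein,
            }
            for g in genes
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def audit_report(result: FilterResult) -> dict:
    """JSON-serializable audit trail: per-filter counts and removed ids."""
    return {
        "removals": [
            {"filter": name, "count": len(ids), "gene_ids": list(ids)}
            for name, ids in result.removals
        ],
        "survivors": {"count": len(result.survivors), "gene_ids": list(result.survivors)},
    }
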