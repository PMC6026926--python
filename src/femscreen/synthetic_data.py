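"""Synthetic inputs for the feminization-candidate screen.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes planted explicitly, together
with truth tables for recovery tests: an annotated focal genome whose
category counts follow a configurable funnel preset, reference-genome
protein sets carrying >=70%-identity homologs for the planted core genes, a
non-feminizing sister-strain protein set with planted 100%-identity
matches, qPCR Ct datasets across two hosts and three sampling campaigns
with planted fold changes, reference-gene correlation structure and a
one-stage cross-host expression lag, and an f-element protein set with
planted candidate copies.

``PAPER_FUNNEL`` is the default preset: 1888 annotated genes of which 792
repeats, 26 pseudogenes, 52 short genes, 16 split-CDS chunks, 721 core
orthologs and 16 genes identical to the non-feminizer are planted, leaving
265 candidates; 216 amplify, 139 are expressed during sexual
differentiation, 13 + 29 are under/over-expressed in the first sampling, 7
fail the second-sampling consistency check (35 final candidates), 29 are
regulated in both hosts, 2 + 1 cross-correlate at lag 1/0, and 27 map to
the f element (20 with identical copies, copy numbers 1-5).

All generators are deterministic functions of their seed: identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .candidate_filter import GeneRecord
from .crosshost import StageSeries, cross_correlation
from .homology import AMINO_ACIDS, ProteinRecord

# ---------------------------------------------------------------------------
# Presets and noise model
# ---------------------------------------------------------------------------

FOCAL_GENOME = "wVulC"
NONFEM_GENOME = "wCon"
REFERENCE_GENOMES = ("wMel", "wRi", "wHa", "wNo", "wPip")
HOST_A = "A_vulgare"
HOST_B = "C_convexus"
STAGES = tuple(range(1, 8))
CALIBRATOR_STAGE = 2
STAGES_OF_INTEREST_A = (3, 4, 5, 6)
#: sexual differentiation in the heterologous host is shifted by one stage
STAGES_OF_INTEREST_B = (2, 3, 4, 5)

#: housekeeping candidates offered to reference-gene selection (the *wsp*
#: genome-copy marker is emitted separately and is not a candidate)
HOUSEKEEPING_GENES = (
    "coxA", "atpD", "sucB", "gatB", "gltA", "L2", "L20", "S4",
    "fabF", "pyrB", "purF", "tkt", "hcpA", "fbpA", "ftsZ",
)
STABLE_HOUSEKEEPING = ("gltA", "L2", "L20", "S4", "fabF", "purF")
WSP = "wsp"

#: per-sample latent template-quantity spread, in cycles at E = 1; shared by
#: every gene of a sample, it cancels in calibrated ratios and carries the
#: stability signal the 6 stable housekeeping genes track
LATENT_CT_SD = 2.5
#: independent per-sample expression noise of the 9 unstable housekeeping
#: genes (0.85 x latent keeps their index correlation below 0.8)
UNSTABLE_CT_SD = 0.85 * LATENT_CT_SD
#: residual biological noise of the stable housekeeping genes and wsp
STABLE_CT_SD = 0.02

#: planted log2 amplitude at the differential-expression crossing stage
DE_LOG2_AMPLITUDE = 2.1
#: |log2 ratio| ceiling for profiles meant to stay inside the 0.5-2 band
NULL_LOG2_MAX = 0.32
INCONSISTENT_LOG2_MAX = 0.45
#: rejection-sampling ceiling for |ccf| of gene pairs without a planted lag
CCF_NULL_MAX = 0.55
CCF_PLANTED_MIN = 0.90


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class FunnelPreset:
    """Planted gene counts for every stage of the screening funnel."""

    n_genes: int = 1888
    n_repeats: int = 792
    n_pseudogenes: int = 26
    n_short: int = 52
    n_split_chunks: int = 16
    n_core: int = 721
    n_identical_to_nonfeminizer: int = 16
    n_amplifiable: int = 216
    n_expressed: int = 139
    n_under_s1: int = 13
    n_over_s1: int = 29
    n_fail_s2: int = 7
    n_regulated_both_hosts: int = 29
    n_ccf_lag1: int = 2
    n_ccf_lag0: int = 1
    n_in_felement: int = 27
    n_identical_in_felement: int = 20
    copy_number_range: tuple[int, int] = (1, 5)

    @property
    def n_candidates(self) -> int:
        return self.n_genes - (
            self.n_repeats + self.n_pseudogenes + self.n_short
            + self.n_split_chunks + self.n_core + self.n_identical_to_nonfeminizer
        )

    @property
    def n_final(self) -> int:
        return self.n_under_s1 + self.n_over_s1 - self.n_fail_s2

    def validate(self) -> None:
        counts = {
            name: getattr(self, name)
            for name in (
                "n_genes", "n_repeats", "n_pseudogenes", "n_short",
                "n_split_chunks", "n_core", "n_identical_to_nonfeminizer",
                "n_amplifiable", "n_expressed", "n_under_s1", "n_over_s1",
                "n_fail_s2", "n_regulated_both_hosts", "n_ccf_lag1",
                "n_ccf_lag0", "n_in_felement", "n_identical_in_felement",
            )
        }
        for name, value in counts.items():
            if value < 0:
                raise SyntheticDataError(f"{name} = {value} is negative")
        removed = (
            self.n_repeats + self.n_pseudogenes + self.n_short
            + self.n_split_chunks + self.n_core
            + self.n_identical_to_nonfeminizer
        )
        if removed > self.n_genes:
            raise SyntheticDataError(
                f"removal categories sum to {removed} > n_genes = {self.n_genes}"
            )
        chain = [
            ("n_amplifiable", self.n_amplifiable, "candidates", self.n_candidates),
            ("n_expressed", self.n_expressed, "n_amplifiable", self.n_amplifiable),
            ("n_under_s1 + n_over_s1", self.n_under_s1 + self.n_over_s1,
             "n_expressed", self.n_expressed),
            ("n_fail_s2", self.n_fail_s2, "n_under_s1 + n_over_s1",
             self.n_under_s1 + self.n_over_s1),
            ("n_regulated_both_hosts", self.n_regulated_both_hosts,
             "final candidates", self.n_final),
            ("n_ccf_lag1 + n_ccf_lag0", self.n_ccf_lag1 + self.n_ccf_lag0,
             "n_regulated_both_hosts", self.n_regulated_both_hosts),
            ("n_in_felement", self.n_in_felement, "final candidates", self.n_final),
            ("n_identical_in_felement", self.n_identical_in_felement,
             "n_in_felement", self.n_in_felement),
        ]
        for name, value, bound_name, bound in chain:
            if value > bound:
                raise SyntheticDataError(f"{name} = {value} exceeds {bound_name} = {bound}")
        lo, hi = self.copy_number_range
        if not 1 <= lo <= hi:
            raise SyntheticDataError(f"invalid copy_number_range {self.copy_number_range}")


PAPER_FUNNEL = FunnelPreset()


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for the qPCR generators."""

    ct_sd: float = 0.1
    efficiency_range: tuple[float, float] = (0.85, 1.0)
    dropout_rate: float = 0.0

    def validate(self) -> None:
        if self.ct_sd < 0:
            raise SyntheticDataError("ct_sd must be nonnegative")
        lo, hi = self.efficiency_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise SyntheticDataError("efficiency_range must lie within [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise SyntheticDataError("dropout_rate must lie within [0, 1]")


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein over the 20 standard residues, uniform background."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _substitute(sequence: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(sequence)
    for pos in positions:
        original = chars[pos]
        choices = [a for a in AMINO_ACIDS if a != original]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def mutate_to_identity(
    protein: str, target_identity: float, seed: int | np.random.Generator
) -> str:
    """Substitute residues so the ungapped identity to the input equals
    round(L * (1 - target)) / L.  No indels are introduced."""
    if not protein:
        raise SyntheticDataError("empty sequence")
    length = len(protein)
    if not 0.0 < target_identity <= 1.0:
        raise SyntheticDataError(f"target identity {target_identity} outside (0, 1]")
    if target_identity < 1.0 / length:
        raise SyntheticDataError(
            f"target identity {target_identity} below the 1/{length} resolution"
        )
    n_sub = round(length * (1.0 - target_identity))
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 901)
    positions = rng.choice(length, size=n_sub, replace=False)
    return _substitute(protein, positions, rng)


def _mutate_spread(
    protein: str, n_sub: int, rng: np.random.Generator, edge_margin: int = 5
) -> str:
    """Substitutions confined to the interior and spread across the length,
    so local alignments neither trim mismatches off the ends nor find a long
    perfect sub-block."""
    length = len(protein)
    margin = min(edge_margin, max(0, (length - n_sub) // 4))
    interior = np.arange(margin, length - margin)
    if n_sub > interior.size:
        raise SyntheticDataError("too many substitutions for sequence length")
    # stratified draw: one position per contiguous chunk of the interior
    chunks = np.array_split(interior, n_sub) if n_sub else []
    positions = np.array(
        [chunk[int(rng.integers(chunk.size))] for chunk in chunks], dtype=int
    )
    return _substitute(protein, positions, rng)


# ---------------------------------------------------------------------------
# Annotation generator
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    """Focal-genome annotation plus the reference protein sets it implies."""

    genes: list[GeneRecord]
    references: dict[str, list[ProteinRecord]]
    nonfeminizer: list[ProteinRecord]
    truth: pd.DataFrame  # gene_id, category
    preset: FunnelPreset

    def proteins(self, gene_ids: Sequence[str] | None = None) -> list[ProteinRecord]:
        wanted = None if gene_ids is None else set(gene_ids)
        return [
            ProteinRecord(FOCAL_GENOME, g.gene_id, g.protein)
            for g in self.genes
            if wanted is None or g.gene_id in wanted
        ]

    def gene_ids(self, category: str) -> list[str]:
        mask = self.truth["category"] == category
        return self.truth.loc[mask, "gene_id"].tolist()


def generate_annotation(preset: FunnelPreset, seed: int) -> AnnotationBundle:
    """Generate the focal annotation with planted disjoint categories.

    Core genes receive >=70%-identity homologs in all five reference
    genomes; the planted conserved genes receive a full-length 100%-identity
    copy in the non-feminizing strain, and a further slice of candidates
    receives near-identical (<100%) decoy homologs there.
    """
    preset.validate()
    rng = _rng(seed, 101)
    n = preset.n_genes
    order = rng.permutation(n)
    categories = np.full(n, "candidate", dtype=object)
    cursor = 0
    for name, count in (
        ("repeat", preset.n_repeats),
        ("pseudogene", preset.n_pseudogenes),
        ("short", preset.n_short),
        ("split_chunk", preset.n_split_chunks),
        ("core", preset.n_core),
        ("identical_nonfem", preset.n_identical_to_nonfeminizer),
    ):
        categories[order[cursor:cursor + count]] = name
        cursor += count

    genes: list[GeneRecord] = []
    references: dict[str, list[ProteinRecord]] = {g: [] for g in REFERENCE_GENOMES}
    nonfem: list[ProteinRecord] = []
    candidate_ids: list[str] = []
    products = {
        "repeat": "transposase (repeat region)",
        "pseudogene": "pseudogene fragment",
        "short": "hypothetical small peptide",
        "split_chunk": "split CDS chunk",
        "core": "conserved housekeeping protein",
        "identical_nonfem": "hypothetical protein (conserved in sister strain)",
        "candidate": "hypothetical protein",
    }
    for i in range(n):
        gene_id = f"wVul_{i + 1:04d}"
        category = categories[i]
        if category == "short":
            plen = int(rng.integers(20, 49))  # < 50 aa, i.e. < 150 bp
        else:
            plen = int(rng.integers(60, 120))
        protein = random_protein(rng, plen)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                product=products[category],
                length_bp=3 * (plen + 1),  # CDS includes the stop codon
                is_repeat=category == "repeat",
                is_pseudogene=category == "pseudogene",
                is_split_chunk=category == "split_chunk",
                protein=protein,
            )
        )
        if category == "core":
            for genome in REFERENCE_GENOMES:
                identity = rng.uniform(0.78, 0.95)
                n_sub = round(plen * (1.0 - identity))
                homolog = _mutate_spread(protein, n_sub, rng)
                references[genome].append(
                    ProteinRecord(genome, f"{genome}_{gene_id}", homolog)
                )
        elif category == "identical_nonfem":
            nonfem.append(ProteinRecord(NONFEM_GENOME, f"wCon_{gene_id}", protein))
        elif category == "candidate":
            candidate_ids.append(gene_id)

    # near-identical (but < 100%) sister-strain homologs for a slice of the
    # candidates: they must survive the conservation filter
    n_decoys = min(60, len(candidate_ids))
    decoy_ids = list(rng.choice(candidate_ids, size=n_decoys, replace=False))
    by_id = {g.gene_id: g for g in genes}
    for gene_id in decoy_ids:
        protein = by_id[gene_id].protein
        n_sub = max(1, round(len(protein) * rng.uniform(0.03, 0.08)))
        nonfem.append(
            ProteinRecord(
                NONFEM_GENOME, f"wCon_{gene_id}",
                _mutate_spread(protein, n_sub, rng),
            )
        )

    truth = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "category": categories}
    )
    return AnnotationBundle(
        genes=genes, references=references, nonfeminizer=nonfem,
        truth=truth, preset=preset,
    )


# ---------------------------------------------------------------------------
# Expression truth: planted folds, lags and cross-host structure
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Planted expression structure downstream recovery tests compare against."""

    amplifiable: list[str]
    expressed: list[str]
    status: dict[str, str]                  # over / under / none (sampling 1)
    s2_fail: list[str]
    final: list[str]
    both_hosts: list[str]
    lag_assignments: dict[str, int]
    profiles: dict[tuple[str, int], pd.DataFrame]  # (host, campaign) -> gene x stage log2
    efficiencies: dict[str, float]
    presence: pd.DataFrame                  # amplifiable genes x stages 3-6

    def folds(self) -> pd.DataFrame:
        rows = []
        for (host, campaign), table in self.profiles.items():
            for gene, row in table.iterrows():
                for stage, log2fold in row.items():
                    rows.append(
                        {"gene": gene, "host": host, "campaign": campaign,
                         "stage": int(stage), "fold": float(2.0 ** log2fold)}
                    )
        return pd.DataFrame(rows)


def _profile(
    rng: np.random.Generator,
    crossing_stage: int | None,
    sign: int,
    other_max: float,
    stage1_max: float | None = None,
) -> np.ndarray:
    """A log2 profile over stages 1..7 with value 0 at the calibrator stage."""
    values = rng.uniform(-other_max, other_max, size=len(STAGES))
    if stage1_max is not None:
        values[0] = rng.uniform(-stage1_max, stage1_max)
    values[CALIBRATOR_STAGE - 1] = 0.0
    if crossing_stage is not None:
        values[crossing_stage - 1] = sign * DE_LOG2_AMPLITUDE
    return values


def _series(gene: str, host: str, values: np.ndarray) -> StageSeries:
    return StageSeries(host=host, gene=gene, stages=STAGES, values=tuple(values))


def _max_abs_ccf(a: np.ndarray, b: np.ndarray, max_lag: int = 2) -> float:
    result = cross_correlation(_series("x", "a", a), _series("x", "b", b), max_lag)
    return max(abs(v) for v in result.ccf)


def build_expression_truth(
    preset: FunnelPreset,
    candidates: Sequence[str],
    noise: NoiseModel,
    seed: int,
) -> ExpressionTruth:
    """Assign per-gene expression truth over the candidate set.

    Cross-host profiles are rejection-sampled against the package's own
    cross-correlation statistic so that exactly the planted genes are
    significant at |ccf| > 1.96/sqrt(7): genes with a planted lag L satisfy
    best_lag = L with |ccf| >= 0.9, every other final candidate stays below
    0.55 at all lags, leaving clear margin around the 0.74 threshold.
    """
    preset.validate()
    noise.validate()
    if len(candidates) < preset.n_amplifiable:
        raise SyntheticDataError(
            f"{len(candidates)} candidates cannot contain "
            f"{preset.n_amplifiable} amplifiable genes"
        )
    rng = _rng(seed, 202)
    order = list(np.array(candidates)[rng.permutation(len(candidates))])
    amplifiable = sorted(order[: preset.n_amplifiable])
    pool = list(np.array(amplifiable)[rng.permutation(len(amplifiable))])
    expressed = pool[: preset.n_expressed]
    under = expressed[: preset.n_under_s1]
    over = expressed[preset.n_under_s1: preset.n_under_s1 + preset.n_over_s1]
    null = expressed[preset.n_under_s1 + preset.n_over_s1:]
    # consistency failures come from the over set first, then under
    fail = (over[: preset.n_fail_s2]
            if preset.n_fail_s2 <= len(over)
            else over + under[: preset.n_fail_s2 - len(over)])
    final = [g for g in under + over if g not in set(fail)]
    n_lag = preset.n_ccf_lag1 + preset.n_ccf_lag0
    lag_genes = final[:n_lag]
    lag_assignments = {
        g: (1 if i < preset.n_ccf_lag1 else 0) for i, g in enumerate(lag_genes)
    }
    both = final[: preset.n_regulated_both_hosts]
    not_both = final[preset.n_regulated_both_hosts:]
    if set(lag_genes) - set(both):
        raise SyntheticDataError(
            "planted lag genes exceed the both-host regulated count"
        )

    status = {g: "under" for g in under}
    status.update({g: "over" for g in over})
    status.update({g: "none" for g in null})

    profile_a1 = {}
    profile_a2 = {}
    profile_b = {}
    for gene in expressed:
        sign = {"over": 1, "under": -1, "none": 0}[status[gene]]
        if sign == 0:
            values = _profile(rng, None, 0, NULL_LOG2_MAX)
            profile_a1[gene] = values
            profile_a2[gene] = values.copy()
            continue
        if gene in lag_assignments:
            crossing = int(rng.choice([3, 4]))
            values = _profile(rng, crossing, sign, 0.6, stage1_max=0.3)
        else:
            crossing = int(rng.choice(STAGES_OF_INTEREST_A))
            values = _profile(rng, crossing, sign, 0.9)
        profile_a1[gene] = values
        profile_a2[gene] = (
            _profile(rng, None, 0, INCONSISTENT_LOG2_MAX)
            if gene in set(fail) else values.copy()
        )

    for gene in final:
        a_values = profile_a2[gene]
        sign = 1 if status[gene] == "over" else -1
        lag = lag_assignments.get(gene)
        if lag is not None:
            for _ in range(5000):
                b_values = np.roll(a_values, lag)
                result = cross_correlation(
                    _series(gene, HOST_A, a_values), _series(gene, HOST_B, b_values)
                )
                others = [
                    abs(v) for l, v in zip(result.lags, result.ccf) if l != lag
                ]
                if (
                    result.best_lag == lag
                    and abs(result.best_ccf) >= CCF_PLANTED_MIN
                    and max(others) <= CCF_NULL_MAX
                ):
                    break
                crossing = int(rng.choice([3, 4]))
                a_values = _profile(rng, crossing, sign, 0.6, stage1_max=0.3)
            else:  # pragma: no cover
                raise SyntheticDataError(f"could not plant lag for {gene}")
            profile_a1[gene] = a_values
            profile_a2[gene] = a_values.copy()
            profile_b[gene] = np.roll(a_values, lag)
            continue
        # Joint rejection sampling: mostly resample the heterologous-host
        # profile, but refresh the native profile too every 40 tries —
        # some native profiles admit no decorrelated partner at all lags.
        regulated_b = gene in set(both)
        for attempt in range(20000):
            if attempt and attempt % 40 == 0:
                crossing_a = int(rng.choice(STAGES_OF_INTEREST_A))
                a_values = _profile(rng, crossing_a, sign, 0.9)
            if regulated_b:
                crossing_b = int(rng.choice([3, 4, 5]))
                b_values = _profile(rng, crossing_b, sign, 0.9)
            else:
                b_values = _profile(rng, None, 0, INCONSISTENT_LOG2_MAX)
            if _max_abs_ccf(a_values, b_values) <= CCF_NULL_MAX:
                break
        else:  # pragma: no cover
            raise SyntheticDataError(f"could not decorrelate {gene}")
        profile_a1[gene] = a_values
        profile_a2[gene] = a_values.copy()
        profile_b[gene] = b_values

    def table(profiles: Mapping[str, np.ndarray], stages: Sequence[int]) -> pd.DataFrame:
        frame = pd.DataFrame.from_dict(
            {g: v for g, v in profiles.items()}, orient="index",
            columns=list(STAGES),
        )
        return frame[list(stages)].sort_index()

    lo, hi = noise.efficiency_range
    efficiencies = {
        gene: float(_rng(seed, 203, i).uniform(lo, hi))
        for i, gene in enumerate(sorted(expressed))
    }
    efficiencies.update({g: 1.0 for g in HOUSEKEEPING_GENES})
    efficiencies[WSP] = 1.0

    presence_rng = _rng(seed, 204)
    expressed_set = set(expressed)
    presence_rows = {}
    for gene in amplifiable:
        if gene in expressed_set:
            calls = presence_rng.random(4) < 0.8
            if not calls.any():
                calls[int(presence_rng.integers(4))] = True
        else:
            calls = np.zeros(4, dtype=bool)
        presence_rows[gene] = calls.astype(int)
    presence = pd.DataFrame.from_dict(
        presence_rows, orient="index", columns=list(STAGES_OF_INTEREST_A)
    ).sort_index()
    presence.index.name = "gene"

    return ExpressionTruth(
        amplifiable=amplifiable,
        expressed=sorted(expressed),
        status=status,
        s2_fail=sorted(fail),
        final=sorted(final),
        both_hosts=sorted(both),
        lag_assignments=lag_assignments,
        profiles={
            (HOST_A, 1): table(profile_a1, range(2, 7)),
            (HOST_A, 2): table(profile_a2, STAGES),
            (HOST_B, 3): table(profile_b, STAGES),
        },
        efficiencies=efficiencies,
        presence=presence,
    )


# ---------------------------------------------------------------------------
# qPCR dataset generator
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ["sample_id", "host", "stage", "pool", "campaign"]


def standard_design() -> pd.DataFrame:
    """The three-campaign sampling design: one pool per stage 2-6 in the
    native host (first sampling), triplicate pools per stage 1-7 in the
    native host (second sampling) and in the heterologous host (third)."""
    rows = []
    for stage in range(2, 7):
        rows.append((f"A1_s{stage}_p1", HOST_A, stage, 1, 1))
    for stage in STAGES:
        for pool in (1, 2, 3):
            rows.append((f"A2_s{stage}_p{pool}", HOST_A, stage, pool, 2))
    for stage in STAGES:
        for pool in (1, 2, 3):
            rows.append((f"B3_s{stage}_p{pool}", HOST_B, stage, pool, 3))
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def generate_qpcr_dataset(
    design: pd.DataFrame,
    folds: pd.DataFrame,
    noise: NoiseModel,
    seed: int,
    efficiencies: Mapping[str, float] | None = None,
    housekeeping: bool = True,
    latent_ct_sd: float = LATENT_CT_SD,
    technical_replicates: int = 2,
) -> pd.DataFrame:
    """Emit a long-format Ct table realizing a planted fold-change table.

    ``folds`` has columns ``gene, host, campaign, stage, fold`` giving each
    target gene's true expression relative to the calibrator stage.  Ct
    values follow Ct = base - (ln q + ln fold)/ln(1+E) where q is a latent
    per-sample template quantity shared by all genes of the sample (it
    cancels in calibrated ratios and drives the housekeeping stability
    index).  Gaussian per-well noise of ``noise.ct_sd`` cycles is added to
    each of the technical replicates.
    """
    noise.validate()
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise SyntheticDataError(f"design table missing columns: {missing}")
    for column in ("gene", "host", "campaign", "stage", "fold"):
        if column not in folds.columns:
            raise SyntheticDataError(f"fold table missing column: {column}")

    genes = sorted(folds["gene"].unique())
    eff = dict(efficiencies or {})
    eff_rng = _rng(seed, 301)
    lo, hi = noise.efficiency_range
    for gene in genes:
        eff.setdefault(gene, float(eff_rng.uniform(lo, hi)))
    for gene in HOUSEKEEPING_GENES + (WSP,):
        eff.setdefault(gene, 1.0)

    base_rng = _rng(seed, 302)
    base_ct = {g: float(base_rng.uniform(20.0, 28.0)) for g in genes}
    for g in HOUSEKEEPING_GENES + (WSP,):
        base_ct[g] = float(base_rng.uniform(16.0, 24.0))

    latent_rng = _rng(seed, 303)
    latent = {
        sid: float(latent_rng.normal(0.0, latent_ct_sd))
        for sid in design["sample_id"]
    }

    fold_lookup = {
        (r.gene, r.host, r.campaign, r.stage): math.log(r.fold)
        for r in folds.itertuples()
    }
    unstable = [g for g in HOUSEKEEPING_GENES if g not in STABLE_HOUSEKEEPING]
    noise_rng = _rng(seed, 304)
    drop_rng = _rng(seed, 305)
    rows = []
    for sample in design.itertuples():
        ln_q = latent[sample.sample_id] * math.log(2.0)
        emitted: list[tuple[str, float]] = []
        for gene in genes:
            key = (gene, sample.host, sample.campaign, sample.stage)
            if key not in fold_lookup:
                continue
            ln_fold = fold_lookup[key]
            ct = base_ct[gene] - (ln_q + ln_fold) / math.log(1.0 + eff[gene])
            if noise.dropout_rate and drop_rng.random() < noise.dropout_rate:
                ct = math.nan
            emitted.append((gene, ct))
        if housekeeping:
            for gene in STABLE_HOUSEKEEPING:
                ct = (base_ct[gene] - ln_q / math.log(2.0)
                      + float(noise_rng.normal(0.0, STABLE_CT_SD)))
                emitted.append((gene, ct))
            for gene in unstable:
                ct = (base_ct[gene] - ln_q / math.log(2.0)
                      + float(noise_rng.normal(0.0, UNSTABLE_CT_SD)))
                emitted.append((gene, ct))
            ct = (base_ct[WSP] - ln_q / math.log(2.0)
                  + float(noise_rng.normal(0.0, STABLE_CT_SD)))
            emitted.append((WSP, ct))
        for gene, ct in emitted:
            for _ in range(technical_replicates):
                well_ct = ct + float(noise_rng.normal(0.0, noise.ct_sd))
                rows.append(
                    (sample.sample_id, sample.host, sample.stage, sample.pool,
                     sample.campaign, gene, round(well_ct, 4) if not math.isnan(ct) else math.nan)
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "host", "stage", "pool", "campaign", "gene", "ct"]
    )


def generate_two_host_profiles(
    preset: FunnelPreset,
    lag_assignments: Mapping[str, int] | None,
    noise: NoiseModel,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Paired Ct datasets for the native (campaign 2) and heterologous
    (campaign 3) host, with the preset's cross-host lag structure planted.

    Passing an explicit ``lag_assignments`` map overrides the preset's lag
    counts (an empty map plants no cross-host correlation); lags with
    |lag| >= the number of stages are rejected.
    """
    if lag_assignments is not None:
        for gene, lag in lag_assignments.items():
            if abs(lag) >= len(STAGES):
                raise SyntheticDataError(
                    f"lag {lag} for {gene} exceeds the stage grid"
                )
        from dataclasses import replace

        lags = list(lag_assignments.values())
        preset = replace(
            preset,
            n_ccf_lag1=sum(1 for l in lags if abs(l) == 1),
            n_ccf_lag0=sum(1 for l in lags if l == 0),
        )
    candidates = [f"wVul_{i + 1:04d}" for i in range(max(preset.n_candidates, 1))]
    truth = build_expression_truth(preset, candidates, noise, seed)
    design = standard_design()
    folds = truth.folds()
    ct = generate_qpcr_dataset(
        design, folds, noise, seed, efficiencies=truth.efficiencies
    )
    ct_a = ct[ct["host"] == HOST_A].reset_index(drop=True)
    ct_b = ct[ct["host"] == HOST_B].reset_index(drop=True)
    return ct_a, ct_b, truth


# ---------------------------------------------------------------------------
# f element generator
# ---------------------------------------------------------------------------

@dataclass
class FElementTruth:
    members: dict[str, int]          # gene -> planted copy number
    identical: list[str]             # members with >= 1 exact copy
    records: list[ProteinRecord]


def generate_felement(
    candidates: Sequence[ProteinRecord],
    preset: FunnelPreset,
    seed: int,
    decoy_identity: float = 0.80,
) -> FElementTruth:
    """Build a synthetic f-element protein set from the final candidates.

    ``preset.n_in_felement`` candidates are represented with copy numbers
    uniform over ``preset.copy_number_range``; ``n_identical_in_felement``
    of them have at least one 100%-identical copy, the other copies are
    mutated to identities in [0.9535, 1.0).  The remaining candidates
    contribute decoys mutated to ``decoy_identity`` (< 0.90, so they fail
    the search threshold), alongside unrelated random proteins.
    """
    preset.validate()
    if preset.n_in_felement > len(candidates):
        raise SyntheticDataError(
            f"n_in_felement = {preset.n_in_felement} exceeds candidate count "
            f"{len(candidates)}"
        )
    if not 0.0 < decoy_identity < 0.90:
        raise SyntheticDataError("decoy identity must lie in (0, 0.90)")
    rng = _rng(seed, 401)
    order = rng.permutation(len(candidates))
    member_records = [candidates[i] for i in order[: preset.n_in_felement]]
    identical_set = {
        r.gene_id for r in member_records[: preset.n_identical_in_felement]
    }
    lo, hi = preset.copy_number_range
    records: list[ProteinRecord] = []
    members: dict[str, int] = {}
    counter = 0

    def add(sequence: str) -> None:
        nonlocal counter
        counter += 1
        records.append(ProteinRecord("f_element", f"fel_{counter:04d}", sequence))

    for record in member_records:
        copies = int(rng.integers(lo, hi + 1))
        members[record.gene_id] = copies
        max_sub = max(1, math.floor(len(record.sequence) * 0.0465))
        for copy_index in range(copies):
            if record.gene_id in identical_set and copy_index == 0:
                add(record.sequence)
            else:
                n_sub = int(rng.integers(1, max_sub + 1))
                add(_mutate_spread(record.sequence, n_sub, rng))
    # decoys: non-member candidates at sub-threshold identity
    for i in order[preset.n_in_felement:]:
        record = candidates[i]
        n_sub = round(len(record.sequence) * (1.0 - decoy_identity))
        add(_mutate_spread(record.sequence, n_sub, rng))
    # unrelated background proteins
    for _ in range(10):
        add(random_protein(rng, int(rng.integers(60, 120))))

    return FElementTruth(
        members=members, identical=sorted(identical_set), records=records
    )
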