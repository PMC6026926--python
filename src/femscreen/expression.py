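"""Reference-gene selection and efficiency-corrected relative expression.

Ct data live in a tidy table with one row per well measurement and columns
``sample_id, host, stage, pool, campaign, gene, ct`` (technical replicates
are averaged at the Ct level before any ratio is computed).  Expression is
quantified by the efficiency-corrected ratio

    ratio(sample) = (1+E_t)^(Ct_t,cal - Ct_t,s)
                    / geomean_r (1+E_r)^(Ct_r,cal - Ct_r,s)

calibrated against the mean Ct of the calibrator developmental stage
(stage 2 by default) within the same host and sampling campaign — the
Pfaffl model, reducing to 2^-ddCt when all efficiencies are 1.  Reference
genes are chosen BestKeeper-style: each housekeeping candidate is
correlated against the per-sample geometric mean Ct index, kept when
r > 0.95, and verified to be stage-invariant relative to the *wsp*
(Wolbachia genome copy) signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "host", "stage", "pool", "campaign", "gene", "ct"]
DEFAULT_CALIBRATOR_STAGE = 2
DEFAULT_STAGES_OF_INTEREST = (3, 4, 5, 6)
DEFAULT_LOW = 0.5
DEFAULT_HIGH = 2.0
DEFAULT_R_MIN = 0.95
#: practical-equivalence margin (cycles) for the stage-invariance check: a
#: reference gene is only rejected when the stage effect is both significant
#: and larger than this span of stage means.
STAGE_INVARIANCE_TOL_CT = 0.3


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionProfile:
    """Calibrated expression ratios for one gene in one host.

    ``samples`` has one row per biological sample with columns
    ``sample_id, stage, pool, campaign, ratio``.
    """

    gene: str
    host: str
    samples: pd.DataFrame

    def stage_means(self, campaign: int | None = None) -> pd.Series:
        df = self.samples
        if campaign is not None:
            df = df[df["campaign"] == campaign]
        return df.groupby("stage")["ratio"].mean()

    def replicate_ratios(self, campaign: int | None = None) -> pd.DataFrame:
        df = self.samples
        if campaign is not None:
            df = df[df["campaign"] == campaign]
        return df[["stage", "pool", "ratio"]]


@dataclass
class DECall:
    gene: str
    status: str  # over / under / none
    supporting_stages: tuple[int, ...] = field(default_factory=tuple)


def validate_ct_frame(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ExpressionError(f"Ct table missing columns: {missing}")
    bad_stage = set(ct["stage"].unique()) - set(range(1, 9))
    if bad_stage:
        raise ExpressionError(f"stages outside 1..8: {sorted(bad_stage)}")
    return ct


def average_technical_replicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical-replicate wells to one Ct per sample and gene."""
    validate_ct_frame(ct)
    keys = ["sample_id", "host", "stage", "pool", "campaign", "gene"]
    return ct.groupby(keys, as_index=False)["ct"].mean()


def _pivot(ct: pd.DataFrame) -> pd.DataFrame:
    """Samples x genes Ct matrix."""
    return ct.pivot_table(index="sample_id", columns="gene", values="ct")


def select_reference_genes(
    ct_housekeeping: pd.DataFrame,
    ct_wsp: pd.DataFrame | None = None,
    r_min: float = DEFAULT_R_MIN,
    method: str = "index",
    anova_alpha: float = 0.05,
    stage_tol_ct: float = STAGE_INVARIANCE_TOL_CT,
) -> list[str]:
    """Select stable reference genes from housekeeping-gene Ct data.

    The stability index is the per-sample geometric mean Ct over all
    housekeeping candidates; genes whose Ct correlates with the index at
    Pearson r > ``r_min`` are kept (``method="pairwise"`` instead requires
    r > r_min against every other selected gene).  When ``ct_wsp`` is given,
    each selected gene is additionally verified to be stage-invariant
    relative to the *wsp* signal: it is dropped only when a one-way ANOVA on
    Ct_gene - Ct_wsp across stages is significant (p <= anova_alpha) *and*
    the span of its stage means exceeds ``stage_tol_ct`` cycles, so that a
    statistically detectable but practically negligible drift does not
    disqualify an otherwise stable gene.
    """
    ct_housekeeping = average_technical_replicates(ct_housekeeping)
    matrix = _pivot(ct_housekeeping)
    if matrix.shape[0] < 3:
        raise ExpressionError("reference selection needs at least 3 samples")
    if matrix.shape[1] < 2:
        raise ExpressionError("reference selection needs at least 2 genes")
    matrix = matrix.dropna(axis=0)
    index = np.exp(np.log(matrix).mean(axis=1))  # geometric mean Ct per sample

    selected: list[str] = []
    correlations: dict[str, float] = {}
    for gene in matrix.columns:
        x = matrix[gene].to_numpy()
        if np.std(x) == 0.0:
            continue  # constant Ct: correlation undefined, exclude
        correlations[gene] = float(stats.pearsonr(x, index.to_numpy())[0])
        if correlations[gene] > r_min:
            selected.append(gene)
    if method == "pairwise":
        selected = [
            g
            for g in selected
            if all(
                g == h
                or float(stats.pearsonr(matrix[g], matrix[h])[0]) > r_min
                for h in selected
            )
        ]
    elif method != "index":
        raise ExpressionError(f"unknown selection method {method!r}")

    if ct_wsp is not None and selected:
        wsp = average_technical_replicates(ct_wsp).set_index("sample_id")["ct"]
        stages = ct_housekeeping.drop_duplicates("sample_id").set_index("sample_id")[
            "stage"
        ]
        kept = []
        for gene in selected:
            delta = (matrix[gene] - wsp.reindex(matrix.index)).dropna()
            groups = [
                delta[stages.reindex(delta.index) == s].to_numpy()
                for s in sorted(stages.reindex(delta.index).unique())
            ]
            groups = [g for g in groups if g.size > 0]
            if len(groups) < 2:
                kept.append(gene)
                continue
            stage_means = np.array([g.mean() for g in groups])
            span = float(stage_means.max() - stage_means.min())
            try:
                p = stats.f_oneway(*groups).pvalue
            except Exception:
                p = 1.0
            if np.isnan(p) or p > anova_alpha or span <= stage_tol_ct:
                kept.append(gene)
        selected = kept
    return sorted(selected)


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    references: Iterable[str],
    efficiencies: Mapping[str, float],
    calibrator_stage: int = DEFAULT_CALIBRATOR_STAGE,
) -> ExpressionProfile:
    """Efficiency-corrected expression ratio of ``target`` per sample.

    The calibrator Ct of every gene is the mean Ct over calibrator-stage
    samples of the same host and campaign.  Efficiencies must lie in [0, 1]
    (amplification factor 1 + E).
    """
    references = sorted(set(references))
    if not references:
        raise ExpressionError("at least one reference gene is required")
    ct = average_technical_replicates(ct)
    genes = [target] + references
    for gene in genes:
        if gene not in set(ct["gene"]):
            raise ExpressionError(f"gene {gene!r} absent from Ct table")
        e = efficiencies.get(gene)
        if e is None or not 0.0 <= e <= 1.0:
            raise ExpressionError(f"efficiency for {gene!r} missing or outside [0, 1]")
    sub = ct[ct["gene"].isin(genes)]
    hosts = sub["host"].unique()
    if len(hosts) != 1:
        raise ExpressionError("relative_expression expects a single host per call")

    rows = []
    for campaign, group in sub.groupby("campaign"):
        if target not in set(group["gene"]):
            continue  # target not measured in this sampling campaign
        cal = group[group["stage"] == calibrator_stage]
        cal_ct = cal.groupby("gene")["ct"].mean()
        absent = [g for g in genes if g not in cal_ct.index or pd.isna(cal_ct[g])]
        if absent:
            raise ExpressionError(
                f"calibrator stage {calibrator_stage} missing Ct for {absent} "
                f"in campaign {campaign}"
            )
        wide = group.pivot_table(
            index=["sample_id", "stage", "pool"], columns="gene", values="ct"
        )
        for (sample_id, stage, pool), row in wide.iterrows():
            if pd.isna(row.get(target)):
                continue
            target_term = (1.0 + efficiencies[target]) ** (
                cal_ct[target] - row[target]
            )
            ref_logs = []
            for ref in references:
                if pd.isna(row.get(ref)):
                    continue
                ref_logs.append(
                    (cal_ct[ref] - row[ref]) * np.log(1.0 + efficiencies[ref])
                )
            if not ref_logs:
                continue
            ref_term = np.exp(np.mean(ref_logs))  # geometric mean over references
            rows.append(
                {
                    "sample_id": sample_id,
                    "stage": int(stage),
                    "pool": pool,
                    "campaign": campaign,
                    "ratio": float(target_term / ref_term),
                }
            )
    frame = pd.DataFrame(rows, columns=["sample_id", "stage", "pool", "campaign", "ratio"])
    return ExpressionProfile(gene=target, host=str(hosts[0]), samples=frame)


def classify_de(
    profile: ExpressionProfile,
    stages_of_interest: Iterable[int] = DEFAULT_STAGES_OF_INTEREST,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    campaign: int | None = None,
) -> DECall:
    """Classify a profile as over-/under-expressed from per-stage mean ratios.

    ``over`` requires a mean ratio >= ``high`` at >= 1 stage of interest,
    ``under`` a mean ratio <= ``low`` (both thresholds inclusive); when both
    occur the status with the larger |log2 ratio| departure wins.
    """
    stages = sorted(set(stages_of_interest))
    if not stages:
        raise ExpressionError("stages_of_interest is empty")
    means = profile.stage_means(campaign=campaign)
    means = means[means.index.isin(stages)]
    over_stages = tuple(int(s) for s, v in means.items() if v >= high)
    under_stages = tuple(int(s) for s, v in means.items() if v <= low)
    if over_stages and under_stages:
        max_over = float(np.max(np.log2(means[list(over_stages)])))
        max_under = float(np.max(-np.log2(means[list(under_stages)])))
        if max_over >= max_under:
            return DECall(profile.gene, "over", over_stages)
        return DECall(profile.gene, "under", under_stages)
    if over_stages:
        return DECall(profile.gene, "over", over_stages)
    if under_stages:
        return DECall(profile.gene, "under", under_stages)
    return DECall(profile.gene, "none", ())


def presence_filter(
    presence: pd.DataFrame, stages: Iterable[int] = DEFAULT_STAGES_OF_INTEREST
) -> list[str]:
    """Genes detected (RT-PCR positive) at >= 1 of the stages of interest.

    ``presence`` is indexed by gene with one boolean/0-1 column per stage.
    """
    stages = sorted(set(stages))
    cols = [c for c in presence.columns if int(c) in stages]
    if len(cols) < len(stages):
        raise ExpressionError(
            f"presence matrix lacks stages {sorted(set(stages) - {int(c) for c in presence.columns})}"
        )
    mask = presence[cols].astype(bool).any(axis=1)
    return sorted(presence.index[mask])


def consistency_filter(
    calls_s1: Iterable[DECall],
    profiles_s2: Mapping[str, ExpressionProfile],
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    campaign: int | None = None,
) -> list[str]:
    """Keep genes whose second-sampling replicates confirm the first call.

    A gene called over (under) in sampling 1 is retained iff at least one
    individual sampling-2 replicate ratio reaches >= high (<= low) at >= 1
    stage; genes failing in every replicate at every stage are dropped.
    """
    retained = []
    missing = []
    for call in calls_s1:
        if call.status not in ("over", "under"):
            raise ExpressionError(
                f"consistency filter expects over/under calls, got {call.status!r} "
                f"for {call.gene}"
            )
        profile = profiles_s2.get(call.gene)
        if profile is None:
            missing.append(call.gene)
            continue
        ratios = profile.replicate_ratios(campaign=campaign)["ratio"]
        if call.status == "over" and (ratios >= high).any():
            retained.append(call.gene)
        elif call.status == "under" and (ratios <= low).any():
            retained.append(call.gene)
    if missing:
        raise ExpressionError(
            f"genes called in sampling 1 but absent from sampling 2: {sorted(missing)}"
        )
    return sorted(retained)


def profile_table(profiles: Iterable[ExpressionProfile]) -> pd.DataFrame:
    """Long-format export: gene, host, stage, mean ratio and replicate list."""
    rows = []
    for profile in profiles:
        grouped = profile.samples.groupby("stage")["ratio"]
        for stage, values in grouped:
            rows.append(
                {
                    "gene": profile.gene,
                    "host": profile.host,
                    "stage": int(stage),
                    "ratio_mean": float(values.mean()),
                    "ratio_reps": ";".join(f"{v:.4f}" for v in values),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "host", "stage", "ratio_mean", "ratio_reps"])
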