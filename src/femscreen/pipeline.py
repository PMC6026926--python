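"""End-to-end orchestration of the feminization-candidate screen.

``run_screen`` executes the stages in order — annotation filter cascade,
core-genome filter, conservation filter against the non-feminizing sister
strain, RT-PCR presence filter, first-sampling differential expression,
second-sampling consistency, two-host classification, cross-host lagged
correlation, and the f-element search — writing every intermediate artifact
and a funnel report that records the gene count surviving each named
stage.  ``make_paper_fixture`` materializes the default synthetic dataset
so that a full run is reproducible from a seed and a config file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidate_filter as cf
from . import crosshost, expression, felement, homology
from . import synthetic_data as sd

logger = logging.getLogger("femscreen")

EXIT_OK = 0
EXIT_SCHEMA_ERROR = 2
EXIT_STAGE_FAILURE = 3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All inputs and thresholds of a screen run.

    Threshold defaults: 150 bp length cut; 70% identity and 1e-6 e-value
    for ortholog clustering; 100% identity over >= 90% length for the
    conservation filter; r > 0.95 for reference genes; 0.5/2-fold
    differential-expression thresholds calibrated to stage 2 over stages
    3-6 (2-5 in the shifted heterologous host); 0.001 e-value and 90%
    identity for the f-element search.
    """

    fixture_dir: str = "fixture"
    outdir: str = "results"
    seed: int = 42
    min_length_bp: int = 150
    cluster_min_identity: float = 0.70
    cluster_max_evalue: float = 1e-6
    nonfem_min_identity: float = 1.0
    nonfem_min_coverage: float = 0.90
    reference_r_min: float = 0.95
    de_low: float = 0.5
    de_high: float = 2.0
    calibrator_stage: int = 2
    stages_of_interest_a: tuple[int, ...] = sd.STAGES_OF_INTEREST_A
    stages_of_interest_b: tuple[int, ...] = sd.STAGES_OF_INTEREST_B
    max_lag: int = 2
    felement_max_evalue: float = 1e-3
    felement_min_identity: float = 0.90
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        for key in ("stages_of_interest_a", "stages_of_interest_b"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages_of_interest_a"] = list(self.stages_of_interest_a)
        data["stages_of_interest_b"] = list(self.stages_of_interest_b)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


@dataclass
class FunnelReport:
    annotated: int = 0
    post_annotation_filters: int = 0
    candidates: int = 0
    amplifiable: int = 0
    expressed: int = 0
    de_sampling1_under: int = 0
    de_sampling1_over: int = 0
    final_candidates: int = 0
    regulated_both_hosts: int = 0
    crosscorr_significant: int = 0
    crosscorr_lag1: int = 0
    in_felement: int = 0
    identical_in_felement: int = 0
    removals: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_text(self) -> str:
        lines = ["Feminization candidate screen - funnel report", ""]
        for name in (
            "annotated", "post_annotation_filters", "candidates", "amplifiable",
            "expressed", "de_sampling1_under", "de_sampling1_over",
            "final_candidates", "regulated_both_hosts", "crosscorr_significant",
            "crosscorr_lag1", "in_felement", "identical_in_felement",
        ):
            lines.append(f"{name:28s} {getattr(self, name)}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def make_paper_fixture(
    outdir,
    seed: int,
    preset: sd.FunnelPreset = sd.PAPER_FUNNEL,
    noise: sd.NoiseModel = sd.NoiseModel(),
    force: bool = False,
) -> Path:
    """Write the full synthetic dataset plus truth tables to ``outdir``.

    Deterministic: a fixed seed reproduces the files byte for byte.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise PipelineError("fixture", f"{outdir} exists and is not empty (use force)")
    (outdir / "references").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    bundle = sd.generate_annotation(preset, seed)
    cf.write_annotation(bundle.genes, outdir / "annotation.tsv")
    for genome, records in sorted(bundle.references.items()):
        homology.write_fasta(records, outdir / "references" / f"{genome}.faa")
    homology.write_fasta(bundle.nonfeminizer, outdir / "nonfeminizer.faa")

    candidates = bundle.gene_ids("candidate")
    truth = sd.build_expression_truth(preset, candidates, noise, seed)
    design = sd.standard_design()
    ct = sd.generate_qpcr_dataset(
        design, truth.folds(), noise, seed, efficiencies=truth.efficiencies
    )
    ct.to_csv(outdir / "qpcr_ct.csv", index=False, float_format="%.4f")
    truth.presence.to_csv(outdir / "presence.tsv", sep="\t")
    pd.DataFrame(
        sorted(truth.efficiencies.items()), columns=["gene", "efficiency"]
    ).to_csv(outdir / "efficiencies.tsv", sep="\t", index=False, float_format="%.6f")

    finals = bundle.proteins(truth.final)
    fel = sd.generate_felement(finals, preset, seed)
    homology.write_fasta(fel.records, outdir / "felement.faa")

    bundle.truth.to_csv(outdir / "truth" / "categories.tsv", sep="\t", index=False)
    expr_truth = pd.DataFrame(
        {
            "gene": sorted(truth.status),
            "status_s1": [truth.status[g] for g in sorted(truth.status)],
            "final": [int(g in set(truth.final)) for g in sorted(truth.status)],
            "both_hosts": [int(g in set(truth.both_hosts)) for g in sorted(truth.status)],
            "lag": [truth.lag_assignments.get(g, "") for g in sorted(truth.status)],
        }
    )
    expr_truth.to_csv(outdir / "truth" / "expression.tsv", sep="\t", index=False)
    truth.folds().to_csv(
        outdir / "truth" / "folds.tsv", sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame(
        [
            {"gene": g, "copies": c, "identical": int(g in set(fel.identical))}
            for g, c in sorted(fel.members.items())
        ]
    ).to_csv(outdir / "truth" / "felement.tsv", sep="\t", index=False)

    config = RunConfig(fixture_dir=str(outdir), seed=seed)
    config.to_yaml(outdir / "config.yaml")
    return outdir


# ---------------------------------------------------------------------------
# Screen execution
# ---------------------------------------------------------------------------

def _log2_series(profile: expression.ExpressionProfile, campaign: int):
    means = profile.stage_means(campaign=campaign).sort_index()
    replicates = tuple(
        tuple(np.log2(group["ratio"].to_numpy()))
        for _, group in profile.samples[profile.samples["campaign"] == campaign]
        .groupby("stage")
    )
    return crosshost.StageSeries(
        host=profile.host,
        gene=profile.gene,
        stages=tuple(int(s) for s in means.index),
        values=tuple(float(np.log2(v)) for v in means.to_numpy()),
        replicates=replicates,
    )


def run_screen(config: RunConfig) -> FunnelReport:
    """Execute the full screen from a fixture directory; returns the report
    and writes all per-stage artifacts to ``config.outdir``."""
    logging.basicConfig(level=config.log_level)
    fixture = Path(config.fixture_dir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = FunnelReport()

    # --- stage 1: annotation + homology filter cascade -------------------
    try:
        genes = cf.read_annotation(fixture / "annotation.tsv")
    except FileNotFoundError as exc:
        raise PipelineError("annotation", str(exc)) from exc
    report.annotated = len(genes)
    if not genes:
        (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        return report

    try:
        focal = [homology.ProteinRecord(sd.FOCAL_GENOME, g.gene_id, g.protein)
                 for g in genes]
        references = []
        ref_dir = fixture / "references"
        genome_names = []
        for path in sorted(ref_dir.glob("*.faa")):
            genome_names.append(path.stem)
            references.extend(homology.read_fasta(path, path.stem))
        logger.info("clustering %d focal + %d reference proteins",
                    len(focal), len(references))
        hits = homology.search_hits(focal + references, mode="local")
        groups = homology.cluster_orthologs(
            hits, config.cluster_min_identity, config.cluster_max_evalue
        )
        core = homology.core_genome(groups, genome_names) if genome_names else []
        stage1 = cf.filter_annotation(genes, config.min_length_bp)
        report.post_annotation_filters = len(stage1.survivors)
        stage2 = cf.filter_core(stage1.survivors, core, sd.FOCAL_GENOME)

        nonfem = homology.read_fasta(fixture / "nonfeminizer.faa", sd.NONFEM_GENOME)
        survivors = [r for r in focal if r.gene_id in set(stage2.survivors)]
        nonfem_hits = homology.search_hits_between(survivors, nonfem, mode="local")
        stage3 = cf.filter_conserved_vs_nonfeminizer(
            stage2.survivors, nonfem_hits,
            config.nonfem_min_identity, config.nonfem_min_coverage,
        )
        cascade = cf.FilterResult(
            survivors=stage3.survivors,
            removals=stage1.removals + stage2.removals + stage3.removals,
        )
        cascade.check_partition([g.gene_id for g in genes])
        for name, ids in cascade.removals:
            logger.debug("filter %s removed %d genes", name, len(ids))
        report.candidates = len(cascade.survivors)
        report.removals = {name: len(ids) for name, ids in cascade.removals}
        homology.hits_to_frame(nonfem_hits).to_csv(
            outdir / "nonfeminizer_hits.tsv", sep="\t", index=False
        )
        (outdir / "filter_audit.json").write_text(
            json.dumps(cf.audit_report(cascade), indent=2)
        )
    except (homology.HomologyError, cf.FilterError) as exc:
        raise PipelineError("candidate_filter", str(exc)) from exc

    # --- stage 2: presence screen ----------------------------------------
    try:
        presence = pd.read_csv(fixture / "presence.tsv", sep="\t", index_col="gene")
        presence.columns = [int(c) for c in presence.columns]
        report.amplifiable = len(presence)
        expressed = expression.presence_filter(presence, config.stages_of_interest_a)
        report.expressed = len(expressed)
    except (FileNotFoundError, expression.ExpressionError) as exc:
        raise PipelineError("presence", str(exc)) from exc

    # --- stage 3: expression profiling ------------------------------------
    try:
        ct = pd.read_csv(fixture / "qpcr_ct.csv")
        expression.validate_ct_frame(ct)
        efficiencies = dict(
            pd.read_csv(fixture / "efficiencies.tsv", sep="\t")
            .set_index("gene")["efficiency"]
        )
        hk = ct[ct["gene"].isin(sd.HOUSEKEEPING_GENES)]
        wsp = ct[ct["gene"] == sd.WSP]
        refs = expression.select_reference_genes(
            hk, wsp, r_min=config.reference_r_min
        )
        logger.info("selected reference genes: %s", refs)
        if not refs:
            raise expression.ExpressionError("no stable reference genes found")
        ct_a = ct[ct["host"] == sd.HOST_A]
        ct_b = ct[ct["host"] == sd.HOST_B]
        profiles_a = {
            gene: expression.relative_expression(
                ct_a, gene, refs, efficiencies, config.calibrator_stage
            )
            for gene in expressed
        }
        calls_s1 = {
            gene: expression.classify_de(
                profiles_a[gene], config.stages_of_interest_a,
                config.de_low, config.de_high, campaign=1,
            )
            for gene in expressed
        }
        under = sorted(g for g, c in calls_s1.items() if c.status == "under")
        over = sorted(g for g, c in calls_s1.items() if c.status == "over")
        report.de_sampling1_under = len(under)
        report.de_sampling1_over = len(over)
        de_calls = [calls_s1[g] for g in under + over]
        finals = expression.consistency_filter(
            de_calls, profiles_a, config.de_low, config.de_high, campaign=2
        )
        report.final_candidates = len(finals)
        expression.profile_table(
            [profiles_a[g] for g in sorted(profiles_a)]
        ).to_csv(outdir / "expression_hostA.tsv", sep="\t", index=False,
                 float_format="%.4f")
    except expression.ExpressionError as exc:
        raise PipelineError("expression", str(exc)) from exc

    # --- stage 4: heterologous host + cross-correlation -------------------
    try:
        profiles_b = {
            gene: expression.relative_expression(
                ct_b, gene, refs, efficiencies, config.calibrator_stage
            )
            for gene in finals
        }
        calls_b = {
            gene: expression.classify_de(
                profiles_b[gene], config.stages_of_interest_b,
                config.de_low, config.de_high, campaign=3,
            )
            for gene in finals
        }
        both = sorted(
            g for g in finals
            if calls_s1[g].status != "none" and calls_b[g].status != "none"
        )
        report.regulated_both_hosts = len(both)

        ccf_rows = []
        significant = []
        lag1 = []
        for gene in finals:
            series_a = _log2_series(profiles_a[gene], campaign=2)
            series_b = _log2_series(profiles_b[gene], campaign=3)
            result = crosshost.cross_correlation(series_a, series_b, config.max_lag)
            if result.significant:
                significant.append(gene)
                if abs(result.best_lag) == 1:
                    lag1.append(gene)
            ccf_rows.append(
                {
                    "gene": gene,
                    "best_lag": result.best_lag,
                    "ccf_at_best": round(result.best_ccf, 4),
                    "significant": int(result.significant),
                    "eta_sq_hostA": (None if result.eta_sq_a is None
                                     else round(result.eta_sq_a, 4)),
                    "eta_sq_hostB": (None if result.eta_sq_b is None
                                     else round(result.eta_sq_b, 4)),
                    "flags": ";".join(result.flags),
                }
            )
        report.crosscorr_significant = len(significant)
        report.crosscorr_lag1 = len(lag1)
        pd.DataFrame(ccf_rows).to_csv(
            outdir / "crosshost.tsv", sep="\t", index=False
        )
        expression.profile_table(
            [profiles_b[g] for g in sorted(profiles_b)]
        ).to_csv(outdir / "expression_hostB.tsv", sep="\t", index=False,
                 float_format="%.4f")
    except (expression.ExpressionError, crosshost.CrossHostError) as exc:
        raise PipelineError("crosshost", str(exc)) from exc

    # --- stage 5: f element ------------------------------------------------
    try:
        gene_proteins = {g.gene_id: g.protein for g in genes}
        final_records = [
            homology.ProteinRecord(sd.FOCAL_GENOME, g, gene_proteins[g])
            for g in finals
        ]
        fel_records = homology.read_fasta(fixture / "felement.faa", "f_element")
        fel_hits = felement.search_felement(
            final_records, fel_records,
            config.felement_max_evalue, config.felement_min_identity,
        )
        report.in_felement = len(fel_hits)
        report.identical_in_felement = sum(
            1 for h in fel_hits if h.max_identity >= 100.0 - 1e-9
        )
        felement.hits_table(fel_hits).to_csv(
            outdir / "felement_hits.tsv", sep="\t", index=False
        )
    except felement.FElementError as exc:
        raise PipelineError("felement", str(exc)) from exc

    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (outdir / "report.txt").write_text(report.to_text())
    return report


def plot_profiles(profiles, path, campaign: int | None = None) -> None:
    """Small per-gene log2 expression figure (one panel per gene)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profiles = list(profiles)
    n = len(profiles)
    ncols = min(5, max(1, n))
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                             squeeze=False)
    for ax, profile in zip(axes.flat, profiles):
        means = profile.stage_means(campaign=campaign)
        ax.plot(means.index, np.log2(means.to_numpy()), marker="o")
        ax.axhline(1.0, color="grey", lw=0.5, ls="--")
        ax.axhline(-1.0, color="grey", lw=0.5, ls="--")
        ax.set_title(f"{profile.gene} ({profile.host})", fontsize=8)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
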