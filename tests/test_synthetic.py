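"""Generator bookkeeping: planted categories, Ct construction round trips,
housekeeping correlation structure and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from femscreen import synthetic_data as sd
from femscreen.candidate_filter import filter_annotation
from femscreen.expression import (
    average_technical_replicates, relative_expression,
)


def test_mutate_to_identity_substitution_counts():
    rng = np.random.default_rng(0)
    seq43 = sd.random_protein(rng, 43)
    mutated = sd.mutate_to_identity(seq43, 0.9535, seed=1)
    mismatches = sum(a != b for a, b in zip(seq43, mutated))
    assert mismatches == 2  # round(43 * 0.0465)
    assert (43 - mismatches) / 43 == pytest.approx(0.953488, abs=1e-6)

    assert sd.mutate_to_identity(seq43, 1.0, seed=1) == seq43
    seq10 = sd.random_protein(rng, 10)
    mutated10 = sd.mutate_to_identity(seq10, 0.5, seed=2)
    assert sum(a != b for a, b in zip(seq10, mutated10)) == 5
    assert len(mutated10) == 10  # no indels


def test_mutate_to_identity_validation():
    with pytest.raises(sd.SyntheticDataError):
        sd.mutate_to_identity("", 0.9, seed=0)
    with pytest.raises(sd.SyntheticDataError):
        sd.mutate_to_identity("MKVLA", 0.0, seed=0)
    with pytest.raises(sd.SyntheticDataError):
        sd.mutate_to_identity("MKVLAMKVLA", 0.05, seed=0)  # below 1/L resolution


def test_preset_invariants_rejected(mini_preset):
    bad = dataclasses.replace(mini_preset, n_repeats=mini_preset.n_genes + 1)
    with pytest.raises(sd.SyntheticDataError, match="n_genes"):
        bad.validate()
    with pytest.raises(sd.SyntheticDataError, match="n_fail_s2"):
        dataclasses.replace(mini_preset, n_fail_s2=99).validate()
    with pytest.raises(sd.SyntheticDataError, match="copy_number_range"):
        dataclasses.replace(mini_preset, copy_number_range=(0, 5)).validate()


def test_generate_annotation_plants_exact_disjoint_categories(mini_preset):
    bundle = sd.generate_annotation(mini_preset, seed=5)
    assert len(bundle.genes) == mini_preset.n_genes
    counts = bundle.truth["category"].value_counts()
    assert counts["repeat"] == mini_preset.n_repeats
    assert counts["pseudogene"] == mini_preset.n_pseudogenes
    assert counts["short"] == mini_preset.n_short
    assert counts["split_chunk"] == mini_preset.n_split_chunks
    assert counts["core"] == mini_preset.n_core
    assert counts["identical_nonfem"] == mini_preset.n_identical_to_nonfeminizer
    # categories are disjoint flags, short genes are the only < 150 bp ones
    for gene, category in zip(bundle.genes, bundle.truth["category"]):
        flags = [gene.is_repeat, gene.is_pseudogene, gene.is_split_chunk]
        assert sum(flags) <= 1
        assert (gene.length_bp < 150) == (category == "short")
    # every core gene has a homolog in each reference genome
    for genome in sd.REFERENCE_GENOMES:
        assert len(bundle.references[genome]) == mini_preset.n_core
    result = filter_annotation(bundle.genes)
    assert result.counts["repeat"] == mini_preset.n_repeats
    assert result.counts["short"] == mini_preset.n_short


def test_single_gene_annotation_and_flag_precedence():
    preset = sd.FunnelPreset(
        n_genes=1, n_repeats=0, n_pseudogenes=0, n_short=0, n_split_chunks=0,
        n_core=0, n_identical_to_nonfeminizer=0, n_amplifiable=0, n_expressed=0,
        n_under_s1=0, n_over_s1=0, n_fail_s2=0, n_regulated_both_hosts=0,
        n_ccf_lag1=0, n_ccf_lag0=0, n_in_felement=0, n_identical_in_felement=0,
    )
    bundle = sd.generate_annotation(preset, seed=0)
    gene = bundle.genes[0]
    assert not (gene.is_repeat or gene.is_pseudogene or gene.is_split_chunk)


def test_generators_are_deterministic(mini_preset):
    first = sd.generate_annotation(mini_preset, seed=9)
    second = sd.generate_annotation(mini_preset, seed=9)
    assert [g.protein for g in first.genes] == [g.protein for g in second.genes]
    other = sd.generate_annotation(mini_preset, seed=10)
    assert [g.protein for g in first.genes] != [g.protein for g in other.genes]
    # different seeds preserve the planted counts
    assert first.truth["category"].value_counts().to_dict() == \
        other.truth["category"].value_counts().to_dict()


def simple_folds(fold, stage=3):
    rows = [{"gene": "tgt", "host": sd.HOST_A, "campaign": 2, "stage": s,
             "fold": fold if s == stage else 1.0} for s in sd.STAGES]
    return pd.DataFrame(rows)


def test_noiseless_ct_shift_is_analytically_forced():
    # fold 2 at one stage, E = 1, no noise, no latent spread:
    # Ct exactly one cycle below the calibrator Ct
    noise = sd.NoiseModel(ct_sd=0.0)
    ct = sd.generate_qpcr_dataset(
        sd.standard_design(), simple_folds(2.0), noise, seed=1,
        efficiencies={"tgt": 1.0}, housekeeping=False, latent_ct_sd=0.0,
    )
    averaged = average_technical_replicates(ct)
    by_stage = averaged.groupby("stage")["ct"].mean()
    assert by_stage[3] == pytest.approx(by_stage[2] - 1.0, abs=1e-4)
    assert by_stage[4] == pytest.approx(by_stage[2], abs=1e-4)


def test_fold_round_trip_with_latent_spread():
    """With zero measurement noise the calibrated ratio recovers the planted
    fold exactly even though the latent per-sample template quantity moves
    every Ct: the latent term cancels between target and references."""
    noise = sd.NoiseModel(ct_sd=0.0, efficiency_range=(0.8, 0.8))
    folds = simple_folds(3.7, stage=5)
    ct = sd.generate_qpcr_dataset(
        sd.standard_design(), folds, noise, seed=2,
        efficiencies={"tgt": 0.8},
    )
    ct_a = ct[ct["host"] == sd.HOST_A]
    profile = relative_expression(
        ct_a, "tgt", list(sd.STABLE_HOUSEKEEPING),
        {**{g: 1.0 for g in sd.STABLE_HOUSEKEEPING}, "tgt": 0.8},
    )
    means = profile.stage_means(campaign=2)
    assert means[5] == pytest.approx(3.7, abs=0.01)
    assert means[4] == pytest.approx(1.0, abs=0.01)


def test_dropout_flags_all_target_wells():
    noise = sd.NoiseModel(ct_sd=0.0, dropout_rate=1.0)
    ct = sd.generate_qpcr_dataset(
        sd.standard_design(), simple_folds(2.0), noise, seed=3,
        efficiencies={"tgt": 1.0},
    )
    assert ct.loc[ct["gene"] == "tgt", "ct"].isna().all()
    assert ct.loc[ct["gene"] == sd.WSP, "ct"].notna().all()


def test_design_schema_validated():
    bad_design = sd.standard_design().drop(columns=["stage"])
    with pytest.raises(sd.SyntheticDataError, match="stage"):
        sd.generate_qpcr_dataset(bad_design, simple_folds(2.0), sd.NoiseModel(), 1)


def test_housekeeping_correlation_structure():
    """The six stable genes are mutually correlated above 0.95; the other
    nine carry enough independent noise to stay below 0.9 against them."""
    noise = sd.NoiseModel(ct_sd=0.05)
    folds = pd.DataFrame(columns=["gene", "host", "campaign", "stage", "fold"])
    ct = sd.generate_qpcr_dataset(sd.standard_design(), folds, noise, seed=4)
    matrix = average_technical_replicates(
        ct[ct["gene"].isin(sd.HOUSEKEEPING_GENES)]
    ).pivot_table(index="sample_id", columns="gene", values="ct")
    corr = matrix.corr()
    stable = list(sd.STABLE_HOUSEKEEPING)
    unstable = [g for g in sd.HOUSEKEEPING_GENES if g not in stable]
    assert (corr.loc[stable, stable].to_numpy() > 0.95).all()
    assert (corr.loc[stable, unstable].to_numpy() < 0.9).all()


def test_two_host_profiles_plant_the_requested_lags(mini_preset):
    ct_a, ct_b, truth = sd.generate_two_host_profiles(
        mini_preset, None, sd.NoiseModel(ct_sd=0.0), seed=6
    )
    assert sorted(truth.lag_assignments.values()) == [0, 1, 1]
    lagged = {g for g, l in truth.lag_assignments.items() if l == 1}
    table_a = truth.profiles[(sd.HOST_A, 2)]
    table_b = truth.profiles[(sd.HOST_B, 3)]
    for gene in lagged:
        a = table_a.loc[gene].to_numpy()
        b = table_b.loc[gene].to_numpy()
        # expected log-ratio at host-B stage s equals host-A stage s-1
        assert b[1:] == pytest.approx(a[:-1])
    for gene, lag in truth.lag_assignments.items():
        if lag == 0:
            assert table_b.loc[gene].to_numpy() == pytest.approx(
                table_a.loc[gene].to_numpy()
            )
    assert set(ct_a["host"]) == {sd.HOST_A}
    assert set(ct_b["host"]) == {sd.HOST_B}


def test_empty_lag_map_plants_no_cross_host_correlation(mini_preset):
    _, _, truth = sd.generate_two_host_profiles(
        mini_preset, {}, sd.NoiseModel(ct_sd=0.0), seed=7
    )
    assert truth.lag_assignments == {}
    with pytest.raises(sd.SyntheticDataError):
        sd.generate_two_host_profiles(
            mini_preset, {"g": 7}, sd.NoiseModel(), seed=7
        )
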