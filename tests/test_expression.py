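"""Efficiency-corrected ratios, reference selection and the DE filters."""

import numpy as np
import pandas as pd
import pytest

from femscreen import synthetic_data as sd
from femscreen.expression import (
    DECall, ExpressionError, ExpressionProfile, classify_de,
    consistency_filter, presence_filter, relative_expression,
    select_reference_genes,
)


def ct_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "host", "stage", "pool", "campaign", "gene", "ct"]
    )


def two_stage_frame(target_delta, ref_delta, target_cal=25.0, ref_cal=20.0):
    """Calibrator stage 2 and one test sample at stage 3, single campaign."""
    return ct_frame([
        ("s2", "A", 2, 1, 1, "tgt", target_cal),
        ("s2", "A", 2, 1, 1, "ref", ref_cal),
        ("s3", "A", 3, 1, 1, "tgt", target_cal - target_delta),
        ("s3", "A", 3, 1, 1, "ref", ref_cal - ref_delta),
    ])


def stage3_ratio(profile):
    return float(profile.samples.set_index("stage").loc[3, "ratio"])


def test_pfaffl_reduces_to_two_power_ddct_when_e_is_one():
    ct = two_stage_frame(target_delta=3.0, ref_delta=1.0)
    profile = relative_expression(ct, "tgt", ["ref"], {"tgt": 1.0, "ref": 1.0})
    # 2^ddCt with ddCt = 3 - 1 = 2
    assert stage3_ratio(profile) == pytest.approx(4.0)


def test_efficiency_corrected_ratio_example():
    # E_t = 0.8, target dCt 2; single reference E_r = 1.0, dCt 1 -> 1.8^2/2
    ct = two_stage_frame(target_delta=2.0, ref_delta=1.0)
    profile = relative_expression(ct, "tgt", ["ref"], {"tgt": 0.8, "ref": 1.0})
    assert stage3_ratio(profile) == pytest.approx(1.8 ** 2 / 2.0)


def test_zero_delta_ct_gives_unit_ratio_and_calibrator_normalizes_to_one():
    ct = two_stage_frame(target_delta=0.0, ref_delta=0.0)
    profile = relative_expression(ct, "tgt", ["ref"], {"tgt": 0.9, "ref": 0.7})
    assert stage3_ratio(profile) == pytest.approx(1.0)
    cal = profile.samples.set_index("stage").loc[2, "ratio"]
    assert float(cal) == pytest.approx(1.0)


def test_constant_reference_is_neutral():
    # references whose Ct does not move contribute a unit factor each,
    # so adding another constant reference leaves ratios unchanged
    ct = two_stage_frame(target_delta=1.0, ref_delta=0.0)
    extra = ct_frame([
        ("s2", "A", 2, 1, 1, "ref2", 22.0),
        ("s3", "A", 3, 1, 1, "ref2", 22.0),
    ])
    eff = {"tgt": 1.0, "ref": 1.0, "ref2": 0.8}
    one_ref = relative_expression(ct, "tgt", ["ref"], eff)
    two_refs = relative_expression(
        pd.concat([ct, extra], ignore_index=True), "tgt", ["ref", "ref2"], eff
    )
    assert stage3_ratio(one_ref) == pytest.approx(stage3_ratio(two_refs))
    assert stage3_ratio(one_ref) == pytest.approx(2.0)


def test_relative_expression_input_validation():
    ct = two_stage_frame(1.0, 0.0)
    with pytest.raises(ExpressionError):
        relative_expression(ct, "tgt", ["ref"], {"tgt": 1.5, "ref": 1.0})
    with pytest.raises(ExpressionError):
        relative_expression(ct, "tgt", ["ref"], {"tgt": 1.0, "ref": 1.0},
                            calibrator_stage=5)
    with pytest.raises(ExpressionError):
        relative_expression(ct, "missing", ["ref"], {"missing": 1.0, "ref": 1.0})


def make_profile(stage_ratios, gene="g", campaign=1):
    rows = []
    for stage, ratios in stage_ratios.items():
        for pool, ratio in enumerate(np.atleast_1d(ratios), start=1):
            rows.append({"sample_id": f"s{stage}p{pool}", "stage": stage,
                         "pool": pool, "campaign": campaign, "ratio": float(ratio)})
    return ExpressionProfile(gene=gene, host="A", samples=pd.DataFrame(rows))


@pytest.mark.parametrize(
    "ratios, status, stages",
    [
        ({2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0, 6: 1.0}, "none", ()),
        ({2: 1.0, 3: 1.0, 4: 2.0, 5: 1.0, 6: 1.0}, "over", (4,)),  # inclusive
        ({2: 1.0, 3: 0.5, 4: 1.0, 5: 1.0, 6: 1.0}, "under", (3,)),
        ({2: 1.0, 3: 0.4, 4: 8.0, 5: 1.0, 6: 1.0}, "over", (4,)),  # extreme wins
        ({2: 1.0, 3: 0.1, 4: 2.5, 5: 1.0, 6: 1.0}, "under", (3,)),
        ({2: 9.0, 3: 1.2, 4: 1.4, 5: 1.1, 6: 1.0}, "none", ()),  # stage 2 ignored
    ],
)
def test_classify_de_thresholds_and_precedence(ratios, status, stages):
    call = classify_de(make_profile(ratios), stages_of_interest=(3, 4, 5, 6))
    assert call.status == status
    assert call.supporting_stages == stages


def test_classify_de_rejects_empty_stage_set():
    with pytest.raises(ExpressionError):
        classify_de(make_profile({2: 1.0, 3: 1.0}), stages_of_interest=())


def test_presence_filter_keeps_any_positive_stage():
    presence = pd.DataFrame(
        {3: [0, 0, 1], 4: [0, 0, 0], 5: [0, 1, 0], 6: [1, 0, 0]},
        index=["g_late", "g_mid", "g_early"],
    )
    assert presence_filter(presence, (3, 4, 5, 6)) == ["g_early", "g_late", "g_mid"]
    presence.loc["g_silent"] = [0, 0, 0, 0]
    assert "g_silent" not in presence_filter(presence, (3, 4, 5, 6))
    with pytest.raises(ExpressionError):
        presence_filter(presence[[3, 4]], (3, 4, 5, 6))


def test_consistency_filter_requires_same_direction_replicate():
    calls = [DECall("g_over", "over", (4,)), DECall("g_under", "under", (3,))]
    profiles = {
        # one replicate at 2.4 confirms the over call
        "g_over": make_profile({3: [1.0, 1.1, 1.0], 4: [1.5, 2.4, 1.2]}),
        # all replicates stay above 0.5: the under call is not confirmed
        "g_under": make_profile({3: [0.8, 0.9, 0.7], 4: [1.0, 1.0, 1.1]}),
    }
    assert consistency_filter(calls, profiles) == ["g_over"]
    profiles["g_under"] = make_profile({3: [0.8, 0.4, 0.9]})
    assert consistency_filter(calls, profiles) == ["g_over", "g_under"]
    with pytest.raises(ExpressionError):
        consistency_filter(calls, {"g_over": profiles["g_over"]})
    with pytest.raises(ExpressionError):
        consistency_filter([DECall("g", "none", ())], profiles)


def test_reference_selection_recovers_planted_stable_genes():
    """The six genes tracking the latent template signal are selected; the
    nine with independent expression noise (and the wsp marker) are not."""
    noise = sd.NoiseModel(ct_sd=0.05)
    folds = pd.DataFrame(columns=["gene", "host", "campaign", "stage", "fold"])
    ct = sd.generate_qpcr_dataset(sd.standard_design(), folds, noise, seed=3)
    hk = ct[ct["gene"].isin(sd.HOUSEKEEPING_GENES)]
    wsp = ct[ct["gene"] == sd.WSP]
    assert select_reference_genes(hk, wsp) == sorted(sd.STABLE_HOUSEKEEPING)


def test_reference_selection_edge_cases():
    rows = []
    for s, sid in enumerate(["a", "b", "c"], start=1):
        rows += [(sid, "A", s, 1, 1, "g1", 20.0 + s), (sid, "A", s, 1, 1, "g2", 18.0 + s)]
    ct = ct_frame(rows)
    # identical Ct trajectories -> both perfectly correlated with the index
    assert select_reference_genes(ct) == ["g1", "g2"]
    with pytest.raises(ExpressionError):
        select_reference_genes(ct[ct["gene"] == "g1"])  # single gene
    with pytest.raises(ExpressionError):
        select_reference_genes(ct[ct["stage"] < 3])  # < 3 samples
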