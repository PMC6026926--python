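import pytest

from femscreen import pipeline
from femscreen.synthetic_data import FunnelPreset, NoiseModel

#: scaled-down funnel used by unit and pipeline tests (same structure as the
#: default preset, ~1 s to generate and analyse)
MINI_PRESET = FunnelPreset(
    n_genes=80, n_repeats=10, n_pseudogenes=3, n_short=4, n_split_chunks=2,
    n_core=20, n_identical_to_nonfeminizer=3, n_amplifiable=30, n_expressed=20,
    n_under_s1=3, n_over_s1=6, n_fail_s2=2, n_regulated_both_hosts=5,
    n_ccf_lag1=2, n_ccf_lag0=1, n_in_felement=4, n_identical_in_felement=2,
)


@pytest.fixture(scope="session")
def mini_preset() -> FunnelPreset:
    return MINI_PRESET


@pytest.fixture(scope="session")
def mini_fixture_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("mini_fixture")
    pipeline.make_paper_fixture(outdir, seed=5, preset=MINI_PRESET, force=True)
    return outdir


@pytest.fixture(scope="session")
def full_report(tmp_path_factory):
    """One full default-preset screen shared by the acceptance tests."""
    fixture_dir = tmp_path_factory.mktemp("paper_fixture")
    outdir = tmp_path_factory.mktemp("paper_results")
    pipeline.make_paper_fixture(fixture_dir, seed=42, force=True)
    config = pipeline.RunConfig(
        fixture_dir=str(fixture_dir), outdir=str(outdir), seed=42,
        log_level="WARNING",
    )
    return pipeline.run_screen(config)


@pytest.fixture(scope="session")
def noise_free() -> NoiseModel:
    return NoiseModel(ct_sd=0.0, efficiency_range=(0.9, 0.9), dropout_rate=0.0)
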