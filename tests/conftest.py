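import pytest

from ctdna_tmi import (
    MutationKey,
    MutationRecord,
    SampleProfile,
    SimulationConfig,
    TMIModel,
    simulate_cohort,
)


def make_profile(patient_id="P1", timepoint="BL", records=()):
    """Build a SampleProfile from (chrom, pos, ref, alt, gene, effect,
    synonymous, depth, vaf) tuples."""
    prof = SampleProfile(patient_id, timepoint)
    for chrom, pos, ref, alt, gene, effect, syn, depth, vaf in records:
        prof.add(
            MutationRecord(
                MutationKey(chrom, pos, ref, alt), gene, effect, syn, depth, vaf
            )
        )
    return prof


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort under the default planted effects."""
    return simulate_cohort(SimulationConfig(n_patients=120, seed=11))


@pytest.fixture(scope="session")
def fitted(default_cohort):
    return TMIModel.from_cohort(default_cohort).fit()


@pytest.fixture()
def small_config():
    """A light cohort configuration for fast IO / pipeline tests."""
    return SimulationConfig(
        n_patients=40,
        mean_gs_burden_low=15.0,
        mean_gs_burden_high=45.0,
        n_shared_background=40,
        n_unfavorable=6,
        seed=7,
    )
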