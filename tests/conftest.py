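import pytest

from epimut.simulate import (
    Spike,
    SpikePlan,
    generate_array_design,
    simulate_cohort,
    simulate_hybridizations,
)


@pytest.fixture(scope="session")
def small_design():
    """Five-promoter design, full default geometry."""
    return generate_array_design(n_promoters=5, seed=101)


@pytest.fixture(scope="session")
def null_hybs(small_design):
    return simulate_hybridizations(small_design, noise_sd=0.25, seed=102)


@pytest.fixture(scope="session")
def spiked_setup():
    """Design + hybridizations with one known spiked promoter."""
    design = generate_array_design(n_promoters=30, seed=103)
    row = design.promoters.iloc[0]
    mid = (row["region_start"] + row["region_end"]) // 2
    plan = SpikePlan(
        (Spike(row["promoter_id"], int(mid - 300), int(mid + 300), 1.5, "s0"),)
    )
    hybs = simulate_hybridizations(design, plan, noise_sd=0.2, seed=104)
    return design, plan, hybs


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(n_per_cell=12, seed=105)
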