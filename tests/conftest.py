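import pytest

from thiocomp.simulate import (
    ProphageSpec,
    SimConfig,
    TranslocationSpec,
    simulate_all,
)

# A reduced study used by unit and integration tests: same event menu as the
# default configuration, scaled to a 45 kb genome so one simulation runs in
# well under a second.
SMALL_CONFIG = SimConfig(
    seed=7,
    genome_length=45_000,
    n_orfs=24,
    translocation=TranslocationSpec(region_a=(4_000, 9_000), region_b=(26_000, 31_000)),
    prophage=ProphageSpec(length_bp=3_000, insertion_site=38_000, n_orfs=3),
    n_transposase_copies=4,
    n_foreign_orfs=2,
    coverage_target=4.0,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_all(SMALL_CONFIG)
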