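"""Shared fixtures: a small synthetic panel, diploid individual and read
set, sized so the whole non-benchmark suite stays fast."""

import pytest

from mhcasm.simulate import (ReadSimConfig, generate_guide_panel,
                             simulate_individual, simulate_reads)


@pytest.fixture(scope="session")
def small_panel():
    return generate_guide_panel(2, base_len=40_000, dr_mix=["DR3", "DR4"],
                                repeat_density=0.1, seed=5,
                                c4_mix=[(1, 0, 1), (0, 1, 0)])


@pytest.fixture(scope="session")
def small_individual(small_panel):
    return simulate_individual(small_panel, (small_panel[0].id, small_panel[1].id),
                               divergence=0.005, indel_rate=5e-4, seed=3)


@pytest.fixture(scope="session")
def small_reads(small_individual):
    return simulate_reads(small_individual, ReadSimConfig(depth=30, seed=7))
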