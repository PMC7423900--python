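"""Shared fixtures: calibrated edit-distance policies and a small synthetic
universe reused across test modules (both are expensive enough to build
once per session)."""

from __future__ import annotations

import pytest

from scnaumi import simulate as sim
from scnaumi.assign import calibrate_ed_policy
from scnaumi.guide import build_index


@pytest.fixture(scope="session")
def cell_policy():
    return calibrate_ed_policy(barcode_len=16, target_false_rate=0.05, n_sims=20000, seed=11)


@pytest.fixture(scope="session")
def umi_policy():
    return calibrate_ed_policy(barcode_len=10, target_false_rate=0.02, n_sims=20000, seed=12)


@pytest.fixture(scope="session")
def small_truth():
    return sim.simulate_universe(n_cells=20, n_genes=10, umis_per_gene_per_cell=0.8, seed=101)


@pytest.fixture(scope="session")
def small_guide(small_truth):
    return sim.emit_guide(small_truth, saturation=0.9, seed=102)


@pytest.fixture(scope="session")
def small_index(small_guide):
    return build_index(small_guide)
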