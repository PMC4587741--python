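"""Shared synthetic datasets and small hand-built fixtures.

All fixtures are generated programmatically; the heavier simulated datasets
are session-scoped so the full suite builds each genome once.
"""

from __future__ import annotations

import pytest

from stitchkit.formats import MoleculeMap
from stitchkit.simulate import simulate_dataset
from stitchkit.stitch import AlignmentFilterSet, StitchConfig

# The simulator's confidence proxy is a matched-label count, not the external
# aligner's -log10 p-value, so simulated runs use filter sets scaled to label
# counts (documented in the simulate module).
SIM_FILTER_SETS = (AlignmentFilterSet(6.0, 30.0), AlignmentFilterSet(4.0, 90.0))


@pytest.fixture(scope="session")
def sim_stitch_config() -> StitchConfig:
    return StitchConfig(filter_sets=SIM_FILTER_SETS)


@pytest.fixture(scope="session")
def ds_clean():
    """Noise-free 5 Mb / 40-scaffold / 10-chromosome dataset."""
    return simulate_dataset(seed=17)


@pytest.fixture(scope="session")
def ds_noisy():
    """2 % sizing noise, 10 % label dropout, 1 false label / 100 kb."""
    return simulate_dataset(sizing_sd=0.02, dropout=0.10,
                            false_per_100kb=1.0, seed=23)


@pytest.fixture(scope="session")
def ds_molecules():
    """Smaller dataset carrying BNX molecules with per-scan stretch."""
    return simulate_dataset(
        genome_length=2_000_000, n_scaffolds=16, n_chromosomes=4,
        scan_stretch={("1", 1): 1.02, ("1", 2): 0.99, ("2", 1): 1.0},
        n_molecules_per_scan=60, seed=31)


@pytest.fixture()
def two_molecules() -> list[MoleculeMap]:
    """Hand-written two-molecule BNX fixture (lengths 180 kb and 210 kb,
    5 and 7 labels)."""
    return [
        MoleculeMap(1, 180000.0,
                    [20000.0, 55000.0, 90000.0, 120000.0, 170000.0],
                    scan_id=1, flowcell_id="FC1",
                    extra_rows=["QX11\t0.5\t0.5\t0.5\t0.5\t0.5"]),
        MoleculeMap(2, 210000.0,
                    [10000.0, 42000.0, 77000.0, 110000.0, 150000.0,
                     180000.0, 205000.0],
                    scan_id=2, flowcell_id="FC1"),
    ]
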