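import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rohscan.pedigree import Pedigree
from rohscan.simulate import SimulationConfig, plant_tracts
from rohscan.variants import VariantTable


def small_sim_config(**kw) -> SimulationConfig:
    """Two-scaffold 10 Mb planted-tract config used across tests."""
    defaults = dict(
        scaffold_lengths={"s1": 5_000_000, "s2": 5_000_000},
        groups={"A": 3, "B": 3},
        roh_fraction=0.25,
        seed=11,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_truth(small_config):
    return plant_tracts(small_config)


@pytest.fixture(scope="session")
def full_sib_pedigree() -> Pedigree:
    """Two founders, two full-sib offspring, and their (inbred) child."""
    return Pedigree(pd.DataFrame({
        "id": ["A", "B", "S1", "S2", "C"],
        "sire": ["0", "0", "A", "A", "S1"],
        "dam": ["0", "0", "B", "B", "S2"],
        "sex": ["M", "F", "M", "F", "M"],
        "cohort": ["Founder", "Founder", "F1", "F1", "F2"],
    }))


def filter_fixture_table(n_samples: int = 30):
    """200-site table with hand-counted per-filter failures.

    Composition (counts fixed by construction, independently tallied in
    the expected dict below):
      140 clean passing sites
       15 passing sites with exactly one low-depth genotype (masked, kept)
       10 sites with QUAL 20            -> dropped (quality)
       10 sites with 8/30 missing       -> dropped (missingness)
       10 sites with 5 low-depth + 3 missing (8/30 after masking) -> dropped
       10 sites with a single het carrier (MAF 1/60)              -> dropped
        5 sites with every depth 1      -> dropped (no callable genotype)
    """
    rows_gt, rows_dp, quals = [], [], []

    def site(gt, dp, q):
        rows_gt.append(gt)
        rows_dp.append(dp)
        quals.append(q)

    base_gt = np.zeros(n_samples, dtype=np.int8)
    base_gt[:10] = 1  # 10 het carriers: alt freq 10/60, passes MAF
    base_dp = np.full(n_samples, 7, dtype=np.int32)

    for _ in range(140):
        site(base_gt.copy(), base_dp.copy(), 50.0)
    for _ in range(15):
        dp = base_dp.copy()
        dp[20] = 2  # one genotype masked by depth, site retained
        site(base_gt.copy(), dp, 50.0)
    for _ in range(10):
        site(base_gt.copy(), base_dp.copy(), 20.0)
    for _ in range(10):
        gt = base_gt.copy()
        gt[-8:] = -1
        site(gt, base_dp.copy(), 50.0)
    for _ in range(10):
        gt = base_gt.copy()
        gt[-3:] = -1
        dp = base_dp.copy()
        dp[10:15] = 2
        site(gt, dp, 50.0)
    for _ in range(10):
        gt = np.zeros(n_samples, dtype=np.int8)
        gt[0] = 1
        site(gt, base_dp.copy(), 50.0)
    for _ in range(5):
        site(base_gt.copy(), np.ones(n_samples, dtype=np.int32), 50.0)

    n = len(quals)
    table = VariantTable(
        samples=[f"S{i:02d}" for i in range(1, n_samples + 1)],
        scaffold=np.array(["s1"] * n, dtype=object),
        position=np.arange(1, n + 1, dtype=np.int64) * 100,
        qual=np.array(quals),
        genotypes=np.stack(rows_gt),
        depth=np.stack(rows_dp),
    )
    expected = {
        "n_input": 200,
        "n_output": 155,
        "n_dropped_qual": 10,
        "n_dropped_missing": 20,
        "n_dropped_maf": 10,
        "n_dropped_all_missing": 5,
        "n_genotypes_depth_masked": 10 * 5 + 15 * 1 + 5 * n_samples,
    }
    return table, expected


@pytest.fixture()
def filter_fixture():
    return filter_fixture_table()
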