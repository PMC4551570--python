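import numpy as np
import pandas as pd
import pytest

from methodcompare import MeasurementTable, SimulationConfig, igrt_fixture, simulate


@pytest.fixture(scope="session")
def balanced_table():
    """4 subjects, 3 complete paired sessions each, fixed values."""
    rng = np.random.default_rng(20240917)
    rows = []
    for i in range(4):
        for t in range(1, 4):
            rows.append((f"A{i}", 1, t, float(rng.normal(0.1, 0.5))))
            rows.append((f"A{i}", 2, t, float(rng.normal(0.0, 0.3))))
    return MeasurementTable(
        pd.DataFrame(rows, columns=["subject", "method", "replicate", "value"])
    )


@pytest.fixture(scope="session")
def sim_table():
    """Medium synthetic dataset with unequal variabilities."""
    cfg = SimulationConfig(
        n_subjects=80,
        replicates=3,
        mu=(0.05, 0.0),
        D_true=np.array([[0.04, 0.02], [0.02, 0.07]]),
        Sigma_true=np.array([[0.34, 0.06], [0.06, 0.10]]),
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def demo_table():
    """Deterministic 28-subject IGRT-style demo dataset."""
    return igrt_fixture(seed=7)


def random_small_table(rng, max_subjects=4, max_sessions=2, missing=0.2):
    """Small random table (possibly with missing cells) for oracles."""
    while True:
        n = int(rng.integers(2, max_subjects + 1))
        rows = []
        for i in range(n):
            p = int(rng.integers(1, max_sessions + 1))
            for t in range(1, p + 1):
                for m in (1, 2):
                    if rng.random() >= missing:
                        rows.append((f"s{i}", m, t, float(rng.normal(0, 1))))
        df = pd.DataFrame(rows, columns=["subject", "method", "replicate", "value"])
        try:
            return MeasurementTable(df)
        except Exception:
            continue


def random_spd(rng, scale=1.0):
    """Random symmetric positive-definite 2x2 matrix."""
    a = rng.normal(0, scale, size=(2, 2))
    return a @ a.T + 0.1 * scale**2 * np.eye(2)
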