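import numpy as np
import pandas as pd
import pytest

from hdebm import BiomarkerMatrix, CohortConfig, EventLikelihoodTable, generate_cohort


def random_table(z: int, n: int, rng: np.random.Generator,
                 scale: float = 1.0) -> EventLikelihoodTable:
    """A random, dimensionally valid likelihood table (no planted structure)."""
    return EventLikelihoodTable(
        scale * rng.standard_normal((n, z)),
        scale * rng.standard_normal((n, z)),
        [f"bm{i}" for i in range(z)],
        [f"s{j}" for j in range(n)],
    )


def planted_table(z: int, n_per_stage: int, rng: np.random.Generator,
                  shift: float = 4.0, sequence=None):
    """Likelihood table from subjects planted uniformly across stages with a
    known event ordering; returns (table, sequence, true_stages)."""
    if sequence is None:
        sequence = rng.permutation(z)
    sequence = np.asarray(sequence)
    stages = np.repeat(np.arange(z + 1), n_per_stage)
    rank = np.empty(z, dtype=int)
    rank[sequence] = np.arange(1, z + 1)
    abnormal = rank[None, :] <= stages[:, None]
    x = np.where(abnormal, -shift, 0.0) + rng.standard_normal((len(stages), z))
    lpe = -0.5 * (x + shift) ** 2 - 0.5 * np.log(2 * np.pi)
    lpn = -0.5 * x**2 - 0.5 * np.log(2 * np.pi)
    table = EventLikelihoodTable(lpe, lpn, [f"bm{i}" for i in range(z)],
                                 [f"s{j}" for j in range(len(stages))])
    return table, sequence, stages


def matrix_from_groups(hc: np.ndarray, hd: np.ndarray, names=None) -> BiomarkerMatrix:
    """Stack HC and HD value blocks into a labelled BiomarkerMatrix."""
    values = np.vstack([hc, hd])
    names = names or [f"bm{i}" for i in range(values.shape[1])]
    idx = [f"s{j}" for j in range(len(values))]
    diag = ["HC"] * len(hc) + ["HD"] * len(hd)
    return BiomarkerMatrix(pd.DataFrame(values, index=idx, columns=names),
                           pd.Series(diag, index=idx))


def positions(sequence: np.ndarray) -> np.ndarray:
    """Map biomarker index -> sequence position (for Kendall tau)."""
    sequence = np.asarray(sequence)
    pos = np.empty(len(sequence))
    pos[sequence] = np.arange(len(sequence))
    return pos


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 6-event cohort used by several pipeline-level tests."""
    config = CohortConfig(n_control=40, n_premanifest=40, n_manifest=40,
                          n_biomarkers=6, seed=11)
    return generate_cohort(config)
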