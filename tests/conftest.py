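import numpy as np
import pandas as pd
import pytest

from coagree import CohortDataset, SimulationConfig, simulate_cohort


def make_dataset(frame_rows, **kwargs) -> CohortDataset:
    """Build a CohortDataset from (patient, time, phase, ref, test) tuples."""
    frame = pd.DataFrame(
        frame_rows, columns=["patient_id", "time_index", "phase", "ci_ref", "ci_test"]
    )
    return CohortDataset(frame=frame, **kwargs)


def dataset_from_diffs(diffs_by_patient, base=2.0) -> CohortDataset:
    """Dataset whose test−ref differences equal the given per-patient lists.

    ci_ref is held at ``base`` so the differences are exactly as specified.
    """
    rows = []
    for pid, diffs in diffs_by_patient.items():
        for t, d in enumerate(diffs):
            rows.append((pid, t, "other", base, base + d))
    return make_dataset(rows)


@pytest.fixture
def tiny_dataset() -> CohortDataset:
    return make_dataset(
        [
            ("A", 0, "baseline", 2.0, 2.5),
            ("A", 1, "other", 2.4, 2.2),
            ("B", 0, "baseline", 3.0, 2.8),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort() -> CohortDataset:
    """One 20-patient × 29-measurement synthetic cohort at study defaults."""
    return simulate_cohort(SimulationConfig(seed=12345))


def random_clustered_dataset(rng: np.random.Generator) -> CohortDataset:
    """Small random unbalanced dataset for oracle comparisons."""
    k = rng.integers(2, 8)
    rows = []
    for i in range(k):
        m = rng.integers(1, 9)
        for t in range(m):
            ref = rng.uniform(1.0, 4.0)
            rows.append((f"p{i}", t, "other", ref, ref + rng.normal(0, 0.7)))
    frame = pd.DataFrame(
        rows, columns=["patient_id", "time_index", "phase", "ci_ref", "ci_test"]
    )
    frame["ci_test"] = frame["ci_test"].clip(lower=0.1)
    return CohortDataset(frame=frame)
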