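import numpy as np
import pandas as pd
import pytest

from lumcna import synth
from lumcna.io import DEFAULT_SCHEMA, ClinicalTable


def small_config(seed: int = 0, n: int = 200, genes: int = 300) -> synth.CohortConfig:
    """A scaled-down cohort config for fast simulation-based tests."""
    return synth.CohortConfig(n_patients=n, n_genes=genes, seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    """One fixed small synthetic cohort shared across read-only tests."""
    cfg = small_config(seed=11)
    cna, clinical, labels = synth.generate_cohort(cfg)
    return cfg, cna, clinical, labels


def make_clinical(times, events, extra=None, seed=0, outcome_copy=True) -> ClinicalTable:
    """Minimal valid clinical table around given survival data."""
    rng = np.random.default_rng(seed)
    n = len(times)
    frame = pd.DataFrame(
        {
            "os_months": np.asarray(times, dtype=float),
            "os_event": np.asarray(events, dtype=int),
            "dss_months": np.asarray(times, dtype=float),
            "dss_event": np.asarray(events, dtype=int),
            "pam50": pd.Categorical(
                rng.choice(["lumA", "lumB"], n), categories=["lumA", "lumB"], ordered=True
            ),
            "grade": pd.Categorical(
                rng.choice(["1", "2", "3"], n), categories=["1", "2", "3"], ordered=True
            ),
            "tumour_size": rng.uniform(5, 60, n).round(1),
            "positive_lymph_nodes": rng.integers(0, 8, n).astype(float),
            "age_at_diagnosis": rng.uniform(30, 85, n).round(1),
            "her2_status": pd.Categorical(
                rng.choice(["negative", "positive"], n),
                categories=["negative", "positive"],
                ordered=True,
            ),
        },
        index=pd.Index([f"P{i:05d}" for i in range(1, n + 1)], name="patient_id"),
    )
    if extra:
        for name, values in extra.items():
            frame[name] = values
    return ClinicalTable(frame, schema=DEFAULT_SCHEMA)
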