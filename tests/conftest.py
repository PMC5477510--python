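import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_paired_counts(counts_by_subject, arm="drug", response="responder"):
    """Build a CountMatrix from {subject: (t0_column, t8_column)} vectors."""
    from mirresponse.smallrna import CountMatrix

    cols, meta_rows = {}, []
    n = None
    for subject, (t0, t8) in counts_by_subject.items():
        for tp, vec in (("T0", t0), ("T8", t8)):
            name = f"{subject}_{tp}"
            cols[name] = np.asarray(vec, dtype=np.int64)
            n = len(cols[name])
            meta_rows.append(
                {
                    "sample": name,
                    "subject": subject,
                    "timepoint": tp,
                    "arm": arm,
                    "response": response,
                }
            )
    counts = pd.DataFrame(cols, index=[f"m{i}" for i in range(n)])
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(counts, meta)


@pytest.fixture
def tiny_study():
    """Small but fully powered synthetic study reused across tests."""
    from mirresponse.synthetic_data import SimulationConfig, simulate_study

    cfg = SimulationConfig(
        n_subjects_per_arm=30,
        n_mirnas=60,
        n_marker_mirnas=4,
        n_genes=300,
        n_target_genes_per_marker=12,
        library_size_mean=200_000,
        seed=42,
    )
    return simulate_study(cfg)
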