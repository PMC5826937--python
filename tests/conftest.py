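import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import stabnet as sn
from stabnet.containers import FeatureTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_experiment():
    """A compact but fully structured synthetic experiment."""
    cfg = sn.SyntheticConfig(n_features=120, n_increasing=10, n_decreasing=10,
                             n_erratic=10, seed=11)
    table, truth = sn.generate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_preprocessed(small_experiment):
    """Filtered + preprocessed study matrix of the small experiment."""
    _, table, truth = small_experiment
    filtered, report = sn.apply_filters(table)
    pm = sn.preprocess(filtered.study_matrix())
    return filtered, pm, truth


def make_table(study=None, qc=None, qc_dilution=None, dilution_factors=None,
               feature_ids=None, days=None, replicates=None):
    """Hand-build a FeatureTable from per-role intensity arrays."""
    blocks, rows = [], []
    p = None
    for arr in (study, qc, qc_dilution):
        if arr is not None:
            p = np.atleast_2d(np.asarray(arr, dtype=float)).shape[1]
            break
    if feature_ids is None:
        feature_ids = [f"{i / 10 + 0.5:.2f}_{100.0 + i:.4f}" for i in range(p)]
    if study is not None:
        study = np.atleast_2d(np.asarray(study, dtype=float))
        n = study.shape[0]
        days = days if days is not None else [0] * n
        replicates = replicates if replicates is not None else [f"r{i}" for i in range(n)]
        for i in range(n):
            rows.append((f"S{i}", "study", days[i], replicates[i], np.nan, "pos"))
        blocks.append(study)
    if qc is not None:
        qc = np.atleast_2d(np.asarray(qc, dtype=float))
        for i in range(qc.shape[0]):
            rows.append((f"QC{i}", "qc", np.nan, np.nan, np.nan, "pos"))
        blocks.append(qc)
    if qc_dilution is not None:
        qc_dilution = np.atleast_2d(np.asarray(qc_dilution, dtype=float))
        facs = dilution_factors or [1.0, 0.2, 0.1, 0.02][: qc_dilution.shape[0]]
        for i in range(qc_dilution.shape[0]):
            rows.append((f"D{i}", "qc_dilution", np.nan, np.nan, facs[i], "pos"))
        blocks.append(qc_dilution)
    intens = np.vstack(blocks)
    samples = pd.DataFrame(
        rows, columns=["sample_id", "role", "storage_day", "replicate",
                       "dilution_factor", "mode"]).set_index("sample_id")
    features = pd.DataFrame(
        {"rt_min": np.arange(p, dtype=float), "mz": 100.0 + np.arange(p),
         "mode": "pos"}, index=pd.Index(feature_ids))
    return FeatureTable(
        intensities=pd.DataFrame(intens, index=samples.index, columns=feature_ids),
        samples=samples, features=features)
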