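import numpy as np
import pandas as pd
import pytest

from metaboline.qc import average_biological_replicates, zscore_features
from metaboline.synthetic import StudyConfig, generate_pathways, generate_study
from metaboline.types import FeatureMatrix, Stage


def quiet_config(**overrides):
    """Study config with every artifact and noise source switched off."""
    base = dict(
        seed=0,
        noise_sd_tech=0.0,
        noise_sd_bio=0.0,
        between_line_sd=0.0,
        tissue_sd=0.0,
        base_log_sd=0.0,
        global_bio_sd=0.0,
        global_tech_sd=0.0,
        drift_amplitude=0.0,
        confluency_effect=0.0,
        batch_frac=0.0,
        batch_effect_sd=0.0,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def default_study():
    return generate_study(StudyConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    cfg = StudyConfig(seed=11, n_cell_lines=10, n_tissues=2, n_features=60)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def averaged_z(default_study):
    matrix, meta, _ = default_study
    avg = average_biological_replicates(matrix, meta)
    return zscore_features(avg.with_data(np.log(avg.data), Stage.cellline_avg))


@pytest.fixture(scope="session")
def pathways(default_study):
    matrix, _, _ = default_study
    return generate_pathways(12, (5, 15), matrix.feature_ids, seed=2)


def make_matrix(values, sample_ids=None, feature_ids=None, stage=Stage.raw):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(pd.DataFrame(values, index=sample_ids, columns=feature_ids), stage)


def make_meta(n, cell_lines, bio_reps=None, tech_reps=None, tissues=None,
              injection=None, confluency=None, batch=None, plate=None):
    return pd.DataFrame(
        {
            "cell_line": cell_lines,
            "tissue": tissues or ["T1"] * n,
            "bio_rep": bio_reps or [1] * n,
            "tech_rep": tech_reps or [1] * n,
            "injection_index": injection or list(range(1, n + 1)),
            "confluency": confluency or [0.5] * n,
            "batch": batch or ["B1"] * n,
            "plate": plate or ["P1"] * n,
            "doubling_time": [np.nan] * n,
        },
        index=[f"s{i}" for i in range(n)],
    )
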