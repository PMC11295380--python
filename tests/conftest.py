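import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hccsubtypes import SynthConfig, generate_cohort, normalize_log1p_cp10k, qc_filter
from hccsubtypes.preprocess import PreprocessConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Desk-scale cohort: 4 patients x 2 samples x 150 cells, 400 genes."""
    return SynthConfig(n_patients=4, samples_per_patient=2, cells_per_sample=150,
                       n_genes=400, program_log_fc=2.5, seed=7)


@pytest.fixture(scope="session")
def cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def qc_cfg() -> PreprocessConfig:
    """QC thresholds rescaled to the 400-gene synthetic panel."""
    return PreprocessConfig(min_features=100, min_tumor_cells_per_sample=20, seed=7)


@pytest.fixture(scope="session")
def normed_expr(cohort, qc_cfg):
    """Log-normalized expression frame of the QC-filtered small cohort."""
    adata, truth = cohort
    filtered, _ = qc_filter(adata, qc_cfg)
    normed = normalize_log1p_cp10k(filtered)
    expr = pd.DataFrame(np.asarray(normed.X.todense()),
                        index=normed.obs_names, columns=normed.var_names)
    return expr, filtered.obs, truth
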