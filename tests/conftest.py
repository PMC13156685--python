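import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import breathshift as bs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort_pair():
    """A small but complete two-cohort dataset with ground truth."""
    cfg = bs.StudyDesignConfig(
        n_subjects_per_cohort=(10, 10),
        n_features=300,
        frac_affected=0.1,
        noise_sd_log10=0.15,
        censor_quantile=0.05,
        seed=101,
    )
    return bs.generate_cohort_pair(cfg)


@pytest.fixture(scope="session")
def imputed_pair(small_cohort_pair):
    ta, tb, truth = small_cohort_pair
    out = []
    for tab in (ta, tb):
        out.append(bs.impute_ros(bs.filter_sparse_features(tab)))
    return out[0], out[1], truth


@pytest.fixture(scope="session")
def stats_pair(imputed_pair):
    ta, tb, truth = imputed_pair
    sa = bs.classify_volcano(bs.paired_differential(bs.aggregate_auc(ta)))
    sb = bs.classify_volcano(bs.paired_differential(bs.aggregate_auc(tb)))
    return sa, sb, truth


@pytest.fixture(scope="session")
def toy_library():
    return bs.generate_compound_library(n_compounds=40, n_pathways=8, seed=7)


def combined_table(ta: bs.FeatureTable, tb: bs.FeatureTable) -> bs.FeatureTable:
    return bs.FeatureTable(
        pd.concat([ta.samples, tb.samples]),
        pd.concat([ta.intensities, tb.intensities]),
    )


@pytest.fixture(scope="session")
def strong_effect_table():
    """Two cohorts with a strong, low-noise post-intervention shift, combined
    into one classifier-ready table (no censoring)."""
    cfg = bs.StudyDesignConfig(
        n_subjects_per_cohort=(19, 21),
        n_features=200,
        frac_affected=0.3,
        effect_log2fc_range=(2.0, 2.5),
        noise_sd_log10=0.1,
        censor_quantile=0.0,
        seed=202,
    )
    ta, tb, _ = bs.generate_cohort_pair(cfg)
    return combined_table(ta, tb)
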