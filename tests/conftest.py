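import numpy as np
import pytest

from aprl.lesion_labelling import label_lesions
from aprl.phantom import PhantomSpec, generate_case, generate_cohort
from aprl.pipeline import RunConfig, cohort_feature_table
from aprl.radiomics import extract_feature_table
from aprl.volume_io import Grid


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A desk-scale phantom: 12 lesions on a 64^3 grid."""
    return PhantomSpec(grid=Grid((64, 64, 64), 0.65), n_lesions=12,
                       rim_fraction=0.25, seed=42)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_case(small_spec, subject_id="sub-042")


@pytest.fixture(scope="session")
def small_labelled(small_case):
    labels, records = label_lesions(
        small_case.prob_map, small_case.gold_mask, small_case.csf_mask,
        small_case.gm_mask, small_case.prl_annotation, subject_id="sub-042",
    )
    return labels, records


@pytest.fixture(scope="session")
def small_features(small_case, small_labelled):
    labels, records = small_labelled
    return extract_feature_table(small_case.phase, labels, records, include_size=True)


@pytest.fixture(scope="session")
def toy_cohort_config() -> RunConfig:
    """10 subjects x ~30 lesions on 64^3 grids: big enough to train on,
    small enough for the suite."""
    return RunConfig(
        seed=11,
        output_dir="scratch/unused",
        phantom={"n_subjects": 10, "n_lesions": 30, "grid_shape": [64, 64, 64]},
        n_train_subjects=8,
        min_lesions=40,
        n_trees=80,
        max_features_grid=("sqrt",),
    )


@pytest.fixture(scope="session")
def toy_cohort_table(toy_cohort_config):
    table, summary, _ = cohort_feature_table(toy_cohort_config)
    return table, summary


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
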