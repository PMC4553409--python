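import numpy as np
import pandas as pd
import pytest

from lateralize import (BoldImage, CohortSpec, FeatureTable, demo_config,
                        make_atlas, simulate_cohort)


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas((12, 12, 8), 12)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 4-subject cohort at demo scale (no planted effects)."""
    spec = CohortSpec(n_left=2, n_right=2, seed=11)
    subjects, parc = simulate_cohort(spec)
    return spec, subjects, parc


@pytest.fixture(scope="session")
def effect_cohort():
    """The demo 7L/5R cohort with the strong planted effects."""
    cfg = demo_config(seed=42, effects=True)
    subjects, parc = simulate_cohort(cfg.cohort)
    return cfg, subjects, parc


def random_bold(rng, grid=(6, 6, 6), T=64, tr=2.5, mask=None):
    data = rng.standard_normal(grid + (T,))
    return BoldImage(data, tr=tr, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_feature_table(rng, n_subjects=12, n_per_subcat=6, informative=None):
    """Small random feature table; `informative` maps feature names to the
    between-group mean shift added to the left group."""
    from lateralize.features import SUBCATEGORIES

    labels = pd.Series(["L"] * (n_subjects // 2 + n_subjects % 2)
                       + ["R"] * (n_subjects // 2),
                       index=[f"s{i}" for i in range(n_subjects)])
    names, tags = [], []
    for sc in SUBCATEGORIES:
        for j in range(n_per_subcat):
            names.append(f"{sc.lower()}_f{j}")
            tags.append(sc)
    values = pd.DataFrame(rng.standard_normal((n_subjects, len(names))),
                          index=labels.index, columns=names)
    for name, shift in (informative or {}).items():
        values.loc[labels == "L", name] += shift
    return FeatureTable(values=values,
                        subcategory=pd.Series(tags, index=names),
                        labels=labels)
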