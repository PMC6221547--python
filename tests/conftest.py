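import warnings

import numpy as np
import pandas as pd
import pytest

import npemix
from npemix import preprocess as pp


@pytest.fixture(scope="session")
def cas_cohort():
    """Default synthetic cohort at the study-like conditions, seed 1."""
    return npemix.generate(npemix.cas_like_default())


@pytest.fixture(scope="session")
def cas_preprocessed(cas_cohort):
    """Scaled complete-case / low-missingness split of the default cohort."""
    roster = cas_cohort.table.clustering_roster()
    t = pp.apply_assay_transforms(roster)
    t = pp.filter_features(t, 0.20)
    t = pp.filter_subjects(t, 0.30)
    complete, low = pp.split_complete_low_missing(t)
    stats = pp.compute_reference_stats(complete.data)
    train = pp.scale(complete.data, stats)
    test = pp.scale(low.data, stats)
    return train, test, stats


@pytest.fixture(scope="session")
def cas_model(cas_preprocessed):
    """npEM model (L=3, seed 1) fitted on the complete-case subset."""
    train, _test, stats = cas_preprocessed
    return npemix.fit(train, npemix.NpemConfig(n_clusters=3, seed=1),
                      reference_stats=stats)


@pytest.fixture(scope="session")
def separated_3cluster():
    """Small, strongly separated 3-cluster dataset for stability tests."""
    rng = np.random.default_rng(42)
    sizes = (24, 20, 12)
    # every pair of clusters differs in at least two coordinates, so no
    # single product-density component can absorb two clusters and no
    # single left-out feature removes the separation
    centers = np.array([[-6.0, -6.0, 0.0], [6.0, 6.0, 0.0], [0.0, 0.0, 9.0]])
    rows, labels = [], []
    for k, (nk, c) in enumerate(zip(sizes, centers)):
        rows.append(rng.normal(c, 0.2, size=(nk, 3)))
        labels += [k + 1] * nk
    X = np.vstack(rows)
    idx = [f"s{i}" for i in range(X.shape[0])]
    df = pd.DataFrame(X, columns=["a", "b", "c"], index=idx)
    return df, pd.Series(labels, index=idx)


@pytest.fixture()
def toy_table():
    """Tiny raw cohort table with hand-countable missingness."""
    df = pd.DataFrame(
        {
            "ige": [0.02, 0.5, np.nan, 2.0, 0.03],
            "lri": [1.0, 0.0, 2.0, np.nan, 3.0],
            "sex": [0.0, 1.0, 1.0, 0.0, 1.0],
            "sparse": [np.nan, np.nan, np.nan, 1.0, 2.0],
        },
        index=[f"s{i}" for i in range(5)],
    )
    meta = {
        "ige": pp.FeatureSpec("ige", "antibody", log_transform=True, lod=0.03),
        "lri": pp.FeatureSpec("lri", "infection"),
        "sex": pp.FeatureSpec("sex", "demographic", is_binary=True),
        "sparse": pp.FeatureSpec("sparse", "clinical"),
    }
    return pp.CohortTable(df, meta)


def fit_quiet(data, config, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return npemix.fit(data, config, **kw)
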