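import pytest

from tfpartner import (
    SyntheticConfig,
    featurize_proteins,
    generate_dataset,
    parse_aaindex,
    train_dual_model,
    well_separated_config,
)
from tfpartner.models import Hyperparameters

AAINDEX_FIXTURE = """\
H TEST000001
D position index: value equals canonical residue position
R PMID:0000000
A Nobody, N.
T A synthetic fixture entry
J None (2013)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.      2.      3.      4.      5.      6.      7.      8.      9.     10.
   11.     12.     13.     14.     15.     16.     17.     18.     19.     20.
//
H TEST000002
D fixture entry with one missing value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.5     1.5    -2.      3.25    0.      1.      2.     -1.      4.      2.5
   NA      12.      0.1     0.2     0.3     0.4     0.5     0.6     0.7     0.8
//
H TEST000003
D constant fixture entry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    2.      2.      2.      2.      2.      2.      2.      2.      2.      2.
    2.      2.      2.      2.      2.      2.      2.      2.      2.      2.
//
"""


@pytest.fixture(scope="session")
def aaindex_text():
    return AAINDEX_FIXTURE


@pytest.fixture(scope="session")
def parsed_indices():
    return parse_aaindex(AAINDEX_FIXTURE)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick, moderately separated dataset for model-level tests."""
    cfg = SyntheticConfig(
        n_tf_tcof=30, n_tf_tf=30, n_tf_other=30,
        length_range=(40, 80), n_indices=10, seed=11,
    )
    ds = generate_dataset(cfg)
    features = featurize_proteins(ds.records, ds.index_set)
    return ds, features


@pytest.fixture(scope="session")
def small_models(small_dataset):
    ds, features = small_dataset
    hp = Hyperparameters(n_trees=25)
    m1 = train_dual_model(ds.pairs, features, "MODEL1", hp)
    m2 = train_dual_model(ds.pairs, features, "MODEL2", hp)
    return m1, m2


@pytest.fixture(scope="session")
def preset_dataset():
    """The well-separated reference configuration (full size)."""
    ds = generate_dataset(well_separated_config())
    features = featurize_proteins(ds.records, ds.index_set)
    return ds, features
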