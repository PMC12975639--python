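import pytest

from murzyme.fixtures import FixtureSpec, default_corpus_spec, gen_feature_table, gen_pdb_corpus
from murzyme.trendclass import default_trend_table


@pytest.fixture(scope="session")
def trend_table():
    return default_trend_table()


@pytest.fixture(scope="session")
def clean_table():
    """Default 39-row (22 murzyme / 17 classical) trend-conformant table."""
    return gen_feature_table(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def holdout_table():
    """Disjoint-seed holdout cohort: 12 murzymes, 5 classical."""
    return gen_feature_table(FixtureSpec(n_murzyme=12, n_classical=5, seed=90042))


@pytest.fixture(scope="session")
def default_corpus():
    """Default synthetic PDB corpus: 200 records, 56/144, overlap 0.3."""
    return gen_pdb_corpus(default_corpus_spec(seed=42))


@pytest.fixture(scope="session")
def separable_corpus():
    """Overlap-0 corpus: class vocabularies fully disjoint."""
    return gen_pdb_corpus(default_corpus_spec(seed=7, overlap=0.0, n_murzyme=40, n_classical=60))
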