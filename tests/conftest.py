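import numpy as np
import pytest

import emrsql as E


@pytest.fixture(scope="session")
def schema():
    return E.bundled_schema()


@pytest.fixture(scope="session")
def corpus300(schema, tmp_path_factory):
    """A small generated corpus plus its fixture database."""
    records = E.sample_records(schema, 60, seed=5)
    db_path = tmp_path_factory.mktemp("fixtures") / "corpus300.db"
    cfg = E.GenConfig(n_pairs=300, n_patients=60, seed=5, db_path=str(db_path))
    examples, db = E.generate_pairs(schema, records, cfg)
    return examples, db


@pytest.fixture(scope="session")
def tiny_params(schema, corpus300):
    """Untrained model parameters over the corpus vocabulary."""
    examples, _ = corpus300
    vocab = E.Vocab.build(
        [list(e.marked_question.source_tokens) for e in examples], schema
    )
    return E.ModelParams.init(E.ModelConfig(), vocab, schema, seed=0)


@pytest.fixture(scope="session")
def case_db(tmp_path_factory):
    from emrsql.casestudy import case_study_fixture

    path = tmp_path_factory.mktemp("case") / "case.db"
    return case_study_fixture(str(path))
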