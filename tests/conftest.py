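import numpy as np
import pytest

from cprrhythm import evaluation, synthetic
from cprrhythm.classifier import TrainConfig

#: corpus size for the end-to-end study: 72 records of 27 s = 216 9-s segments,
#: balanced over VF / ORG / ASY, artifact at 0 dB in-band SNR
CORPUS_N = 72
CORPUS_SEED = 20240521
CORPUS_SNR_DB = 0.0


@pytest.fixture(scope="session")
def corpus_records():
    return synthetic.gen_corpus(CORPUS_N, snr_db=CORPUS_SNR_DB, seed=CORPUS_SEED, duration=27.0)


@pytest.fixture(scope="session")
def corpus_tables(corpus_records):
    """Feature tables for the full corpus, split by record into halves."""
    table = evaluation.build_feature_table(corpus_records)
    rids = table.record_id.unique()
    train = table[table.record_id.isin(set(rids[::2]))].reset_index(drop=True)
    test = table[table.record_id.isin(set(rids[1::2]))].reset_index(drop=True)
    return train, test


@pytest.fixture(scope="session")
def trained_saa(corpus_tables):
    train, _ = corpus_tables
    saa, report = evaluation.train_shock_advice(train, TrainConfig(seed=0))
    return saa, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
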