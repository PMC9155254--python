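import pytest

from simpedit import fixtures as fx
from simpedit import resources as res
from simpedit.core_text import tokenize


@pytest.fixture(scope="session")
def synth_config():
    return fx.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def resource_dir(tmp_path_factory, synth_config):
    out = tmp_path_factory.mktemp("resources")
    fx.make_resources(synth_config, out)
    return out


@pytest.fixture(scope="session")
def freq_lex(resource_dir):
    return res.read_frequency_list(resource_dir / "frequencies.tsv")


@pytest.fixture(scope="session")
def emb_table(resource_dir):
    return res.read_embeddings(resource_dir / "embeddings.txt")


@pytest.fixture(scope="session")
def subs_lex(resource_dir):
    return res.read_substitution_lexicon(resource_dir / "substitutions.tsv")


@pytest.fixture(scope="session")
def rule_catalog(resource_dir):
    return res.read_rule_catalog(resource_dir / "rules.tsv")


@pytest.fixture(scope="session")
def toy_original_doc():
    return tokenize(fx.TOY_ORIGINAL_TEXT)


@pytest.fixture(scope="session")
def toy_simplified_doc():
    return tokenize(fx.TOY_SIMPLIFIED_TEXT)
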