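import pytest
from hypothesis import HealthCheck, settings

from genenorm import (
    GeneratorConfig,
    SynonymLexicon,
    default_stops,
    generate_corpus,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def stops():
    return default_stops()


@pytest.fixture(scope="session")
def toy_lexicon():
    lex = SynonymLexicon()
    lex.add("G1", ["NF kappa B", "nuclear factor kappa B"])
    lex.add("G2", ["LEF"])
    lex.add("G3", ["TCF"])
    lex.add("G4", ["PRNP gene", "PRNP"])
    lex.add("G5", ["ly9, mouse, homolog of"])
    return lex


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero-ambiguity, zero-noise corpus: the full pipeline should be exact."""
    return generate_corpus(
        GeneratorConfig(ambiguity_fraction=0.0, variant_noise=frozenset(), seed=42)
    )


@pytest.fixture(scope="session")
def noisy_bundle():
    """All noise kinds on, half the synonyms shared between genes."""
    return generate_corpus(
        GeneratorConfig(
            ambiguity_fraction=0.5,
            seed=7,
            variant_noise=frozenset(
                {"hyphenation", "case_change", "word_order", "stop_insertion"}
            ),
        )
    )


@pytest.fixture(scope="session")
def high_signal_ambiguous_bundle():
    """One mention per abstract so each context belongs to a single gene;
    half the synonyms ambiguous -> >= 100 ambiguous disambiguation cases."""
    return generate_corpus(
        GeneratorConfig(
            ambiguity_fraction=0.5,
            mentions_per_doc=(1, 1),
            n_docs=250,
            family_name_fraction=0.0,
            seed=7,
        )
    )
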