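import socket

import pytest

from fairbadge.synthetic_fixtures import (MetadataProfile,
                                          default_corpus_profiles,
                                          write_corpus)


@pytest.fixture(autouse=True)
def no_network(monkeypatch):
    """The whole suite runs hermetically: any socket open is a failure."""
    def guard(*args, **kwargs):
        raise RuntimeError("network access is disabled in the test suite")
    monkeypatch.setattr(socket, "socket", guard)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 24-article fixture corpus with metadata, shared across tests."""
    root = tmp_path_factory.mktemp("corpus")
    profiles = default_corpus_profiles(seed=11, n=24)
    metadata = MetadataProfile(seed=11, n_studies=6, n_attributes=30,
                               n_full=4, n_rare=18)
    truth = write_corpus(root, profiles, metadata)
    return root, truth
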