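import pytest

from splicecode import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_records():
    """60 balanced events with a strong planted motif (fast CV fixture)."""
    return generate_dataset(SyntheticConfig(n_per_class=30, signal_strength=1.0,
                                            seed=42))


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory, tiny_records):
    from splicecode import write_fixture

    out = tmp_path_factory.mktemp("tiny_dataset")
    write_fixture(tiny_records, out)
    return out
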