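import pytest

from ureidoscan.simulate import SynthConfig, generate_benchmark


@pytest.fixture(scope="session")
def benchmark17():
    """The default labeled synthetic benchmark used across stages."""
    config = SynthConfig(
        n_urea=5, n_canonical=20, n_decoy_only=5, identity=0.7, seed=17
    )
    records, truth, labels = generate_benchmark(config)
    return config, records, truth, labels
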