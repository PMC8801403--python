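from pathlib import Path

import pytest

from geis import synthetic_data as sd

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_gff3_path() -> Path:
    return DATA_DIR / "toy.gff3"


@pytest.fixture(scope="session")
def toy_models(toy_gff3_path):
    from geis.annotation import parse_gff3

    return parse_gff3(toy_gff3_path)


@pytest.fixture(scope="session")
def small_scenario():
    """A seeded seven-variant scenario shared by alignment/calling tests."""
    return sd.build_scenario(sd.SimConfig(seed=11))


@pytest.fixture(scope="session")
def error_free_reads():
    """Error-free simulated reads plus their ground truth (mixed variant kinds)."""
    cfg = sd.SimConfig(
        seed=17, n_reads=120, error_rate=0.0,
        variant_kinds=("substitution", "insertion", "deletion"),
    )
    reads, truth, scenario = sd.simulate_reads(cfg)
    return cfg, reads, truth, scenario
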