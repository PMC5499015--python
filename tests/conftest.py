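import numpy as np
import pytest

from acetylcensus.io import SeqRecord
from acetylcensus.pipeline import load_inputs, run_census
from acetylcensus.profiles import AMINO_ACIDS, SeedAlignment, build_profile
from acetylcensus.simulate import simulate, small_config


def random_protein_string(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def make_alignment(rows: list[str], family: str = "FAM") -> SeedAlignment:
    return SeedAlignment(
        family=family,
        rows=tuple(SeqRecord(f"{family}_r{i}", f"{family}_r{i}", s) for i, s in enumerate(rows)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170705)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """A reduced synthetic study (12 species) run end to end through the census.

    Session-scoped: the simulate + classify cost is paid once and shared by
    the pipeline and acceptance tests.
    """
    out = tmp_path_factory.mktemp("bundle")
    bundle = simulate(small_config(7), out)
    inputs = load_inputs(out)
    result = run_census(inputs, seed=7, n_random=500)
    return bundle, inputs, result
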