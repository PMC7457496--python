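import pytest

from plastidkit.fixtures import (
    FragmentationSpec,
    PlastomeSpec,
    generate_plastome,
)


@pytest.fixture(scope="session")
def small_plastome():
    """A 37 kb quadripartite fixture used across modules."""
    return generate_plastome(
        PlastomeSpec(lsc_length=20_000, ssc_length=5_000, ir_length=6_000, seed=1)
    )


@pytest.fixture(scope="session")
def tiny_plastome():
    """A 10.5 kb fixture for expensive scans."""
    return generate_plastome(
        PlastomeSpec(lsc_length=6_000, ssc_length=2_000, ir_length=2_500, seed=2)
    )


def region_coords(structure):
    return [(r.start, r.end, r.label) for r in structure.regions()]
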