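import numpy as np
import pytest

from innervaquant import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def day15_spec():
    """A mid-density day-15 section spec used across modules."""
    return sim.SyntheticSpec(
        height=256,
        width=384,
        day_label=15,
        fiber_fraction={cell: 0.18 for cell in sim.day_cells(15)},
        seed=42,
    )


@pytest.fixture
def day15_section(day15_spec):
    return sim.generate_section(day15_spec, sample_id="fixture-d15")


def make_spec(fraction: float, day: int = 15, seed: int = 0, **overrides):
    """Section spec with one fraction applied to every available cell."""
    params = dict(
        height=256,
        width=384,
        day_label=day,
        fiber_fraction={cell: fraction for cell in sim.day_cells(day)},
        seed=seed,
    )
    params.update(overrides)
    return sim.SyntheticSpec(**params)
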