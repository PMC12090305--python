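import pytest

from firepas.synthetic import (LandscapeSpec, TrajectorySpec,
                               generate_landscape, generate_trajectories)


@pytest.fixture(scope="session")
def small_landscape():
    """Compact valley landscape: fast but window-complete everywhere."""
    spec = LandscapeSpec(extent=(400.0, 400.0), fine_cell_size=4.0,
                         n_stands=12, terrain_kind="valley", seed=11)
    return generate_landscape(spec)


@pytest.fixture(scope="session")
def small_states(small_landscape):
    spec = TrajectorySpec(managements=("NO", "Clearcut"),
                          climates=("historical", "SSP5-8.5"),
                          timesteps=(2020, 2050, 2080), seed=11)
    return generate_trajectories(spec, small_landscape.stands)
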