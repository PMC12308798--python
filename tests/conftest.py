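import pytest

from lamella.core import mmg_topology
from lamella.synthetic import SyntheticSystemSpec, generate_membrane_trajectory


@pytest.fixture(scope="session")
def topo():
    return mmg_topology()


@pytest.fixture(scope="session")
def small_bilayer():
    """2 x 25 lipid single bilayer, 6 frames, mixed motifs."""
    spec = SyntheticSystemSpec(
        n_per_leaflet=25,
        motif_fractions=(0.5, 0.2, 0.2, 0.1),
        n_frames=6,
        seed=11,
    )
    return generate_membrane_trajectory(spec)


@pytest.fixture(scope="session")
def double_and_interdigitated():
    """Matched-composition stacked systems for thickness/APL ordering checks."""
    common = dict(
        n_per_leaflet=36,
        motif_fractions=(0.7, 0.2, 0.05, 0.05),
        n_frames=4,
        seed=13,
    )
    double = generate_membrane_trajectory(
        SyntheticSystemSpec(arrangement="double_bilayer", apl_target=41.2, **common)
    )
    inter = generate_membrane_trajectory(
        SyntheticSystemSpec(arrangement="interdigitated", apl_target=72.0, **common)
    )
    return double, inter
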