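"""Shared phantom fixtures.

Session-scoped: phantom generation and full pipeline runs are the
expensive part of the suite, so cases used by several tests are built
once and reused read-only.
"""

import numpy as np
import pytest

from clotseg import (
    CaseInput,
    generate_phantom,
    run_pipeline,
    tube_phantom_spec,
)


@pytest.fixture(scope="session")
def straight_phantom():
    """Noise-free straight tube, 10 mm occlusion starting 12 mm in."""
    return generate_phantom(tube_phantom_spec(occlusion_start_mm=12.0, occlusion_length_mm=10.0))


@pytest.fixture(scope="session")
def patent_phantom():
    """Noise-free straight tube without occlusion."""
    return generate_phantom(tube_phantom_spec(occlusion_start_mm=None))


@pytest.fixture(scope="session")
def thin_tube_phantom():
    """2 mm-radius tube for analytic cylinder checks."""
    return generate_phantom(
        tube_phantom_spec(occlusion_start_mm=15.0, occlusion_length_mm=10.0, radius_mm=2.0)
    )


@pytest.fixture(scope="session")
def straight_output(straight_phantom):
    ph = straight_phantom
    return run_pipeline(
        CaseInput(image=ph.image, seeds=ph.seeds, symmetry_plane=ph.symmetry_plane)
    )


@pytest.fixture(scope="session")
def patent_output(patent_phantom):
    ph = patent_phantom
    return run_pipeline(
        CaseInput(image=ph.image, seeds=ph.seeds, symmetry_plane=ph.symmetry_plane)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
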