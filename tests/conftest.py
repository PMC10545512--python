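import numpy as np
import pytest

from cineqc.core_io import CANONICAL_LABELS, LabelStack
from cineqc.phantom import default_phantom_spec, generate_phantom, random_phantom_spec


@pytest.fixture(scope="session")
def reference_study():
    """The fixed reference phantom plus its analytic truth (read-only)."""
    return generate_phantom(default_phantom_spec(seed=11))


@pytest.fixture()
def study_factory():
    """Factory for seeded random phantoms at screening-test scale."""

    def make(seed, **kwargs):
        return generate_phantom(random_phantom_spec(seed, **kwargs))

    return make


def make_stack(voxels, spacing=(1.0, 1.0, 10.0), phase="ED"):
    """Hand-built LabelStack for arithmetic-level rule tests."""
    return LabelStack(
        voxels=np.asarray(voxels, dtype=np.int16),
        in_plane_spacing=spacing[:2],
        slice_spacing=spacing[2],
        label_map=dict(CANONICAL_LABELS),
        phase_tag=phase,
    )
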