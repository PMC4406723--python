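import numpy as np
import pytest

from headforge.grids import LabelVolume
from headforge.phantom import (
    PhantomSpec,
    TissueDef,
    default_head_spec,
    generate_label_phantom,
)


@pytest.fixture(scope="session")
def head_labels_32() -> LabelVolume:
    """Small default head phantom shared by read-only tests."""
    return generate_label_phantom(default_head_spec((32, 32, 32), (4.0, 4.0, 4.0)))


@pytest.fixture(scope="session")
def head_labels_48() -> LabelVolume:
    return generate_label_phantom(default_head_spec((48, 48, 48), (2.0, 2.0, 2.0)))


@pytest.fixture()
def ball_labels() -> LabelVolume:
    spec = PhantomSpec(
        (24, 24, 24), (1.0, 1.0, 1.0),
        [TissueDef(1, "ball",
                   {"kind": "ellipsoid", "center": [11.5] * 3, "radii": [8.0] * 3})],
    )
    return generate_label_phantom(spec)


def make_sphere_mask(shape, center, radius, spacing=1.0):
    """Brute-force oracle-style sphere rasterisation."""
    idx = np.indices(shape, dtype=float)
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    d2 = sum(((idx[a] * sp[a] - center[a]) ** 2 for a in range(3)))
    return d2 <= radius**2
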