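import numpy as np
import pytest

from handicor import (
    build_topology,
    generate_fixed_hinge,
    generate_pure_rolling,
    generate_rolling_sliding,
)
from handicor.contact_curves import PolarContactCurve


@pytest.fixture(scope="session")
def topology():
    return build_topology()


@pytest.fixture(scope="session")
def hinge_case():
    return generate_fixed_hinge((0.0, 0.0), 5.0, np.pi / 3, n_samples=200)


@pytest.fixture(scope="session")
def rolling_case():
    return generate_pure_rolling(3.0, 10.0, 0.5, n_samples=200)


@pytest.fixture(scope="session")
def mixed_case():
    return generate_rolling_sliding(5.0, 0.5, 1.0, n_samples=200)


def polar_pair(case):
    """Head and base polar curves (about the head pole) from a generated case."""
    pole = case.pole
    head = PolarContactCurve.from_points(case.head_contact_points, pole=pole)
    base = case.base_contact_points
    if hasattr(base, "points"):
        base = PolarContactCurve.from_points(base.points, pole=pole, side="base")
    return head, base
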