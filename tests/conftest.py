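import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shoulderx as sx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_spec() -> sx.PhantomSpec:
    """The 3-4-5 phantom: CSA = atan2-exact 36.8699, AI = 0.7, LAA = 53.1301."""
    return sx.PhantomSpec(
        csa_target=36.8699, ai_target=0.7, laa_target=53.1301, glenoid_length=120.0, seed=7
    )


@pytest.fixture(scope="session")
def reference_phantom(reference_spec):
    truth = sx.solve_landmarks(reference_spec)
    return truth, sx.render_masks(truth)


@pytest.fixture(scope="session")
def base_landmarks() -> sx.LandmarkSet:
    """Continuous landmark set with CSA 36.8699, AI 0.75, LAA 53.1301."""
    return sx.LandmarkSet(
        G=sx.Point(0.0, 0.0),
        I=sx.Point(0.0, 10.0),
        A=sx.Point(6.0, 2.0),
        H=sx.Point(8.0, 9.0),
        lateral_sign=+1,
    )


def random_landmark_sets(n: int, seed: int) -> list[sx.LandmarkSet]:
    """Valid landmark sets drawn around anatomically plausible geometry."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        L = rng.uniform(50, 200)
        gx, gy = rng.uniform(20, 80, 2)
        a = sx.Point(gx + rng.uniform(0.3, 1.2) * L, gy + rng.uniform(-0.8, 0.6) * L)
        h = sx.Point(gx + rng.uniform(0.3, 1.5) * L, gy + rng.uniform(0.4, 1.6) * L)
        try:
            out.append(
                sx.LandmarkSet(
                    G=sx.Point(gx, gy), I=sx.Point(gx, gy + L), A=a, H=h, lateral_sign=+1
                )
            )
        except sx.ShoulderXError:
            continue
    return out
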