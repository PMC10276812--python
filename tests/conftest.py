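import numpy as np
import pytest

from statenav.kinetics import DrugParams, GatingParams, KineticScheme, build_scheme


@pytest.fixture(scope="session")
def default_scheme() -> KineticScheme:
    return build_scheme()


@pytest.fixture(scope="session")
def structure_fixtures() -> dict:
    from statenav.synth import gen_structure_fixtures

    return gen_structure_fixtures()


def random_scheme(rng: np.random.Generator) -> KineticScheme:
    """A randomly calibrated six-state scheme (valid by construction)."""
    gating = GatingParams(
        v_half=float(rng.uniform(-95.0, -55.0)),
        slope=float(rng.uniform(5.0, 11.0)),
        tau_anchors=(
            (-40.0, float(rng.uniform(1.0, 8.0))),
            (-100.0, float(rng.uniform(1.0, 8.0))),
        ),
        slow_entry_rate=float(rng.uniform(1e-4, 2e-3)),
        slow_exit_rate=float(rng.uniform(0.01, 0.2)),
    )
    kd_rest = float(rng.uniform(100.0, 5000.0))
    drug = DrugParams(
        kd_rest=np.inf if rng.random() < 0.15 else kd_rest,
        kd_inact=float(rng.uniform(10.0, 300.0)),
        k_on=float(10.0 ** rng.uniform(-8.5, -5.0)),
        bound_gating_factor=float(rng.uniform(0.3, 2.0)),
    )
    return build_scheme(gating, drug)
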