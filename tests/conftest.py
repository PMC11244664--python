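"""Shared fixtures: the default study phantom/plan are expensive enough to
build once per session; toy objects are cheap and function-scoped."""

import pytest

from pbs4d import (
    DoseInfluence,
    build_phantom,
    generate_plan,
    load_machine,
    reference_metrics,
)
from pbs4d.plan import EnergyLayer, Spot, TreatmentPlan


@pytest.fixture(scope="session")
def phantom():
    """Default study phantom: 2-mm grid, 25-mm target, ±10 mm SI motion."""
    return build_phantom()


@pytest.fixture(scope="session")
def generated(phantom):
    """Default synthetic PA plan plus its calibrated dose model."""
    return generate_plan(phantom)


@pytest.fixture(scope="session")
def machines():
    return [load_machine(name) for name in ("2015", "2025A", "2025B")]


@pytest.fixture(scope="session")
def reference(phantom, generated):
    return reference_metrics(generated.plan, phantom, generated.model)


@pytest.fixture(scope="session")
def influence(phantom, generated):
    return DoseInfluence(generated.model, phantom, generated.plan)


@pytest.fixture
def toy_plan():
    """Three 2-MU spots on one 230-MeV layer, 10 mm apart in x."""
    return TreatmentPlan(
        layers=(EnergyLayer(230.0, (Spot(0, 0, 2.0), Spot(10, 0, 2.0), Spot(20, 0, 2.0))),)
    )
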