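import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import netdea as nd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(values, dmu_ids=None, periods=None, variable_ids=None, groups=None):
    """Small helper: panel from a (n, T, J) array with default labels."""
    values = np.asarray(values, dtype=float)
    n, T, J = values.shape
    dmu_ids = dmu_ids or tuple(f"D{i+1}" for i in range(n))
    periods = periods or tuple(f"p{t+1}" for t in range(T))
    variable_ids = variable_ids or tuple(f"v{j+1}" for j in range(J))
    groups = groups or {d: "G" for d in dmu_ids}
    return nd.PanelDataset(dmu_ids, periods, variable_ids, values, groups)


def single_division_spec(m, r, orientation="input_oriented"):
    inputs = tuple(f"x{i+1}" for i in range(m))
    outs = tuple(f"v{i+1}" for i in range(r))
    return nd.NetworkSpec(
        divisions=("d1",),
        inputs={"d1": inputs},
        desirable_outputs={"d1": outs},
        undesirable_outputs={},
        orientation={"d1": orientation},
    )


def random_single_division_instance(rng, n=None, with_undesirable=False):
    """Random K=1 instance with entries in [1, 10]; returns (panel, spec, o)."""
    n = n if n is not None else int(rng.integers(1, 4))
    m = int(rng.integers(1, 3))
    r = int(rng.integers(1, 3))
    w = 1 if with_undesirable else 0
    orientation = rng.choice(["input_oriented", "output_oriented"])
    inputs = tuple(f"x{i+1}" for i in range(m))
    outs = tuple(f"v{i+1}" for i in range(r))
    unds = tuple(f"u{i+1}" for i in range(w))
    spec = nd.NetworkSpec(
        divisions=("d1",),
        inputs={"d1": inputs},
        desirable_outputs={"d1": outs},
        undesirable_outputs={"d1": unds} if w else {},
        orientation={"d1": orientation},
    )
    values = rng.uniform(1.0, 10.0, size=(n, 1, m + r + w))
    panel = make_panel(values, variable_ids=inputs + outs + unds)
    return panel, spec, int(rng.integers(0, n))


def two_division_spec(with_undesirable=True):
    """Input-oriented stage feeding an output-oriented stage via one link."""
    return nd.NetworkSpec(
        divisions=("stage1", "stage2"),
        inputs={"stage1": ("x1", "x2")},
        desirable_outputs={"stage2": ("v1",)},
        undesirable_outputs={"stage2": ("u1",)} if with_undesirable else {},
        links=(("stage1", "stage2", "z1"),),
    )


def random_two_division_instance(rng, n=5, with_undesirable=True):
    spec = two_division_spec(with_undesirable)
    var_ids = spec.variables()
    values = rng.uniform(1.0, 10.0, size=(n, 1, len(var_ids)))
    panel = make_panel(values, variable_ids=var_ids)
    return panel, spec


@pytest.fixture
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture
def hospital_panel():
    """Default-condition synthetic hospital panel (small seed, full size)."""
    return nd.generate_panel(nd.SyntheticConfig(seed=7))
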