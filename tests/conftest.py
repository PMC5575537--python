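import numpy as np
import pytest

from rhizosim.architecture import RootClassParams, RootSystem


def make_class(**kw) -> RootClassParams:
    defaults = dict(name="root", elongation_rate=[(0.0, 1.0)],
                    initial_diameter=0.05, segment_length=0.5)
    defaults.update(kw)
    return RootClassParams(**defaults)


def straight_system(length=10.0, rate=1.0, segment_length=1.0,
                    diameter=0.05, seed=0, base=(0.0, 0.0, 0.0),
                    **class_kw) -> RootSystem:
    """A single vertical root of the requested length (pure gravitropism,
    no impedance, vigor off), grown in daily steps."""
    params = make_class(name="primary", elongation_rate=[(0.0, rate)],
                        segment_length=segment_length,
                        initial_diameter=diameter,
                        gravitropism_weight=1.0, **class_kw)
    rs = RootSystem({"primary": params}, seed=seed, seed_depth=base[2])
    rs.add_axis("primary", base_position=np.array(base))
    days = length / rate
    n = int(round(days / 0.25))
    for _ in range(n):
        rs.grow(0.25)
    return rs


@pytest.fixture
def vertical_10cm():
    return straight_system(length=10.0)
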