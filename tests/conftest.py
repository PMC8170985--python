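"""Shared fixtures: expensive simulation runs are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from myofoam import fixtures

SFO_SWEEP = (0.5, 1.0, 2.0, 10.0)


@pytest.fixture(scope="session")
def coupon_runs():
    """Coupon run per SFO value, keyed by SFO."""
    out = {}
    for sfo in SFO_SWEEP:
        fx = fixtures.make_uniaxial_coupon(sfo=sfo, seed=11)
        out[sfo] = (fx, fx.run())
    return out


@pytest.fixture(scope="session")
def drop_runs():
    """Drop-block run per SFO value, keyed by SFO."""
    out = {}
    for sfo in SFO_SWEEP:
        fx = fixtures.make_drop_block(sfo=sfo, seed=11)
        out[sfo] = (fx, fx.run())
    return out


@pytest.fixture(scope="session")
def cuboid_runs():
    """Cuboid8 runs: four SFO values plus a rate-table material."""
    out = {}
    for sfo in SFO_SWEEP:
        fx = fixtures.make_cuboid8(sfo=sfo, seed=11)
        out[sfo] = (fx, fx.run())
    fx = fixtures.make_cuboid8(rate_table=fixtures.default_rate_table(), seed=11)
    out["rate_table"] = (fx, fx.run())
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_deformation_gradient(rng, spread=0.3):
    """Random invertible F with positive determinant, moderate stretch."""
    while True:
        F = np.eye(3) + spread * (rng.random((3, 3)) - 0.5)
        if np.linalg.det(F) > 0.3:
            return F
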