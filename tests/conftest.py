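"""Shared fixtures: compact phantoms, planned arms and accumulated doses.

The expensive objects (dose engines, plans, 4D accumulations) are session
scoped and shared between unit and acceptance tests; they are built on
compact grids so the whole suite stays desk scale.
"""

import numpy as np
import pytest

from sbrt4d.cohort import load_table1
from sbrt4d.dose3d import DoseEngine, plan_itv, plan_track
from sbrt4d.dose4d import accumulate_4d
from sbrt4d.phantom4d import (
    PhantomConfig, make_phantom, scenario_high_overlap,
)
from sbrt4d.structures import build_structure_sets


@pytest.fixture(scope="session")
def table1_records():
    return load_table1()


@pytest.fixture(scope="session")
def hi_pack():
    """High-overlap scenario (large SI motion, duodenum adjacent): phantom,
    structure sets, engine and both planned arms."""
    phantom = make_phantom(scenario_high_overlap(grid=48))
    ssets = build_structure_sets(phantom)
    engine = DoseEngine(phantom.grid, phantom.body_mask)
    res_itv = plan_itv(phantom, ssets, engine=engine)
    res_trk = plan_track(phantom, ssets, engine=engine)
    return {
        "phantom": phantom, "ssets": ssets, "engine": engine,
        "itv": res_itv, "tracking": res_trk,
    }


@pytest.fixture(scope="session")
def hi_acc(hi_pack):
    """4D accumulations for the high-overlap scenario, both arms."""
    engine = hi_pack["engine"]
    phantom = hi_pack["phantom"]
    return {
        "itv": accumulate_4d(engine, hi_pack["itv"].plan, phantom, "itv"),
        "tracking": accumulate_4d(engine, hi_pack["tracking"].plan, phantom,
                                  "tracking"),
    }


@pytest.fixture(scope="session")
def zero_pack():
    """Zero-motion phantom with both arms planned and 4D-accumulated."""
    cfg = PhantomConfig(grid_shape=(40, 40, 40),
                        motion_amplitude_mm=(0.0, 0.0, 0.0))
    phantom = make_phantom(cfg)
    ssets = build_structure_sets(phantom)
    engine = DoseEngine(phantom.grid, phantom.body_mask)
    res_itv = plan_itv(phantom, ssets, engine=engine)
    res_trk = plan_track(phantom, ssets, engine=engine)
    acc_itv = accumulate_4d(engine, res_itv.plan, phantom, "itv")
    acc_trk = accumulate_4d(engine, res_trk.plan, phantom, "tracking")
    return {
        "phantom": phantom, "ssets": ssets, "engine": engine,
        "itv": res_itv, "tracking": res_trk,
        "acc_itv": acc_itv, "acc_tracking": acc_trk,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20170906)
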