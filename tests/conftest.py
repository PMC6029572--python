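"""Shared fixtures: a desk-scale phantom, protocol and fast frequency plan."""

from types import SimpleNamespace

import numpy as np
import pytest

from mfeit import (ElectrodeLayout, InjectionProtocol, NoiseModel,
                   PhantomModel, build_measurement_list, parse_triggers,
                   synthesize_recording)
from mfeit.filters import FilterSpec
from mfeit.protocol import FrequencyPlan, PlanEntry


@pytest.fixture(scope="session")
def layout8() -> ElectrodeLayout:
    return ElectrodeLayout.default(8)


@pytest.fixture(scope="session")
def protocol5() -> InjectionProtocol:
    return InjectionProtocol(((1, 5), (2, 6), (3, 7), (4, 8), (1, 3)))


@pytest.fixture(scope="session")
def phantom8() -> PhantomModel:
    return PhantomModel.random_mesh(8, seed=7)


@pytest.fixture(scope="session")
def plan_short() -> FrequencyPlan:
    """Three high carriers (sub-second sweep) for fast end-to-end tests."""
    rows = ((200.0, 90.0, 64, "BP IIR 5"),
            (1000.0, 140.0, 64, None),
            (2000.0, 280.0, 128, "BP FIR 490"))
    return FrequencyPlan(tuple(
        PlanEntry(c, a, p, round(1000.0 * p / c),
                  FilterSpec.from_string(f, c) if f else None)
        for c, a, p, f in rows))


@pytest.fixture(scope="session")
def small_noiseless(plan_short, protocol5, layout8, phantom8) -> SimpleNamespace:
    """Noiseless two-frame synthetic recording plus everything to process it."""
    rec, gt = synthesize_recording(plan_short, protocol5, layout8, phantom8,
                                   NoiseModel.silent(), n_frames=2)
    mlist = build_measurement_list(protocol5, layout8)
    index = parse_triggers(rec, plan_short, protocol5.n_injections, 2)
    return SimpleNamespace(rec=rec, gt=gt, mlist=mlist, index=index,
                           plan=plan_short, protocol=protocol5,
                           layout=layout8, phantom=phantom8)
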