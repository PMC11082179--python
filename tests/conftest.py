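import numpy as np
import pandas as pd
import pytest

from elegreet.records import SignalRecord
from elegreet.simulate import SimulationParams, generate_signals, reference_fixture


def make_signal(**kw) -> SignalRecord:
    base = dict(
        event_id="ev1",
        signaller_id="A",
        recipient_id="B",
        signal_type="Ear-Spread",
        category="body_act",
        articulator="ears",
        modality="silent_visual",
        onset_s=0.0,
        offset_s=1.0,
        signaller_attending="yes",
        recipient_attending="yes",
        distance_m=2.0,
        signaller_aware_of_recipient="yes",
    )
    base.update(kw)
    return SignalRecord(**base)


def make_vocal(**kw) -> SignalRecord:
    base = dict(
        signal_type="Rumble",
        category="vocalisation",
        articulator="vocal_tract",
        modality="vocal",
        signaller_attending="unknown",
        recipient_attending="unknown",
        distance_m=float("nan"),
    )
    base.update(kw)
    return make_signal(**base)


@pytest.fixture(scope="session")
def fixture_records():
    return reference_fixture()


@pytest.fixture(scope="session")
def synthetic_dataset():
    params = SimulationParams(seed=11)
    records, truth = generate_signals(params)
    return records, truth, params
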