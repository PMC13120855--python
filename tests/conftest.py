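import pytest

from dyadica import Bout, BoutTable, DEFAULT_CATALOG, FlyInfo, Trial


@pytest.fixture
def catalog():
    return DEFAULT_CATALOG


def make_trial(
    duration=36000, frame_rate=30.0, copulation_onset=None, assay="dyad", n_flies=2
):
    sexes = ["male", "male", "female"]
    return Trial(
        trial_id="t1",
        assay=assay,
        frame_rate=frame_rate,
        duration=duration,
        roster=tuple(
            FlyInfo(fly_id=chr(ord("A") + i), sex=sexes[i % 3])
            for i in range(n_flies)
        ),
        copulation_onset=copulation_onset,
    )


def make_table(rows, trial_id="t1"):
    """rows: (fly, action, start, end) or (fly, action, start, end, target)."""
    return BoutTable(trial_id, tuple(Bout(*r) for r in rows))


@pytest.fixture
def simple_trial():
    return make_trial()
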