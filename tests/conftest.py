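import datetime

import numpy as np
import pytest

from itsmc.data_model_io import (
    DEFAULT_WINDOW,
    HalfYearPanel,
    InjuryEvent,
    Location,
)

# Printed study counts: (before, after) by stratum; 17 pre / 10 post periods.
TABLE1_COUNTS = {
    "all": (1748, 874),
    "private": (1269, 610),
    "public": (480, 264),
}
N_PRE, N_POST = 17, 10


def make_fixture_events(n_pre: int = 1748, n_post: int = 874) -> list[InjuryEvent]:
    """Deterministic event list: n_pre events cycled over the 17 pre periods,
    n_post over the 10 post periods, alternating private/public locations."""
    window = DEFAULT_WINDOW
    periods = window.periods()
    k = window.intervention_index()
    events = []
    for j in range(n_pre):
        year, half = periods[j % k]
        day = datetime.date(year, 2 if half == 1 else 8, 1 + (j % 27))
        loc = Location.PRIVATE if j % 2 == 0 else Location.PUBLIC
        events.append(InjuryEvent(date=day, location=loc))
    post_periods = periods[k:]
    for j in range(n_post):
        year, half = post_periods[j % len(post_periods)]
        day = datetime.date(year, 3 if half == 1 else 9, 1 + (j % 27))
        loc = Location.PRIVATE if j % 2 == 0 else Location.PUBLIC
        events.append(InjuryEvent(date=day, location=loc))
    return events


def make_table1_panel() -> HalfYearPanel:
    """Conservation-consistent panel carrying the printed stratum counts.

    private 1269/610 and public 480/264 exactly; counts_all is their sum
    (1749/874 — the printed 'All before' of 1748 is internally inconsistent
    with the printed strata and is checked via the scalar operations)."""
    periods = DEFAULT_WINDOW.periods()
    k = DEFAULT_WINDOW.intervention_index()
    n = len(periods)

    def spread(total, slots):
        base, extra = divmod(total, slots)
        return np.array([base + (1 if i < extra else 0) for i in range(slots)])

    private = np.r_[spread(1269, k), spread(610, n - k)]
    public = np.r_[spread(480, k), spread(264, n - k)]
    return HalfYearPanel(
        periods=periods,
        counts_private=private,
        counts_public=public,
        counts_all=private + public,
        intervention_index=k,
    )


@pytest.fixture
def table1_panel() -> HalfYearPanel:
    return make_table1_panel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)
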