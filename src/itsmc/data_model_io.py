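"""Event and panel data model for half-year stratified count series.

Emergency-department injury events carry a calendar date and a location
stratum (private / public / unknown).  Events are binned into half-year
periods (H1 = Jan 1 - Jun 30, H2 = Jul 1 - Dec 31) stratified by location,
producing a :class:`HalfYearPanel` with an intervention boundary index that
splits the series into a pre- and a post-period.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import enum
import io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Location",
    "InjuryEvent",
    "StudyWindow",
    "HalfYearPanel",
    "BinResult",
    "DEFAULT_WINDOW",
    "STRATA",
    "bin_events",
    "split_pre_post",
    "read_events_csv",
    "read_panel_csv",
    "write_panel_csv",
]

STRATA = ("all", "private", "public")


class Location(enum.Enum):
    """Location stratum of an injury event."""

    PRIVATE = "private"
    PUBLIC = "public"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str) -> "Location":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown location {token!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclasses.dataclass(frozen=True)
class InjuryEvent:
    """One emergency-department presentation: calendar date + location."""

    date: datetime.date
    location: Location

    def __post_init__(self) -> None:
        if not isinstance(self.date, datetime.date) or isinstance(
            self.date, datetime.datetime
        ):
            raise TypeError("date must be a datetime.date (no time component)")
        if not isinstance(self.location, Location):
            raise TypeError("location must be a Location")


def _period_of(date: datetime.date) -> tuple[int, int]:
    return (date.year, 1 if date.month <= 6 else 2)


def _period_start(year: int, half: int) -> datetime.date:
    return datetime.date(year, 1 if half == 1 else 7, 1)


def _period_end(year: int, half: int) -> datetime.date:
    return datetime.date(year, 6, 30) if half == 1 else datetime.date(year, 12, 31)


@dataclasses.dataclass(frozen=True)
class StudyWindow:
    """Observation window with an intervention date inside it.

    The window must be aligned to half-year boundaries: ``start`` on a
    Jan 1 or Jul 1, ``end`` on a Jun 30 or Dec 31.
    """

    start: datetime.date
    end: datetime.date
    intervention_date: datetime.date

    def __post_init__(self) -> None:
        if not (self.start < self.intervention_date <= self.end):
            raise ValueError(
                "require start < intervention_date <= end, got "
                f"{self.start} / {self.intervention_date} / {self.end}"
            )
        if (self.start.month, self.start.day) not in ((1, 1), (7, 1)):
            raise ValueError(f"window start {self.start} is not a half-year boundary")
        if (self.end.month, self.end.day) not in ((6, 30), (12, 31)):
            raise ValueError(f"window end {self.end} is not a half-year boundary")

    def periods(self) -> list[tuple[int, int]]:
        """Ordered (year, half) grid covering the window."""
        out = []
        year, half = _period_of(self.start)
        while (year, half) <= _period_of(self.end):
            out.append((year, half))
            year, half = (year, 2) if half == 1 else (year + 1, 1)
        return out

    def intervention_index(self) -> int:
        """Index of the first post-intervention period.

        The intervention date is snapped to the nearest half-year boundary
        (period start); the first period starting on or after that boundary
        is the first post period.
        """
        d = self.intervention_date
        candidates = [
            _period_start(d.year, 1),
            _period_start(d.year, 2),
            datetime.date(d.year + 1, 1, 1),
        ]
        boundary = min(candidates, key=lambda b: abs((b - d).days))
        periods = self.periods()
        for i, (y, h) in enumerate(periods):
            if _period_start(y, h) >= boundary:
                if i == 0:
                    raise ValueError("intervention boundary precedes the window")
                return i
        raise ValueError("intervention boundary falls after the window")


#: Jan 1 2002 - Jun 30 2015 with the ban taking effect June 1 2010:
#: 27 half-year periods, 17 pre (2002H1..2010H1) and 10 post (2010H2..2015H1).
DEFAULT_WINDOW = StudyWindow(
    start=datetime.date(2002, 1, 1),
    end=datetime.date(2015, 6, 30),
    intervention_date=datetime.date(2010, 6, 1),
)


@dataclasses.dataclass
class HalfYearPanel:
    """Stratified half-year counts with an intervention boundary.

    ``counts_all`` may exceed ``counts_private + counts_public`` when events
    with unknown location are present; the difference is exposed as
    :meth:`counts_unknown`.
    """

    periods: list[tuple[int, int]]
    counts_private: np.ndarray
    counts_public: np.ndarray
    counts_all: np.ndarray
    intervention_index: int

    def __post_init__(self) -> None:
        self.counts_private = np.asarray(self.counts_private, dtype=np.int64)
        self.counts_public = np.asarray(self.counts_public, dtype=np.int64)
        self.counts_all = np.asarray(self.counts_all, dtype=np.int64)
        n = len(self.periods)
        for name in ("counts_private", "counts_public", "counts_all"):
            v = getattr(self, name)
            if v.shape != (n,):
                raise ValueError(f"{name} has shape {v.shape}, expected ({n},)")
            if (v < 0).any():
                raise ValueError(f"{name} contains negative counts")
        if (self.counts_all < self.counts_private + self.counts_public).any():
            raise ValueError("counts_all below sum of strata (conservation violated)")
        if not 0 < self.intervention_index < n:
            raise ValueError(
                f"intervention_index {self.intervention_index} outside (0, {n})"
            )

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def counts_unknown(self) -> np.ndarray:
        return self.counts_all - self.counts_private - self.counts_public

    def counts(self, stratum: str) -> np.ndarray:
        if stratum not in STRATA:
            raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
        return getattr(self, f"counts_{stratum}" if stratum != "all" else "counts_all")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [y for y, _ in self.periods],
                "half": [h for _, h in self.periods],
                "private": self.counts_private,
                "public": self.counts_public,
                "all": self.counts_all,
            }
        )


@dataclasses.dataclass
class BinResult:
    """Outcome of binning: the panel plus any rejected (out-of-window) events."""

    panel: HalfYearPanel
    rejected: list[InjuryEvent]

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def bin_events(
    events: list[InjuryEvent],
    window: StudyWindow = DEFAULT_WINDOW,
    *,
    on_outside: str = "reject",
) -> BinResult:
    """Bin events into a stratified half-year panel over ``window``.

    Each event is assigned to the half-year containing its date.  Events
    dated outside the window are collected in ``BinResult.rejected`` (or
    raise, with ``on_outside="error"``).  Total events are conserved:
    ``panel.counts_all.sum() + n_rejected == len(events)``.
    """
    if on_outside not in ("reject", "error"):
        raise ValueError("on_outside must be 'reject' or 'error'")
    periods = window.periods()
    index = {p: i for i, p in enumerate(periods)}
    n = len(periods)
    private = np.zeros(n, dtype=np.int64)
    public = np.zeros(n, dtype=np.int64)
    total = np.zeros(n, dtype=np.int64)
    rejected: list[InjuryEvent] = []
    for ev in events:
        if not window.start <= ev.date <= window.end:
            if on_outside == "error":
                raise ValueError(f"event dated {ev.date} outside study window")
            rejected.append(ev)
            continue
        i = index[_period_of(ev.date)]
        total[i] += 1
        if ev.location is Location.PRIVATE:
            private[i] += 1
        elif ev.location is Location.PUBLIC:
            public[i] += 1
    panel = HalfYearPanel(
        periods=periods,
        counts_private=private,
        counts_public=public,
        counts_all=total,
        intervention_index=window.intervention_index(),
    )
    return BinResult(panel=panel, rejected=rejected)


def split_pre_post(panel: HalfYearPanel, stratum: str = "all"):
    """Split one stratum's count series at the intervention boundary.

    Returns ``(pre, post)`` with ``len(pre) == panel.intervention_index``;
    their concatenation reproduces the stratum's full series.
    """
    series = panel.counts(stratum)
    k = panel.intervention_index
    return series[:k].copy(), series[k:].copy()


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_events_csv(path) -> list[InjuryEvent]:
    """Read events from a CSV with header columns ``date`` (ISO) and ``location``."""
    events = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"date", "location"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: expected header columns 'date' and 'location'")
        for rownum, row in enumerate(reader, start=1):
            try:
                date = datetime.date.fromisoformat(row["date"].strip())
                loc = Location.parse(row["location"])
            except ValueError as exc:
                raise ValueError(f"{path}: row {rownum}: {exc}") from None
            events.append(InjuryEvent(date=date, location=loc))
    return events


def write_events_csv(events: list[InjuryEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "location"])
        for ev in events:
            writer.writerow([ev.date.isoformat(), ev.location.value])


def write_panel_csv(panel: HalfYearPanel, path) -> None:
    """Write a panel as ``year,half,private,public,all`` with the intervention
    index recorded in a leading comment line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# intervention_index={panel.intervention_index}\n")
        panel.to_frame().to_csv(fh, index=False)


def read_panel_csv(path) -> HalfYearPanel:
    text = Path(path).read_text()
    intervention_index = None
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            if key.strip() == "intervention_index":
                intervention_index = int(val)
        else:
            body_lines.append(line)
    if intervention_index is None:
        raise ValueError(f"{path}: missing '# intervention_index=N' comment line")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    missing = {"year", "half", "private", "public", "all"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return HalfYearPanel(
        periods=list(zip(df["year"].astype(int), df["half"].astype(int))),
        counts_private=df["private"].to_numpy(),
        counts_public=df["public"].to_numpy(),
        counts_all=df["all"].to_numpy(),
        intervention_index=intervention_index,
    )
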