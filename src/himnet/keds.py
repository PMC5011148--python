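"""WEIS-coded dyadic event data and monthly multiplex construction.

Event datasets in the KEDS tradition record one dyadic political event per
line: a date, a source actor, a target actor and a 3-digit WEIS (World
Event/Interaction Survey) category code.  The 66 monitored categories each
define one layer of a monthly multiplex network: layer i has an undirected
binary link (a, b) in month M iff at least one event of that category
occurred between a and b (in either direction) during M.  The node set is
the union of all actors over the whole analysis range, fixed across time,
so early months carry many isolated nodes — required for HIM comparability
across months.

Actor codes are used verbatim from the file; no alias merging is attempted
(any merging done upstream of a deposited file is unrecoverable, a known
reproducibility caveat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import Graph, MultiplexSeries, MultiplexSnapshot

__all__ = [
    "EventRecord",
    "LayerCatalog",
    "WEIS_LAYERS",
    "default_catalog",
    "parse_events",
    "build_multiplex",
    "degree_summary",
    "edge_summary",
    "edge_occurrence_series",
    "STANDARD_PERIODS",
]

log = logging.getLogger(__name__)

# The 66 monitored WEIS categories: (layer number, code, category, description).
WEIS_LAYERS: tuple[tuple[int, str, str, str], ...] = (
    (1, "011", "Yield", "Surrender, yield or order, submit to arrest"),
    (2, "012", "Yield", "Yield position, retreat; evacuate"),
    (3, "013", "Yield", "Admit wrongdoing; retract statement"),
    (4, "015", "Yield", "Cede Power"),
    (5, "021", "Comment", "Explicit decline to comment"),
    (6, "022", "Comment", "Comment on situation - pessimistic"),
    (7, "023", "Comment", "Comment on situation - neutral"),
    (8, "024", "Comment", "Comment on situation - optimistic"),
    (9, "025", "Comment", "Explain policy or future position"),
    (10, "031", "Consult", "Meet with at neutral site, or send note"),
    (11, "032", "Consult", "Consult & Visit; go to"),
    (12, "033", "Consult", "Receive visit; host"),
    (13, "041", "Approve", "Praise, hail, applaud, condole"),
    (14, "042", "Approve", "Endorse other's policy or position; give verbal support"),
    (15, "051", "Promise", "Promise own policy support"),
    (16, "052", "Promise", "Promise material support"),
    (17, "053", "Promise", "Promise other future support action"),
    (18, "054", "Promise", "Assure; reassure"),
    (19, "061", "Grant", "Express regret; apologize"),
    (20, "062", "Grant", "Give state invitation"),
    (21, "063", "Grant", "Grant asylum"),
    (22, "064", "Grant", "Grant privilege, diplomatic recognition"),
    (23, "065", "Grant", "Suspend negative sanctions; truce"),
    (24, "066", "Grant", "Release and/or return persons or property"),
    (25, "070", "Reward", "Reward"),
    (26, "071", "Reward", "Extend economic aid (as gift and/or loan)"),
    (27, "072", "Reward", "Extend military assistance"),
    (28, "073", "Reward", "Give other assistance"),
    (29, "081", "Agree", "Make substantive agreement"),
    (30, "082", "Agree", "Agree to future action or procedure; agree to meet"),
    (31, "091", "Request", "Ask for information"),
    (32, "092", "Request", "Ask for policy assistance"),
    (33, "093", "Request", "Ask for material assistance"),
    (34, "094", "Request", "Request action; call for"),
    (35, "095", "Request", "Entreat; plead; appeal to"),
    (36, "101", "Propose", "Offer proposal"),
    (37, "102", "Propose", "Urge or suggest action or policy"),
    (38, "111", "Reject", "Turn down proposal; reject protest demand, threat"),
    (39, "112", "Reject", "Refuse; oppose; refuse to allow"),
    (40, "121", "Accuse", "Charge; criticize; blame; disapprove"),
    (41, "122", "Accuse", "Denounce; denigrate; abuse"),
    (42, "131", "Protest", "Make complaint (not formal)"),
    (43, "132", "Protest", "Make formal complaint or protest"),
    (44, "141", "Deny", "Deny an accusation"),
    (45, "142", "Deny", "Deny an attributed policy, action role or position"),
    (46, "150", "Demand", "Issue order or command; insist; demand compliance"),
    (47, "160", "Warn", "Give warning"),
    (48, "161", "Warn", "Warn of policies"),
    (49, "171", "Threaten", "Threat without specific negative sanctions"),
    (50, "172", "Threaten", "Threat with specific non-military negative sanctions"),
    (51, "173", "Threaten", "Threat with force specified"),
    (52, "174", "Threaten", "Ultimatum; threat with negative sanctions and time limit"),
    (53, "181", "Demonstrate", "Non-military demonstration; to walk out on"),
    (54, "182", "Demonstrate", "Armed force mobilization"),
    (55, "191", "Reduce Relations", "Cancel or postpone planned event"),
    (56, "192", "Reduce Relations", "Reduce routine international activity; recall officials"),
    (57, "193", "Reduce Relations", "Reduce or halt aid"),
    (58, "194", "Reduce Relations", "Halt negotiations"),
    (59, "195", "Reduce Relations", "Break diplomatic relations"),
    (60, "201", "Expel", "Order personnel out of country"),
    (61, "202", "Expel", "Expel organization or group"),
    (62, "211", "Seize", "Seize position or possessions"),
    (63, "212", "Seize", "Detain or arrest person(s)"),
    (64, "221", "Force", "Non-injury obstructive act"),
    (65, "222", "Force", "Non-military injury-destruction"),
    (66, "223", "Force", "Military engagement"),
)

#: Named analysis windows: full range, First Gulf War, Iraq Disarmament Crisis.
STANDARD_PERIODS: dict[str, tuple[date, date]] = {
    "FULL": (date(1979, 4, 1), date(1999, 3, 31)),
    "FGW": (date(1990, 8, 1), date(1991, 3, 31)),
    "IDC": (date(1998, 2, 1), date(1998, 2, 28)),
}


@dataclass(frozen=True)
class EventRecord:
    """One dyadic event: day, source actor, target actor, WEIS code."""

    date: date
    source_actor: str
    target_actor: str
    weis_code: str

    def dyad(self) -> tuple[str, str]:
        """Unordered actor pair, sorted."""
        return tuple(sorted((self.source_actor, self.target_actor)))  # type: ignore


@dataclass(frozen=True)
class LayerCatalog:
    """Ordered mapping layer number <-> WEIS code <-> description."""

    entries: tuple[tuple[int, str, str, str], ...] = WEIS_LAYERS

    def __post_init__(self) -> None:
        nums = [e[0] for e in self.entries]
        codes = [e[1] for e in self.entries]
        if nums != list(range(1, len(self.entries) + 1)):
            raise ValueError("layer numbers must be 1..n in order")
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate WEIS codes in catalog")
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def n_layers(self) -> int:
        return len(self.entries)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e[1] for e in self.entries)

    def layer_of(self, code: str) -> int | None:
        """1-based layer number of a WEIS code, None if not monitored."""
        try:
            return self.codes.index(code) + 1
        except ValueError:
            return None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["layer", "weis_code", "weis_category", "description"]
        )


def default_catalog() -> LayerCatalog:
    return LayerCatalog()


def _parse_date(token: str) -> date:
    token = token.strip()
    for fmt in ("%y%m%d", "%Y%m%d", "%Y-%m-%d", "%d/%m/%y"):
        try:
            d = datetime.strptime(token, fmt).date()
            # two-digit years: the KEDS era is 1900s
            if fmt == "%y%m%d" and d.year > 2050:
                d = d.replace(year=d.year - 100)
            return d
        except ValueError:
            continue
    raise ValueError(f"unparseable date {token!r}")


def parse_events(
    path: str,
    catalog: LayerCatalog | None = None,
    columns: Sequence[int] = (0, 1, 2, 3),
) -> list[EventRecord]:
    """Parse a KEDS-style event file into records, in file order.

    Lines are whitespace/tab delimited; ``columns`` gives the indices of the
    (date, source, target, code) fields so other dialects can be read.
    Events whose code carries extra digits beyond three are truncated to the
    3-digit WEIS category.  Malformed lines and unmonitored codes are
    counted and logged, not fatal; a file with zero parseable records
    raises.
    """
    cat = catalog or default_catalog()
    monitored = set(cat.codes)
    ci_date, ci_src, ci_tgt, ci_code = columns
    need = max(columns) + 1
    records: list[EventRecord] = []
    bad_lines = 0
    unknown_codes = 0
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "%")):
                continue
            parts = line.split()
            if len(parts) < need:
                bad_lines += 1
                log.warning("%s:%d: expected >=%d fields, got %d", path, lineno, need, len(parts))
                continue
            try:
                day = _parse_date(parts[ci_date])
            except ValueError:
                bad_lines += 1
                log.warning("%s:%d: bad date %r", path, lineno, parts[ci_date])
                continue
            src, tgt = parts[ci_src], parts[ci_tgt]
            code = parts[ci_code][:3]
            if not src or not tgt:
                bad_lines += 1
                continue
            if code not in monitored:
                unknown_codes += 1
                log.warning("%s:%d: unmonitored WEIS code %r skipped", path, lineno, parts[ci_code])
                continue
            records.append(EventRecord(day, src, tgt, code))
    if bad_lines or unknown_codes:
        log.info(
            "%s: %d records, %d malformed lines, %d unmonitored-code events skipped",
            path, len(records), bad_lines, unknown_codes,
        )
    if not records:
        raise ValueError(f"{path}: no parseable event records")
    return records


def _month_range(start: date, end: date) -> list[tuple[int, int]]:
    months = []
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        months.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return months


def build_multiplex(
    events: Iterable[EventRecord],
    catalog: LayerCatalog | None = None,
    period_start: date | None = None,
    period_end: date | None = None,
) -> MultiplexSeries:
    """Bin events into a monthly multiplex series.

    One snapshot per calendar month in [period_start, period_end] (default:
    the span of the events); layer i holds an undirected binary link (a, b)
    iff at least one event of layer i's WEIS code occurred between a and b,
    in either direction, during that month.  The node set is the union of
    all actors across the whole range.
    """
    cat = catalog or default_catalog()
    events = list(events)
    if not events:
        raise ValueError("no events supplied")
    start = period_start or min(e.date for e in events)
    end = period_end or max(e.date for e in events)
    if (start.year, start.month) > (end.year, end.month):
        raise ValueError("empty date range")
    in_range = [e for e in events if start <= e.date <= end]
    if not in_range:
        raise ValueError("no events inside the requested range")
    actors = sorted({a for e in in_range for a in (e.source_actor, e.target_actor)})
    index = {a: i for i, a in enumerate(actors)}
    nu = len(actors)
    months = _month_range(start, end)
    month_idx = {ym: k for k, ym in enumerate(months)}
    lam = cat.n_layers
    # adjacency stack per (month, layer)
    stacks = np.zeros((len(months), lam, nu, nu))
    for e in in_range:
        t = month_idx[(e.date.year, e.date.month)]
        k = cat.layer_of(e.weis_code)
        if k is None:
            continue
        i, j = index[e.source_actor], index[e.target_actor]
        if i == j:
            continue
        stacks[t, k - 1, i, j] = stacks[t, k - 1, j, i] = 1.0
    labels = tuple(actors)
    layer_names = tuple(f"L{num:02d}_{code}" for num, code, _, _ in cat.entries)
    snapshots = []
    for t in range(len(months)):
        layers = tuple(Graph(stacks[t, k], labels) for k in range(lam))
        snapshots.append(MultiplexSnapshot(layers, layer_names))
    stamps = tuple(f"{y:04d}-{m:02d}" for y, m in months)
    return MultiplexSeries(tuple(snapshots), stamps)


def _select_period(
    events: list[EventRecord], period: str | tuple[date, date]
) -> list[EventRecord]:
    if isinstance(period, str):
        if period not in STANDARD_PERIODS:
            raise KeyError(
                f"unknown period {period!r}; known: {sorted(STANDARD_PERIODS)}"
            )
        start, end = STANDARD_PERIODS[period]
    else:
        start, end = period
    return [e for e in events if start <= e.date <= end]


def degree_summary(
    events: list[EventRecord],
    periods: Sequence[str | tuple[date, date]] = ("FULL",),
    top: int = 10,
) -> pd.DataFrame:
    """Actors ranked by event participation, per named period.

    Each event contributes 1 to both endpoints; percentages are over twice
    the period's event total (every event has two endpoints).
    """
    frames = []
    for period in periods:
        sel = _select_period(events, period)
        total = len(sel)
        counts: dict[str, int] = {}
        for e in sel:
            counts[e.source_actor] = counts.get(e.source_actor, 0) + 1
            counts[e.target_actor] = counts.get(e.target_actor, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
        for rank, (actor, c) in enumerate(ranked, start=1):
            frames.append(
                {
                    "period": period if isinstance(period, str) else str(period),
                    "rank": rank,
                    "actor": actor,
                    "events": c,
                    "percent": 100.0 * c / (2 * total) if total else np.nan,
                }
            )
    return pd.DataFrame(frames)


def edge_summary(
    events: list[EventRecord],
    periods: Sequence[str | tuple[date, date]] = ("FULL",),
    top: int = 10,
) -> pd.DataFrame:
    """Dyads (unordered actor pairs) ranked by event count, per period."""
    frames = []
    for period in periods:
        sel = _select_period(events, period)
        total = len(sel)
        counts: dict[tuple[str, str], int] = {}
        for e in sel:
            d = e.dyad()
            counts[d] = counts.get(d, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
        for rank, (dyad, c) in enumerate(ranked, start=1):
            frames.append(
                {
                    "period": period if isinstance(period, str) else str(period),
                    "rank": rank,
                    "dyad": f"{dyad[0]}-{dyad[1]}",
                    "events": c,
                    "percent": 100.0 * c / total if total else np.nan,
                }
            )
    return pd.DataFrame(frames)


def edge_occurrence_series(
    events: list[EventRecord],
    dyads: Sequence[tuple[str, str]],
    period_start: date | None = None,
    period_end: date | None = None,
) -> pd.DataFrame:
    """Monthly event counts for the named dyads (either direction)."""
    events = list(events)
    start = period_start or min(e.date for e in events)
    end = period_end or max(e.date for e in events)
    months = _month_range(start, end)
    month_idx = {ym: k for k, ym in enumerate(months)}
    wanted = {tuple(sorted(d)): k for k, d in enumerate(dyads)}
    counts = np.zeros((len(months), len(dyads)), dtype=int)
    for e in events:
        if not start <= e.date <= end:
            continue
        k = wanted.get(e.dyad())
        if k is not None:
            counts[month_idx[(e.date.year, e.date.month)], k] += 1
    out = pd.DataFrame(
        counts, columns=[f"{a}-{b}" for a, b in (tuple(sorted(d)) for d in dyads)]
    )
    out.insert(0, "month", [f"{y:04d}-{m:02d}" for y, m in months])
    return out
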