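"""Event-log data model: one record per ball event, plus CSV/JSON readers.

A match is notated as an ordered stream of ball events. Each event carries the
acting team, the actor's tactical position (1..11 -- substitutes inherit the
position number of the player they replace), the action type, the pitch zone
in the acting team's attack direction (1 = defensive zone ... 4 = offensive /
finishing zone), and the set-piece context that initiated the possession.

Timestamps are seconds from the start of each half, because the period
division downstream operates per half (each half is cut into three equal
fractions of its own full duration, stoppage time included).

Two on-disk representations are supported:

* ``json`` -- self-contained: match id, team ids, half durations and events.
* ``csv``  -- the event table only (comma-separated, UTF-8, header row, an
  absent receiver encoded as the empty string).  Match metadata that the CSV
  cannot carry (half durations, and team ids / match id when the event table
  is empty) is supplied to :func:`read_event_log` by the caller.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

ACTIONS = ("pass", "contact", "shot", "loss")
RESTARTS = ("open_play", "corner", "throw_in", "free_kick", "kickoff")
N_POSITIONS = 11

CSV_FIELDS = (
    "match_id",
    "half",
    "t",
    "team",
    "actor",
    "action",
    "receiver",
    "completed",
    "zone",
    "restart",
)


class SchemaError(ValueError):
    """An event log violates the schema; the message names the row and field."""


@dataclass(frozen=True)
class PassEvent:
    """One notated ball event.

    ``receiver`` is present exactly when the event is a pass completed to a
    teammate; ``completed`` is only ever true for passes.  ``zone`` is coded
    relative to the acting team's attack direction, so zone 4 is always that
    team's finishing zone.
    """

    match_id: str
    half: int
    t: float
    team: str
    actor: int
    action: str
    receiver: int | None = None
    completed: bool = False
    zone: int = 1
    restart: str = "open_play"

    def validate(self, index: int | None = None) -> None:
        where = f"event {index}" if index is not None else "event"
        if self.half not in (1, 2):
            raise SchemaError(f"{where}: field 'half' must be 1 or 2, got {self.half}")
        if not (isinstance(self.t, (int, float)) and math.isfinite(self.t) and self.t >= 0):
            raise SchemaError(f"{where}: field 't' must be a finite number >= 0, got {self.t}")
        if self.action not in ACTIONS:
            raise SchemaError(f"{where}: field 'action' must be one of {ACTIONS}, got {self.action!r}")
        if self.restart not in RESTARTS:
            raise SchemaError(f"{where}: field 'restart' must be one of {RESTARTS}, got {self.restart!r}")
        if not (isinstance(self.actor, int) and 1 <= self.actor <= N_POSITIONS):
            raise SchemaError(f"{where}: field 'actor' must be an integer in 1..11, got {self.actor}")
        if self.zone not in (1, 2, 3, 4):
            raise SchemaError(f"{where}: field 'zone' must be an integer in 1..4, got {self.zone}")
        if self.receiver is not None:
            if not (isinstance(self.receiver, int) and 1 <= self.receiver <= N_POSITIONS):
                raise SchemaError(
                    f"{where}: field 'receiver' must be an integer in 1..11, got {self.receiver}"
                )
            if self.receiver == self.actor:
                raise SchemaError(
                    f"{where}: field 'receiver' equals 'actor' ({self.actor}); "
                    "a player cannot pass to himself"
                )
        if self.completed and self.action != "pass":
            raise SchemaError(f"{where}: field 'completed' is true but action is {self.action!r}")
        if self.completed and self.receiver is None:
            raise SchemaError(f"{where}: field 'receiver' absent on a completed pass")
        if self.action in ("shot", "loss", "contact") and self.receiver is not None:
            raise SchemaError(
                f"{where}: field 'receiver' present on action {self.action!r}"
            )
        if self.action == "pass" and not self.completed and self.receiver is not None:
            raise SchemaError(f"{where}: field 'receiver' present on an incomplete pass")


@dataclass
class MatchLog:
    """A full match: two teams, two half durations, an ordered event stream."""

    match_id: str
    team_ids: tuple[str, str]
    half_durations: tuple[float, float]
    events: list[PassEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.team_ids = tuple(self.team_ids)  # type: ignore[assignment]
        self.half_durations = tuple(float(d) for d in self.half_durations)  # type: ignore[assignment]
        self.events = list(self.events)
        self.validate()

    def validate(self) -> None:
        if len(self.team_ids) != 2 or self.team_ids[0] == self.team_ids[1]:
            raise SchemaError(
                f"match {self.match_id}: 'team_ids' must hold exactly two distinct teams, "
                f"got {self.team_ids}"
            )
        if len(self.half_durations) != 2 or any(d <= 0 for d in self.half_durations):
            raise SchemaError(
                f"match {self.match_id}: 'half_durations' must be two positive durations, "
                f"got {self.half_durations}"
            )
        last_t = {1: -math.inf, 2: -math.inf}
        for i, ev in enumerate(self.events):
            ev.validate(i)
            if ev.match_id != self.match_id:
                raise SchemaError(f"event {i}: field 'match_id' {ev.match_id!r} != {self.match_id!r}")
            if ev.team not in self.team_ids:
                raise SchemaError(f"event {i}: field 'team' {ev.team!r} not in {self.team_ids}")
            if ev.t > self.half_durations[ev.half - 1]:
                raise SchemaError(
                    f"event {i}: field 't' {ev.t} exceeds half {ev.half} duration "
                    f"{self.half_durations[ev.half - 1]}"
                )
            if ev.t < last_t[ev.half]:
                raise SchemaError(
                    f"event {i}: field 't' decreases within half {ev.half} "
                    f"({ev.t} after {last_t[ev.half]})"
                )
            last_t[ev.half] = ev.t

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MatchLog):
            return NotImplemented
        return (
            self.match_id == other.match_id
            and tuple(self.team_ids) == tuple(other.team_ids)
            and tuple(self.half_durations) == tuple(other.half_durations)
            and self.events == other.events
        )


def _event_to_row(ev: PassEvent) -> dict[str, str]:
    return {
        "match_id": ev.match_id,
        "half": str(ev.half),
        "t": repr(float(ev.t)),
        "team": ev.team,
        "actor": str(ev.actor),
        "action": ev.action,
        "receiver": "" if ev.receiver is None else str(ev.receiver),
        "completed": "true" if ev.completed else "false",
        "zone": str(ev.zone),
        "restart": ev.restart,
    }


def _row_to_event(row: dict[str, str], index: int) -> PassEvent:
    def intfield(name: str) -> int:
        try:
            return int(row[name])
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"row {index}: field {name!r} is not an integer: {row.get(name)!r}") from exc

    missing = [f for f in CSV_FIELDS if f not in row or row[f] is None]
    if missing:
        raise SchemaError(f"row {index}: missing fields {missing}")
    try:
        t = float(row["t"])
    except ValueError as exc:
        raise SchemaError(f"row {index}: field 't' is not a number: {row['t']!r}") from exc
    completed_raw = str(row["completed"]).strip().lower()
    if completed_raw not in ("true", "false", "0", "1"):
        raise SchemaError(f"row {index}: field 'completed' must be boolean, got {row['completed']!r}")
    receiver_raw = row["receiver"]
    receiver = None if receiver_raw in ("", None) else intfield("receiver")
    ev = PassEvent(
        match_id=str(row["match_id"]),
        half=intfield("half"),
        t=t,
        team=str(row["team"]),
        actor=intfield("actor"),
        action=str(row["action"]),
        receiver=receiver,
        completed=completed_raw in ("true", "1"),
        zone=intfield("zone"),
        restart=str(row["restart"]),
    )
    try:
        ev.validate(index)
    except SchemaError as exc:
        raise SchemaError(f"row {index}: {exc}") from exc
    return ev


def write_event_log(log: MatchLog, path: str | Path, format: str = "csv") -> None:
    """Write a MatchLog to ``path`` as ``csv`` (event table) or ``json``.

    The JSON form is self-contained and round-trips losslessly.  The CSV form
    is the event table only; an empty log yields a header-only file.
    """
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
            writer.writeheader()
            for ev in log.events:
                writer.writerow(_event_to_row(ev))
    elif format == "json":
        payload = {
            "match_id": log.match_id,
            "team_ids": list(log.team_ids),
            "half_durations": list(log.half_durations),
            "events": [_event_to_row(ev) for ev in log.events],
        }
        with path.open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def read_event_log(
    path: str | Path,
    format: str = "csv",
    *,
    match_id: str | None = None,
    team_ids: Sequence[str] | None = None,
    half_durations: Sequence[float] | None = None,
) -> MatchLog:
    """Read and validate a MatchLog.

    For ``json`` the file is self-contained and the keyword metadata must not
    be supplied.  For ``csv`` the metadata the event table cannot carry is
    taken from the keywords; when omitted, match id and team ids are inferred
    from the rows and each half's duration defaults to its last timestamp
    (adequate for inspection, not for a lossless round trip).
    """
    path = Path(path)
    if format == "json":
        with path.open("r", encoding="utf-8") as fh:
            payload = json.load(fh)
        for key in ("match_id", "team_ids", "half_durations", "events"):
            if key not in payload:
                raise SchemaError(f"json log missing key {key!r}")
        events = [_row_to_event(row, i) for i, row in enumerate(payload["events"])]
        return MatchLog(
            match_id=str(payload["match_id"]),
            team_ids=tuple(payload["team_ids"]),
            half_durations=tuple(payload["half_durations"]),
            events=events,
        )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")

    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != list(CSV_FIELDS):
            raise SchemaError(
                f"csv header mismatch: expected {list(CSV_FIELDS)}, got {reader.fieldnames}"
            )
        events = [_row_to_event(row, i) for i, row in enumerate(reader)]

    if match_id is None:
        mids = {ev.match_id for ev in events}
        if len(mids) != 1:
            raise SchemaError(
                "csv log: cannot infer match_id "
                f"({len(mids)} distinct ids in rows); pass match_id="
            )
        match_id = mids.pop()
    if team_ids is None:
        teams = sorted({ev.team for ev in events})
        if len(teams) != 2:
            raise SchemaError(
                f"csv log: cannot infer team_ids ({len(teams)} teams in rows); pass team_ids="
            )
        team_ids = teams
    if half_durations is None:
        half_durations = tuple(
            max([ev.t for ev in events if ev.half == h], default=1.0) or 1.0 for h in (1, 2)
        )
    return MatchLog(
        match_id=match_id,
        team_ids=tuple(team_ids),
        half_durations=tuple(half_durations),
        events=events,
    )


def events_to_dataframe(events: Iterable[PassEvent]):
    """Event list as a pandas DataFrame (one row per event), for audit/export."""
    import pandas as pd

    rows = [_event_to_row(ev) for ev in events]
    df = pd.DataFrame(rows, columns=CSV_FIELDS)
    if len(df):
        df["half"] = df["half"].astype(int)
        df["t"] = df["t"].astype(float)
        df["actor"] = df["actor"].astype(int)
        df["zone"] = df["zone"].astype(int)
        df["completed"] = df["completed"] == "true"
    return df
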