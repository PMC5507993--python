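"""Segmentation of an event stream into offensive plays.

An offensive play is the maximal attacking sequence of one team between
gaining and losing ball possession.  Operationally a play starts at the first
completed pass of a possession (a team is considered in possession once it
completes a pass and keeps the ball afterwards; the broader notational
criterion -- at least two consecutive contacts with the ball, a positive pass,
or a shot -- is noted here but the completed pass is the start condition used
throughout) and ends at a loss of possession (loss event or incomplete pass),
a shot, the opponent's first completed pass, or the half-time whistle.

Plays are classified as:

* ``SOP``  -- successful: the play contains a shot at goal, or the team held
  possession during an event located in the finishing zone (zone 4).
* ``neutral`` -- set-piece initiated plays whose finishing-zone access is not
  earned in open play (first event from a corner kick or throw-in, or a free
  kick whose first pass is received directly in zone 4) and that do not end in
  a shot; also plays truncated by the half-time whistle with possession
  retained and no success criterion met.  Neutral plays are excluded from the
  network analysis.
* ``UOP``  -- unsuccessful: possession lost without meeting a success
  criterion.

Each play is assigned to one of six equal-duration match periods (three per
half, computed on that half's own full duration so unequal stoppage times are
respected).  A play belongs to the period containing its first event; period
boundaries are half-open [lower, upper) except the final fraction, which is
closed at the half's end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from passnet.event_model import MatchLog, PassEvent

CATEGORIES = ("SOP", "UOP", "neutral")


@dataclass
class OffensivePlay:
    """A maximal same-team possession sequence and its classification."""

    match_id: str
    team: str
    events: list[PassEvent]
    category: str | None = None
    period: int | None = None
    #: global indexes of the play's events in the source log (for audit)
    event_indices: list[int] = field(default_factory=list)
    #: true when the play was cut by the half-time whistle with the ball kept
    truncated: bool = False

    @property
    def n_passes(self) -> int:
        return sum(1 for ev in self.events if ev.action == "pass" and ev.completed)

    @property
    def half(self) -> int:
        return self.events[0].half

    @property
    def restart(self) -> str:
        return self.events[0].restart


def _is_completed_pass(ev: PassEvent) -> bool:
    return ev.action == "pass" and ev.completed


def _is_terminal(ev: PassEvent) -> bool:
    # events after which the acting team no longer holds the ball
    return ev.action in ("shot", "loss") or (ev.action == "pass" and not ev.completed)


def segment_possessions(log: MatchLog) -> list[OffensivePlay]:
    """Cut the event stream into uncategorized offensive plays.

    Every completed pass belongs to exactly one play.  Leading events of a
    possession before its first completed pass (e.g. a lone incomplete pass)
    start no play.  Plays open at the half-time whistle are closed with
    ``truncated=True``.
    """
    plays: list[OffensivePlay] = []
    current: OffensivePlay | None = None

    def close(truncated: bool = False) -> None:
        nonlocal current
        if current is not None:
            current.truncated = truncated
            plays.append(current)
            current = None

    last_half: int | None = None
    for i, ev in enumerate(log.events):
        if last_half is not None and ev.half != last_half:
            close(truncated=True)
        last_half = ev.half
        if current is not None and ev.team != current.team:
            # opponent acts: possession changed hands without an explicit
            # terminal event in the stream
            close()
        if current is None:
            if _is_completed_pass(ev):
                current = OffensivePlay(
                    match_id=log.match_id, team=ev.team, events=[ev], event_indices=[i]
                )
                if _is_terminal(ev):  # unreachable for a completed pass; kept for clarity
                    close()
            continue
        current.events.append(ev)
        current.event_indices.append(i)
        if _is_terminal(ev):
            close()
    close(truncated=True)
    return plays


def categorize_play(play: OffensivePlay) -> str:
    """Classify one segmented play as SOP, UOP or neutral.

    Order of the checks: a shot always makes the play successful; otherwise
    set-piece screens (corner, throw-in, free kick delivered straight into the
    finishing zone) make it neutral before the zone criterion is consulted, so
    finishing-zone entries granted by the set piece itself do not count as
    earned entries; otherwise any possession-held event in zone 4 makes it
    successful; a whistle-truncated play with the ball kept is neutral; all
    remaining plays lost possession and are unsuccessful.
    """
    has_shot = any(ev.action == "shot" for ev in play.events)
    if has_shot:
        play.category = "SOP"
        return play.category

    restart = play.restart
    if restart in ("corner", "throw_in"):
        play.category = "neutral"
        return play.category
    if restart == "free_kick" and len(play.events) > 1 and play.events[1].zone == 4:
        # first pass of the free kick received directly in the finishing zone
        play.category = "neutral"
        return play.category

    entered_zone4 = any(ev.zone == 4 and ev.action != "loss" for ev in play.events)
    if entered_zone4:
        play.category = "SOP"
    elif play.truncated and not _is_terminal(play.events[-1]):
        play.category = "neutral"
    else:
        play.category = "UOP"
    return play.category


def period_of_time(t: float, half: int, half_durations: tuple[float, float]) -> int:
    """Period (1..6) containing time ``t`` of the given half.

    Each half is divided into three fractions of equal duration; fraction
    boundaries are half-open [lower, upper), the last fraction closed at the
    half's end.  Only the relative position within the half matters, so the
    assignment is invariant to uniform time rescaling.
    """
    duration = float(half_durations[half - 1])
    t = float(t)
    if t > duration:
        raise ValueError(f"time t={t} exceeds half {half} duration {duration}")
    fraction = min(int(3.0 * t / duration), 2)
    return 3 * (half - 1) + fraction + 1


def assign_period(play: OffensivePlay, half_durations: tuple[float, float]) -> int:
    """Period (1..6) containing the play's first event (see period_of_time)."""
    first = play.events[0]
    play.period = period_of_time(first.t, first.half, half_durations)
    return play.period


def filter_plays(plays: list[OffensivePlay]) -> tuple[list[OffensivePlay], list[OffensivePlay]]:
    """Drop neutral plays; return the (SOP, UOP) partition."""
    for p in plays:
        if p.category not in CATEGORIES:
            raise ValueError("filter_plays requires categorized plays")
    sops = [p for p in plays if p.category == "SOP"]
    uops = [p for p in plays if p.category == "UOP"]
    return sops, uops


def segment_and_categorize(log: MatchLog) -> list[OffensivePlay]:
    """Full front end: segment, categorize and period-assign a match log."""
    plays = segment_possessions(log)
    for play in plays:
        categorize_play(play)
        assign_period(play, log.half_durations)
    return plays


def plays_to_dataframe(plays: list[OffensivePlay]):
    """One audit row per play: match, team, period, category, n_passes."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "match_id": p.match_id,
                "team": p.team,
                "half": p.half,
                "period": p.period,
                "category": p.category,
                "n_passes": p.n_passes,
                "restart": p.restart,
                "t_start": p.events[0].t,
            }
            for p in plays
        ],
        columns=[
            "match_id",
            "team",
            "half",
            "period",
            "category",
            "n_passes",
            "restart",
            "t_start",
        ],
    )
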