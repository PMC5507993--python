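"""Possession-chain match simulator with a planted success model.

The generator emulates the statistical structure the downstream analysis
assumes, standing in for hand-notated broadcast footage:

* two teams of 11 tactical positions alternating possessions through two
  halves of ~45 min plus a uniform stoppage draw, so the six equal-duration
  match periods have genuinely unequal lengths across halves;
* each possession is a chain of passes -- completion and continuation are
  Bernoulli draws, the receiver of every pass is drawn from the passing
  team's preference matrix (one symmetric-Dirichlet row per passer, drawn
  once per team per match).  The Dirichlet concentration is the single dial
  for link diversity: a small concentration piles probability on few
  receivers, so passes reuse the same ordered pairs and network density
  stays low; a large concentration spreads passes over many distinct pairs
  and density rises, independently of pass volume;
* pitch zones progress toward the finishing zone (zone 4); set-piece starts
  (corner, throw-in, free kick) occur at a configurable rate, and corner or
  throw-in possessions are rendered without shots so they land in the
  neutral category that the analysis discards;
* play success is planted at the network level: for every (team, period)
  cell the cell's total passes and pooled-link density determine a logistic
  success probability, and each of the cell's open-play possessions is
  independently designated successful (rendered to enter zone 4 or finish
  with a shot) or unsuccessful (capped at zone 3, ending in a loss) with
  that probability.  With ``success_model=None`` the generator runs in
  natural mode instead: zones advance stochastically all the way to zone 4
  and success emerges from the chain dynamics alone.

Every draw flows from one ``numpy`` Generator seeded by (seed, match index),
so the same parameters reproduce a byte-identical event log.  A ground-truth
channel records each play's boundaries, category and cell, the planted
success probabilities, and the per-cell pass tallies, for oracle testing of
the segmentation and regression stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from passnet.event_model import MatchLog, PassEvent, N_POSITIONS
from passnet.network_builder import build_networks
from passnet.network_metrics import MAX_LINKS, compute_cases
from passnet.play_segmentation import OffensivePlay, categorize_play, period_of_time

from scipy.special import expit


@dataclass
class SimParams:
    """Generator settings; defaults are the study conditions of the pipeline.

    ``mean_possessions_per_period`` counts both teams' possessions in one
    sixth of the match.  ``success_model`` holds the planted logit
    coefficients (a, b_total_passes, c_density10) applied to each (team,
    period) cell's total passes and pooled density on the 0..10 scale; set
    it to ``None`` for natural (unplanted) dynamics.
    """

    seed: int = 0
    n_matches: int = 12
    half_duration: float = 2700.0
    stoppage_range: tuple[float, float] = (60.0, 300.0)
    mean_possessions_per_period: float = 20.0
    pass_continue_prob: float = 0.85
    pass_complete_prob: float = 0.85
    preference_concentration: float = 1.0
    zone_advance_prob: float = 0.35
    shot_prob_in_z4: float = 0.4
    set_piece_rate: float = 0.10
    success_model: tuple[float, float, float] | None = (0.4, 0.05, -1.1)

    def validate(self) -> None:
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError(f"seed must be a nonnegative integer, got {self.seed}")
        if not (isinstance(self.n_matches, (int, np.integer)) and self.n_matches >= 1):
            raise ValueError(f"n_matches must be >= 1, got {self.n_matches}")
        if self.half_duration <= 0:
            raise ValueError("half_duration must be positive")
        lo, hi = self.stoppage_range
        if not (0 <= lo <= hi):
            raise ValueError(f"stoppage_range must satisfy 0 <= lo <= hi, got {self.stoppage_range}")
        if self.mean_possessions_per_period <= 0:
            raise ValueError("mean_possessions_per_period must be positive")
        for name in ("pass_continue_prob", "pass_complete_prob", "zone_advance_prob", "shot_prob_in_z4"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0 or v == 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 <= self.set_piece_rate < 1.0):
            raise ValueError(f"set_piece_rate must be in [0, 1), got {self.set_piece_rate}")
        if self.preference_concentration <= 0:
            raise ValueError("preference_concentration must be positive")
        if self.success_model is not None and len(self.success_model) != 3:
            raise ValueError("success_model must be (a, b_total_passes, c_density10) or None")


@dataclass
class PlayTruth:
    """Ground truth for one simulated play (possession with >= 1 completed pass)."""

    team: str
    half: int
    period: int
    category: str
    n_passes: int
    first_index: int
    last_index: int
    restart: str
    planted_success: bool | None


@dataclass
class GroundTruth:
    """Oracle channel emitted alongside each simulated match log."""

    match_id: str
    plays: list[PlayTruth] = field(default_factory=list)
    #: planted per-cell success probability, keyed by (team, period)
    planted_p: dict = field(default_factory=dict)
    #: possession slots drawn, including those whose first pass failed
    slot_count: int = 0

    @property
    def possession_count(self) -> int:
        """Possessions that produced a play (at least one completed pass)."""
        return len(self.plays)

    def cell_pass_tally(self) -> dict:
        """Completed passes per (team, period, category) cell."""
        tally: dict = {}
        for p in self.plays:
            key = (p.team, p.period, p.category)
            tally[key] = tally.get(key, 0) + p.n_passes
        return tally


@dataclass
class _Skeleton:
    """Phase-A draw for one possession slot: who passes to whom, and how it stops."""

    team: str
    half: int
    slot_start: float
    slot_len: float
    period: int
    restart: str
    start_zone: int
    chain: list[tuple[int, int]]  # completed (passer, receiver) pairs
    stop: str  # "retained" | "incomplete"
    fail_actor: int  # actor of the incomplete attempt when stop == "incomplete"
    designated: bool | None = None  # planted success designation (pool plays only)


def _draw_preferences(rng: np.random.Generator, concentration: float) -> np.ndarray:
    """11 x 11 receiver-preference matrix: Dirichlet row over the 10 teammates."""
    pref = np.zeros((N_POSITIONS, N_POSITIONS))
    alpha = np.full(N_POSITIONS - 1, concentration)
    for i in range(N_POSITIONS):
        probs = rng.dirichlet(alpha)
        others = [j for j in range(N_POSITIONS) if j != i]
        pref[i, others] = probs
    return pref


def _draw_skeleton(
    rng: np.random.Generator,
    params: SimParams,
    pref: np.ndarray,
) -> tuple[list[tuple[int, int]], str, int]:
    """Draw the completed-pass chain and its stop mode for one possession."""
    chain: list[tuple[int, int]] = []
    actor = int(rng.integers(1, N_POSITIONS + 1))
    while True:
        receiver = int(rng.choice(N_POSITIONS, p=pref[actor - 1])) + 1
        if rng.random() >= params.pass_complete_prob:
            return chain, "incomplete", actor
        chain.append((actor, receiver))
        actor = receiver
        if rng.random() >= params.pass_continue_prob:
            return chain, "retained", actor


def _start_zone(rng: np.random.Generator, restart: str) -> int:
    if restart == "kickoff":
        return 2
    if restart == "corner":
        return 4
    if restart == "throw_in":
        return int(rng.choice([2, 3]))
    if restart == "free_kick":
        return int(rng.choice([1, 2, 3]))
    return int(rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2]))


def simulate_match(params: SimParams, match_index: int = 0) -> tuple[MatchLog, GroundTruth]:
    """Simulate one match; returns the event log and its ground truth.

    Possessions alternate between the two teams in consecutive time slots;
    the per-half slot count is Poisson with mean three times
    ``mean_possessions_per_period``.  See the module docstring for the
    planted-success mechanism.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), int(match_index)]))
    match_id = f"M{match_index:03d}"
    teams = ("home", "away")
    half_durations = tuple(
        params.half_duration + rng.uniform(*params.stoppage_range) for _ in range(2)
    )
    pref = {team: _draw_preferences(rng, params.preference_concentration) for team in teams}

    # ---- phase A: skeletons -------------------------------------------------
    skeletons: list[_Skeleton] = []
    for half in (1, 2):
        dur = half_durations[half - 1]
        n_slots = max(1, int(rng.poisson(3.0 * params.mean_possessions_per_period)))
        slot_len = dur / n_slots
        first_team = 0 if half == 1 else 1
        for s in range(n_slots):
            team = teams[(first_team + s) % 2]
            if s == 0:
                restart = "kickoff"
            elif rng.random() < params.set_piece_rate:
                restart = str(rng.choice(["corner", "throw_in", "free_kick"]))
            else:
                restart = "open_play"
            chain, stop, fail_actor = _draw_skeleton(rng, params, pref[team])
            slot_start = s * slot_len
            skeletons.append(
                _Skeleton(
                    team=team,
                    half=half,
                    slot_start=slot_start,
                    slot_len=slot_len,
                    period=period_of_time(slot_start, half, half_durations),
                    restart=restart,
                    start_zone=_start_zone(rng, restart),
                    chain=chain,
                    stop=stop,
                    fail_actor=fail_actor,
                )
            )

    # ---- phase B: plant success per (team, period) cell ---------------------
    planted_p: dict = {}
    if params.success_model is not None:
        a, b_total, c_density10 = params.success_model
        pool: dict = {}
        for sk in skeletons:
            if sk.restart not in ("corner", "throw_in") and sk.chain:
                pool.setdefault((sk.team, sk.period), []).append(sk)
        for (team, period), cell in pool.items():
            total = sum(len(sk.chain) for sk in cell)
            links = {pair for sk in cell for pair in sk.chain}
            density10 = 10.0 * len(links) / MAX_LINKS
            p = float(expit(a + b_total * total + c_density10 * density10))
            planted_p[(team, period)] = p
            for sk in cell:
                sk.designated = bool(rng.random() < p)

    # ---- phase C: render events ---------------------------------------------
    events: list[PassEvent] = []
    gt = GroundTruth(match_id=match_id, planted_p=planted_p, slot_count=len(skeletons))

    def emit(half, times, team, actor, action, receiver, completed, zone, restart):
        events.append(
            PassEvent(
                match_id=match_id,
                half=half,
                t=times.pop(0),
                team=team,
                actor=actor,
                action=action,
                receiver=receiver,
                completed=completed,
                zone=zone,
                restart=restart,
            )
        )

    for sk in skeletons:
        first_index = len(events)
        if not sk.chain:
            # a possession whose very first pass failed: one event, no play
            times = [sk.slot_start]
            emit(sk.half, times, sk.team, sk.fail_actor, "pass", None, False, sk.start_zone, sk.restart)
            continue

        neutral_render = sk.restart in ("corner", "throw_in")
        planted = params.success_model is not None and not neutral_render
        # zone ceiling during the chain: planted plays stay below zone 4 and
        # earn it (or not) at the terminal; neutral corner plays sit in zone 4
        zone_cap = 3 if planted else 4
        z = min(sk.start_zone, zone_cap) if planted else sk.start_zone

        seq: list[tuple] = []  # (actor, action, receiver, completed, zone)
        shot_fired = False
        for k, (passer, receiver) in enumerate(sk.chain):
            seq.append((passer, "pass", receiver, True, z))
            if rng.random() < params.zone_advance_prob:
                z = min(z + 1, zone_cap)
            if not planted and not neutral_render and z == 4:
                if rng.random() < params.shot_prob_in_z4:
                    seq.append((receiver, "shot", None, False, 4))
                    shot_fired = True
                    break
        holder = sk.chain[len([s for s in seq if s[1] == "pass"]) - 1][1]

        if shot_fired:
            pass
        elif planted and sk.designated:
            # successful: enter the finishing zone, shoot or hold then lose it
            if params.success_model is not None and sk.restart == "free_kick" and len(sk.chain) == 1:
                # a one-pass free kick must finish with a shot: a quiet
                # zone-4 touch straight from the kick would be a set-piece
                # delivery, not an earned entry
                seq.append((holder, "shot", None, False, 4))
            elif rng.random() < params.shot_prob_in_z4:
                seq.append((holder, "shot", None, False, 4))
            else:
                seq.append((holder, "contact", None, False, 4))
                seq.append((holder, "loss", None, False, 4))
        elif planted and not sk.designated:
            if sk.stop == "incomplete":
                seq.append((sk.fail_actor, "pass", None, False, min(z, 3)))
            else:
                seq.append((holder, "loss", None, False, min(z, 3)))
        else:
            # neutral renders and natural mode share plain terminals
            if neutral_render or sk.stop == "incomplete":
                if sk.stop == "incomplete":
                    seq.append((sk.fail_actor, "pass", None, False, z))
                else:
                    seq.append((holder, "loss", None, False, z))
            else:
                # natural mode, ball retained: the holder dribbles on, zones
                # advancing, until the finishing zone or a loss (hazard is the
                # pass-failure rate); bounded for pathological settings
                for _ in range(50):
                    if z == 4:
                        break
                    if rng.random() >= params.pass_complete_prob:
                        break
                    if rng.random() < params.zone_advance_prob:
                        z = min(z + 1, 4)
                    seq.append((holder, "contact", None, False, z))
                if z == 4:
                    if rng.random() < params.shot_prob_in_z4:
                        seq.append((holder, "shot", None, False, 4))
                    else:
                        # controlled the ball in the finishing zone, then lost it
                        seq.append((holder, "contact", None, False, 4))
                        seq.append((holder, "loss", None, False, 4))
                else:
                    seq.append((holder, "loss", None, False, z))

        dt = sk.slot_len / (len(seq) + 1)
        times = [sk.slot_start + k * dt for k in range(len(seq))]
        for actor, action, receiver, completed, zone in seq:
            emit(sk.half, times, sk.team, actor, action, receiver, completed, zone, sk.restart)

        last_index = len(events) - 1
        play = OffensivePlay(
            match_id=match_id,
            team=sk.team,
            events=events[first_index : last_index + 1],
            event_indices=list(range(first_index, last_index + 1)),
        )
        category = categorize_play(play)
        if planted and sk.designated is not None:
            want = "SOP" if sk.designated else "UOP"
            if category != want:
                raise RuntimeError(
                    f"rendering bug: designated {want} play categorized as {category}"
                )
        gt.plays.append(
            PlayTruth(
                team=sk.team,
                half=sk.half,
                period=sk.period,
                category=category,
                n_passes=play.n_passes,
                first_index=first_index,
                last_index=last_index,
                restart=sk.restart,
                planted_success=sk.designated,
            )
        )

    log = MatchLog(
        match_id=match_id,
        team_ids=teams,
        half_durations=half_durations,
        events=events,
    )
    return log, gt


def ground_truth_case_table(log: MatchLog, gt: GroundTruth) -> pd.DataFrame:
    """The 24 network cases of one match, built from ground-truth play slices.

    This bypasses segmentation entirely: plays are reconstructed from the
    simulator's recorded event index ranges, so the table is the oracle the
    pipeline output is compared against.
    """
    plays = []
    for pt in gt.plays:
        if pt.category == "neutral":
            continue
        play = OffensivePlay(
            match_id=log.match_id,
            team=pt.team,
            events=log.events[pt.first_index : pt.last_index + 1],
            category=pt.category,
            period=pt.period,
        )
        plays.append(play)
    nets = build_networks(plays, team_ids=log.team_ids)
    cases = compute_cases(nets)
    cases["planted_p"] = [
        gt.planted_p.get((team, period), np.nan)
        for team, period in zip(cases["team"], cases["period"])
    ]
    return cases


def simulate_study(params: SimParams) -> tuple[list[MatchLog], pd.DataFrame]:
    """Simulate ``params.n_matches`` matches and assemble the case table.

    Returns the match logs and the concatenated ground-truth NetworkCase
    table (24 rows per match, so 288 pre-screening cases for a 12-match
    study).
    """
    params.validate()
    logs: list[MatchLog] = []
    tables = []
    for m in range(params.n_matches):
        log, gt = simulate_match(params, match_index=m)
        logs.append(log)
        tables.append(ground_truth_case_table(log, gt))
    cases = pd.concat(tables, ignore_index=True)
    return logs, cases


def simulate_network_cases(
    n: int,
    coef: tuple[float, float, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Network-level cases drawn directly from a known logistic model.

    Covariates: ``total_passes`` ~ Poisson(20), ``density10`` ~ Uniform(0.5,
    3.5); outcome ~ Bernoulli(expit(a + b total_passes + c density10)).
    Used for parameter-recovery and calibration checks of the regression
    engine, independent of the match simulator.
    """
    a, b, c = coef
    rng = np.random.default_rng(seed)
    total = rng.poisson(20.0, size=n).astype(float)
    density10 = rng.uniform(0.5, 3.5, size=n)
    p = expit(a + b * total + c * density10)
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {"outcome": y, "total_passes": total, "density10": density10, "planted_p": p}
    )


def density_dial_check(
    params: SimParams, levels: list[float], n_matches: int | None = None
) -> tuple[pd.DataFrame, bool]:
    """Mean realized network density at each preference-concentration level.

    Simulates ``n_matches`` matches per level (default: ``params.n_matches``)
    and averages density over the nonempty per-cell networks.  Returns the
    level table (mean, standard error, cell count) and whether the means are
    non-decreasing in concentration within Monte-Carlo tolerance: a decrease
    between adjacent levels is tolerated when it is smaller than twice the
    standard error of the difference (the dial's response saturates at high
    concentration, where sampling noise dominates the tiny true increments).
    """
    if len(levels) < 3:
        raise ValueError("need at least 3 concentration levels")
    rows = []
    n_m = params.n_matches if n_matches is None else n_matches
    for level in sorted(levels):
        p = dataclasses.replace(params, preference_concentration=float(level), n_matches=n_m)
        _, cases = simulate_study(p)
        d = cases.loc[cases["total_passes"] > 0, "density"]
        rows.append(
            {
                "concentration": float(level),
                "mean_density": float(d.mean()),
                "se": float(d.std(ddof=1) / np.sqrt(len(d))),
                "n_networks": int(len(d)),
            }
        )
    table = pd.DataFrame(rows)
    monotone = True
    for i in range(1, len(table)):
        drop = table.loc[i - 1, "mean_density"] - table.loc[i, "mean_density"]
        tol = 2.0 * float(np.hypot(table.loc[i - 1, "se"], table.loc[i, "se"]))
        if drop > tol:
            monotone = False
    return table, monotone
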