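"""Aggregation of categorized plays into 24 directed passing networks.

Every match yields exactly 24 networks: one per combination of the six match
periods, the two teams, and the two retained outcome categories (SOP, UOP).
Cells without plays are materialized as all-zero networks so the 24-per-match
contract is structural; downstream screening drops zero-pass successful
networks, mirroring how empty cells are handled in the regression.

The node set is always the full 11 tactical positions, whether or not a
position touched the ball in a cell: the metric denominators use n = 11
throughout.  A link is a unique ordered passer-to-receiver pair with at least
one completed pass (binary, directed); the weight matrix keeps the full pass
counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from passnet.event_model import N_POSITIONS
from passnet.play_segmentation import OffensivePlay

EXPORT_FORMATS = ("edgelist", "graphml", "adjacency")


@dataclass
class PassNetwork:
    """An 11-node directed passing network for one (match, period, team, category) cell."""

    match_id: str
    team: str
    period: int
    category: str
    weight: np.ndarray = field(default_factory=lambda: np.zeros((N_POSITIONS, N_POSITIONS), dtype=int))

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=int)
        if self.weight.shape != (N_POSITIONS, N_POSITIONS):
            raise ValueError(f"weight matrix must be 11x11, got {self.weight.shape}")
        if (self.weight < 0).any():
            raise ValueError("weight matrix must be nonnegative")
        if np.diagonal(self.weight).any():
            raise ValueError("weight matrix has nonzero diagonal (self-passes are impossible)")
        if self.category not in ("SOP", "UOP"):
            raise ValueError(f"category must be SOP or UOP, got {self.category!r}")
        if not 1 <= int(self.period) <= 6:
            raise ValueError(f"period must be in 1..6, got {self.period}")

    @property
    def n_nodes(self) -> int:
        return N_POSITIONS

    @property
    def link(self) -> np.ndarray:
        """Binary adjacency: link[i, j] = 1 iff at least one pass i+1 -> j+1."""
        return (self.weight > 0).astype(int)

    @property
    def total_passes(self) -> int:
        return int(self.weight.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PassNetwork):
            return NotImplemented
        return (
            self.match_id == other.match_id
            and self.team == other.team
            and self.period == other.period
            and self.category == other.category
            and np.array_equal(self.weight, other.weight)
        )


def build_networks(
    plays: list[OffensivePlay],
    team_ids: tuple[str, str] | None = None,
) -> list[PassNetwork]:
    """Build the 24 per-match networks from one match's categorized plays.

    ``plays`` must all belong to one match and contain no neutral plays (drop
    them with :func:`passnet.play_segmentation.filter_plays` first).  When
    ``team_ids`` is omitted it is inferred from the plays, which requires both
    teams to appear.  Each completed pass of each play increments exactly one
    weight cell of exactly one network.
    """
    match_ids = {p.match_id for p in plays}
    if len(match_ids) > 1:
        raise ValueError(f"plays span {len(match_ids)} matches; build one match at a time")
    match_id = match_ids.pop() if match_ids else "empty"

    for p in plays:
        if p.category == "neutral":
            raise ValueError("neutral plays must be removed before building networks")
        if p.category not in ("SOP", "UOP"):
            raise ValueError("plays must be categorized before building networks")
        if p.period is None:
            raise ValueError("plays must have assigned periods before building networks")

    if team_ids is None:
        teams = tuple(sorted({p.team for p in plays}))
        if len(teams) != 2:
            raise ValueError(
                f"cannot infer team ids from plays ({len(teams)} teams present); pass team_ids="
            )
        team_ids = teams  # type: ignore[assignment]

    nets: dict[tuple[int, str, str], PassNetwork] = {}
    for period in range(1, 7):
        for team in team_ids:
            for category in ("SOP", "UOP"):
                nets[(period, team, category)] = PassNetwork(
                    match_id=match_id, team=team, period=period, category=category
                )
    for p in plays:
        key = (p.period, p.team, p.category)
        if key not in nets:
            raise ValueError(f"play team {p.team!r} not in team_ids {team_ids}")
        w = nets[key].weight
        for ev in p.events:
            if ev.action == "pass" and ev.completed:
                w[ev.actor - 1, ev.receiver - 1] += 1
    return list(nets.values())


def export_network(net: PassNetwork, path: str | Path, format: str = "edgelist") -> None:
    """Write one network as edge-list CSV, GraphML, or 11x11 adjacency CSV.

    All three are lossless for the weight matrix; GraphML additionally carries
    the cell metadata (match, team, period, category) as graph attributes and
    the pass count as the ``weight`` edge attribute.
    """
    path = Path(path)
    if format == "edgelist":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for i in range(N_POSITIONS):
                for j in range(N_POSITIONS):
                    if net.weight[i, j]:
                        writer.writerow([i + 1, j + 1, int(net.weight[i, j])])
    elif format == "adjacency":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            for i in range(N_POSITIONS):
                writer.writerow([int(x) for x in net.weight[i]])
    elif format == "graphml":
        import networkx as nx

        g = nx.DiGraph(
            match_id=net.match_id,
            team=net.team,
            period=int(net.period),
            category=net.category,
        )
        g.add_nodes_from(range(1, N_POSITIONS + 1))
        for i in range(N_POSITIONS):
            for j in range(N_POSITIONS):
                if net.weight[i, j]:
                    g.add_edge(i + 1, j + 1, weight=int(net.weight[i, j]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}; expected one of {EXPORT_FORMATS}")


def import_network(
    path: str | Path,
    format: str = "edgelist",
    *,
    match_id: str = "imported",
    team: str = "imported",
    period: int = 1,
    category: str = "UOP",
) -> PassNetwork:
    """Read a network written by :func:`export_network`.

    The CSV formats carry the weight matrix only, so cell metadata must be
    supplied by the caller; GraphML restores it from graph attributes.
    """
    path = Path(path)
    weight = np.zeros((N_POSITIONS, N_POSITIONS), dtype=int)
    if format == "edgelist":
        with path.open("r", newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header != ["source", "target", "weight"]:
                raise ValueError(f"bad edge-list header {header}")
            for row in reader:
                i, j, w = int(row[0]), int(row[1]), int(row[2])
                weight[i - 1, j - 1] = w
    elif format == "adjacency":
        with path.open("r", newline="", encoding="utf-8") as fh:
            rows = [[int(x) for x in row] for row in csv.reader(fh) if row]
        weight = np.asarray(rows, dtype=int)
    elif format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        for u, v, data in g.edges(data=True):
            weight[int(u) - 1, int(v) - 1] = int(data.get("weight", 1))
        meta = g.graph
        match_id = str(meta.get("match_id", match_id))
        team = str(meta.get("team", team))
        period = int(meta.get("period", period))
        category = str(meta.get("category", category))
    else:
        raise ValueError(f"unknown export format {format!r}; expected one of {EXPORT_FORMATS}")
    return PassNetwork(match_id=match_id, team=team, period=period, category=category, weight=weight)
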