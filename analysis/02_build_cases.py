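#!/usr/bin/env python
"""Segment the simulated logs into plays and build the 24 networks per match.

Reads the JSON event logs written by 01_simulate_study.py, segments each
into offensive plays, classifies them (successful / unsuccessful / neutral),
drops the neutral plays, aggregates the rest into the 6 x 2 x 2 passing
networks of each match, computes density, average clustering and degree
centralization, and writes one regression case per network to
results/cases.csv.  A per-play audit table goes to results/plays.csv and the
first match's networks are exported as GraphML under results/networks/.
"""

from pathlib import Path

import pandas as pd

from passnet import (
    build_networks,
    compute_cases,
    export_network,
    filter_plays,
    read_event_log,
    segment_and_categorize,
)
from passnet.play_segmentation import plays_to_dataframe

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    paths = sorted((RESULTS / "event_logs").glob("M*.json"))
    if not paths:
        raise SystemExit("no event logs found; run analysis/01_simulate_study.py first")

    all_cases, all_plays, n_neutral = [], [], 0
    netdir = RESULTS / "networks"
    netdir.mkdir(parents=True, exist_ok=True)
    for k, path in enumerate(paths):
        log = read_event_log(path, format="json")
        plays = segment_and_categorize(log)
        sops, uops = filter_plays(plays)
        n_neutral += len(plays) - len(sops) - len(uops)
        nets = build_networks(sops + uops, team_ids=log.team_ids)
        all_cases.append(compute_cases(nets))
        all_plays.append(plays_to_dataframe(plays))
        if k == 0:
            for net in nets:
                name = f"{net.match_id}_{net.team}_p{net.period}_{net.category}.graphml"
                export_network(net, netdir / name, format="graphml")

    cases = pd.concat(all_cases, ignore_index=True)
    plays = pd.concat(all_plays, ignore_index=True)
    cases.to_csv(RESULTS / "cases.csv", index=False)
    plays.to_csv(RESULTS / "plays.csv", index=False)

    print(f"segmented {len(plays)} plays from {len(paths)} matches "
          f"({(plays.category == 'SOP').sum()} SOP, {(plays.category == 'UOP').sum()} UOP, "
          f"{n_neutral} neutral dropped)")
    print(f"built {len(cases)} network cases; "
          f"{(cases.total_passes == 0).sum()} empty cells materialized as all-zero networks")
    print(f"wrote {RESULTS / 'cases.csv'}, {RESULTS / 'plays.csv'} and {netdir}/")


if __name__ == "__main__":
    main()
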