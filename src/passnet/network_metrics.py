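"""The three predictor metrics of a passing network.

All metrics are computed on the binary link matrix (a repeated pass between
the same ordered pair adds weight but no new link) with the node count fixed
at n = 11 tactical positions, so positions that never touched the ball dilute
density and clustering.

* density             Delta = L / (n (n - 1)), the fraction of realized
                      directed links out of the 110 possible ones.
* avg_clustering      C-bar = (1/n) sum_i C_i, where the local coefficient
                      C_i of node i is the number of directed links among the
                      members of i's neighborhood (union of in- and
                      out-neighbors, k_i of them) divided by k_i (k_i - 1);
                      C_i = 0 by convention when k_i < 2.
* degree_centralization
                      Freeman's C_D = sum_v (deg(v*) - deg(v)) / (n^2 - 3n + 2)
                      with deg taken on the symmetrized binary graph, so the
                      denominator (n - 1)(n - 2) makes the star graph attain
                      exactly 1 and every degree-regular graph score 0.  A
                      switchable convention (``degree_mode="directed_total"``)
                      uses in-degree + out-degree instead for sensitivity
                      checks; that variant can exceed 1 and is not the
                      default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from passnet.event_model import N_POSITIONS
from passnet.network_builder import PassNetwork

MAX_LINKS = N_POSITIONS * (N_POSITIONS - 1)  # 110 possible directed links


def _link_matrix(net: PassNetwork | np.ndarray) -> np.ndarray:
    a = net.link if isinstance(net, PassNetwork) else (np.asarray(net) > 0).astype(int)
    if a.shape != (N_POSITIONS, N_POSITIONS):
        raise ValueError(f"expected an 11x11 matrix, got {a.shape}")
    a = a.copy()
    np.fill_diagonal(a, 0)
    return a


def density(net: PassNetwork | np.ndarray) -> float:
    """Fraction of realized directed links: L / (n(n-1)), in [0, 1]."""
    a = _link_matrix(net)
    return float(a.sum()) / MAX_LINKS


def local_clustering(net: PassNetwork | np.ndarray, i: int) -> float:
    """Local clustering coefficient of tactical position ``i`` (1-based)."""
    if not (isinstance(i, (int, np.integer)) and 1 <= i <= N_POSITIONS):
        raise ValueError(f"node index must be in 1..11, got {i}")
    a = _link_matrix(net)
    idx = i - 1
    neighborhood = np.flatnonzero((a[idx] + a[:, idx]) > 0)
    k = len(neighborhood)
    if k < 2:
        return 0.0
    sub = a[np.ix_(neighborhood, neighborhood)]
    return float(sub.sum()) / (k * (k - 1))


def avg_clustering(net: PassNetwork | np.ndarray) -> float:
    """Average local clustering coefficient over all 11 positions."""
    return sum(local_clustering(net, i) for i in range(1, N_POSITIONS + 1)) / N_POSITIONS


def degree_centralization(
    net: PassNetwork | np.ndarray, degree_mode: str = "symmetric"
) -> float:
    """Freeman degree centralization, 0 (all degrees equal) to 1 (star)."""
    a = _link_matrix(net)
    if degree_mode == "symmetric":
        sym = ((a + a.T) > 0).astype(int)
        deg = sym.sum(axis=1)
    elif degree_mode == "directed_total":
        deg = a.sum(axis=1) + a.sum(axis=0)
    else:
        raise ValueError(f"unknown degree_mode {degree_mode!r}")
    n = N_POSITIONS
    return float((deg.max() - deg).sum()) / (n * n - 3 * n + 2)


def compute_cases(networks: list[PassNetwork], degree_mode: str = "symmetric") -> pd.DataFrame:
    """One regression observation per network.

    ``outcome`` is 1 for successful-play networks and 0 for unsuccessful
    ones; ``total_passes`` uses the weight matrix, the three metrics the
    binary links.
    """
    rows = []
    for net in networks:
        rows.append(
            {
                "match_id": net.match_id,
                "team": net.team,
                "period": net.period,
                "outcome": 1 if net.category == "SOP" else 0,
                "total_passes": net.total_passes,
                "density": density(net),
                "clustering": avg_clustering(net),
                "centralization": degree_centralization(net, degree_mode=degree_mode),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "match_id",
            "team",
            "period",
            "outcome",
            "total_passes",
            "density",
            "clustering",
            "centralization",
        ],
    )
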