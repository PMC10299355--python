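"""Independent exact transportation solver used only as a test oracle.

Successive shortest paths with node potentials on the complete bipartite
donor->receiver graph, written without reference to the package's own
solver so that distance-to-regularity results can be cross-checked by a
genuinely separate route.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def transport_min_cost(supply: np.ndarray, demand: np.ndarray, cost: np.ndarray) -> float:
    """Minimum total cost shipping ``supply`` to ``demand`` (continuous flows).

    ``cost[i, j]`` >= 0 is the unit shipping cost from donor i to receiver j;
    total supply must equal total demand.
    """
    supply = np.asarray(supply, dtype=float).copy()
    demand = np.asarray(demand, dtype=float).copy()
    cost = np.asarray(cost, dtype=float)
    m, n = cost.shape
    assert abs(supply.sum() - demand.sum()) <= 1e-9 * max(supply.sum(), 1.0)
    total = supply.sum()
    if total <= _EPS:
        return 0.0
    big = np.inf
    nn = m + n  # donors 0..m-1, receivers m..m+n-1
    flow = np.zeros((m, n))
    pot = np.zeros(nn)
    pot_source = 0.0  # potential of the implicit super-source feeding all donors

    while supply.sum() > _EPS * max(total, 1.0):
        # Dijkstra over the residual graph with reduced costs; donors with
        # remaining supply start at the (non-negative) reduced cost of their
        # super-source edge so multi-source labels stay consistent.
        dist = np.full(nn, big)
        prev = np.full(nn, -1, dtype=int)
        open_donors = supply > _EPS
        dist[:m][open_donors] = np.maximum(pot_source - pot[:m][open_donors], 0.0)
        done = np.zeros(nn, dtype=bool)
        while True:
            cand = np.where(~done, dist, big)
            u = int(np.argmin(cand))
            if cand[u] == big:
                break
            done[u] = True
            if u < m:  # donor -> every receiver (forward residual, infinite cap)
                red = np.maximum(cost[u] + pot[u] - pot[m:], 0.0)
                better = ~done[m:] & (dist[u] + red < dist[m:])
                dist[m:][better] = dist[u] + red[better]
                prev[m:][better] = u
            else:  # receiver -> donors with positive flow (backward residual)
                j = u - m
                has = flow[:, j] > _EPS
                red = np.maximum(-cost[:, j] + pot[u] - pot[:m], 0.0)
                better = has & ~done[:m] & (dist[u] + red < dist[:m])
                dist[:m][better] = dist[u] + red[better]
                prev[:m][better] = u

        open_recv = np.flatnonzero(demand > _EPS)
        t = int(open_recv[np.argmin(dist[m + open_recv])])
        target = m + t
        assert dist[target] < big, "no augmenting path found"

        # trace the path and find the bottleneck
        path = []
        v = target
        while prev[v] != -1:
            path.append((prev[v], v))
            v = prev[v]
        path.reverse()
        source = path[0][0]
        bottleneck = min(supply[source], demand[t])
        for a, b in path:
            if a >= m:  # backward edge receiver a -> donor b
                bottleneck = min(bottleneck, flow[b, a - m])
        for a, b in path:
            if a < m:
                flow[a, b - m] += bottleneck
            else:
                flow[b, a - m] -= bottleneck
        supply[source] -= bottleneck
        demand[t] -= bottleneck
        pot += np.minimum(dist, dist[target])
        pot_source += dist[target]

    return float((flow * cost).sum())


def distance_to_regularity_oracle(xy: np.ndarray, counts: np.ndarray) -> float:
    """D computed by the independent solver from raw counts."""
    counts = np.asarray(counts, dtype=float)
    dev = counts - counts.mean()
    donors = dev > _EPS
    receivers = dev < -_EPS
    if not donors.any() or not receivers.any():
        return 0.0
    dxy = xy[donors][:, None, :] - xy[receivers][None, :, :]
    cost = np.sqrt((dxy**2).sum(axis=-1))
    return transport_min_cost(dev[donors], -dev[receivers], cost)
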