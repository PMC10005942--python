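"""Independent brute-force oracles used by the test suite only."""

import numpy as np


def naive_agglomerate(points: np.ndarray, method: str) -> np.ndarray:
    """O(n^3) Lance-Williams agglomerator returning a scipy-style merge table.

    Heights are on the distance scale; Ward follows the same convention as
    scipy (height = sqrt of 2x the within-cluster sum-of-squares increase).
    """
    n = points.shape[0]
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    active = {i: ([i], 1) for i in range(n)}  # id -> (members, size)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        ma, sa = active[a]
        mb, sb = active[b]
        Z[step] = [min(a, b), max(a, b), h, sa + sb]
        merged = (ma + mb, sa + sb)
        del active[a], active[b]
        new_dist = {}
        for (i, j), d in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(i, j)] = d
        for c, (mc, sc) in active.items():
            dca = dist[tuple(sorted((c, a)))]
            dcb = dist[tuple(sorted((c, b)))]
            dab = h
            if method == "single":
                d = min(dca, dcb)
            elif method == "complete":
                d = max(dca, dcb)
            elif method == "average":
                d = (sa * dca + sb * dcb) / (sa + sb)
            elif method == "ward":
                s = sa + sb + sc
                d = np.sqrt(
                    ((sa + sc) * dca**2 + (sb + sc) * dcb**2 - sc * dab**2) / s
                )
            else:
                raise ValueError(method)
            new_dist[tuple(sorted((c, next_id)))] = d
        dist = new_dist
        active[next_id] = merged
        next_id += 1
    return Z


def grid_search_cca_r1(X: np.ndarray, Y: np.ndarray, n_angles: int = 360) -> float:
    """Maximal corr(Xa, Yb) over a dense grid of unit-norm 2-D weight pairs.

    Only valid for two-column blocks; serves as an independent oracle for
    the first canonical correlation.
    """
    assert X.shape[1] == 2 and Y.shape[1] == 2
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    thetas = np.linspace(0, np.pi, n_angles, endpoint=False)
    best = 0.0
    xa = Xc @ np.stack([np.cos(thetas), np.sin(thetas)])
    yb = Yc @ np.stack([np.cos(thetas), np.sin(thetas)])
    xa = (xa - xa.mean(0)) / xa.std(0)
    yb = (yb - yb.mean(0)) / yb.std(0)
    corr = np.abs(xa.T @ yb / X.shape[0])
    return float(corr.max())
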