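import itertools

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_changepoints(y, min_distance=5, kmax=2):
    """Independent exhaustive-enumeration oracle for piecewise-linear
    changepoint placement: for each k, the RSS-minimising placement with
    every segment >= min_distance frames. Returns {k: (rss, changepoints)}.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cache = {}

    def rss(i, j):
        if (i, j) not in cache:
            x = np.arange(i, j, dtype=float)
            A = np.column_stack([np.ones(j - i), x])
            beta, *_ = np.linalg.lstsq(A, y[i:j], rcond=None)
            r = y[i:j] - A @ beta
            cache[(i, j)] = float(r @ r)
        return cache[(i, j)]

    out = {0: (rss(0, n), [])}
    for k in range(1, kmax + 1):
        best = (np.inf, None)
        for cps in itertools.combinations(range(min_distance, n - min_distance + 1), k):
            edges = [0, *cps, n]
            if any(b - a < min_distance for a, b in zip(edges[:-1], edges[1:])):
                continue
            tot = sum(rss(a, b) for a, b in zip(edges[:-1], edges[1:]))
            if tot < best[0]:
                best = (tot, list(cps))
        if best[1] is not None:
            out[k] = best
    return out


def segmentation_rss(y, changepoints):
    """Total per-segment linear-fit RSS of a given segmentation."""
    y = np.asarray(y, dtype=float)
    edges = [0, *changepoints, len(y)]
    tot = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        x = np.arange(a, b, dtype=float)
        A = np.column_stack([np.ones(b - a), x])
        beta, *_ = np.linalg.lstsq(A, y[a:b], rcond=None)
        tot += float(np.sum((y[a:b] - A @ beta) ** 2))
    return tot
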