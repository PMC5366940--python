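"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's greedy search path: the cluster
oracle enumerates every cluster up to a given size exhaustively, and the
random-search oracle probes the ridge criterion at random coefficient
vectors.
"""

from itertools import combinations, product

import numpy as np

from methylsex.plr import ridge_logistic_fit


def enumerate_best_cluster(X, y, lam, max_size=3, tol=1e-10):
    """Best (lowest-criterion) cluster over all subsets of size <= max_size
    with all orientation assignments.

    The first member's orientation is fixed to +1 (a global sign flip of
    the centroid is absorbed by the coefficient).  Returns (criterion,
    members) with members as ((index, sign), ...).
    """
    n, p = X.shape
    best = (np.inf, None)
    ones = np.ones((n, 1))
    for size in range(1, max_size + 1):
        for subset in combinations(range(p), size):
            for signs in product((1, -1), repeat=size - 1):
                sgn = (1,) + signs
                centroid = np.mean(
                    [s * X[:, j] for j, s in zip(subset, sgn)], axis=0
                )
                design = np.column_stack([ones, centroid])
                _, crit, _, _ = ridge_logistic_fit(design, y, lam, tol=tol)
                if crit < best[0]:
                    best = (crit, tuple(zip(subset, sgn)))
    return best


def greedy_reachable(X, y, lam, max_size=3, tol=1e-10):
    """Whether plain forward selection (scored exhaustively, no pruning)
    attains the enumerated optimum.

    Grows a cluster by repeatedly appending the single oriented feature
    (scored by exact refits over all candidates) that most lowers the
    criterion, stopping when nothing improves.  Instances where this
    path ends at the enumerated best are "greedy-reachable".
    """
    n, p = X.shape
    ones = np.ones((n, 1))

    def crit_of(members):
        centroid = np.mean([s * X[:, j] for j, s in members], axis=0)
        design = np.column_stack([ones, centroid])
        return ridge_logistic_fit(design, y, lam, tol=tol)[1]

    _, crit = ridge_logistic_fit(ones, y, lam, tol=tol), None
    crit = ridge_logistic_fit(ones, y, lam, tol=tol)[1]
    members = []
    while len(members) < max_size:
        chosen = set(j for j, _ in members)
        best = (crit, None)
        for j in range(p):
            if j in chosen:
                continue
            for s in (1, -1):
                c = crit_of(members + [(j, s)])
                if c < best[0] - 1e-12:
                    best = (c, (j, s))
        if best[1] is None:
            break
        members.append(best[1])
        crit = best[0]
    best_crit, _ = enumerate_best_cluster(X, y, lam, max_size, tol)
    return crit - best_crit <= 1e-9


def plr_instance(n=20, p=8, delta=1.0, seed=0):
    """A small standardized instance with one weakly informative feature."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += delta * (y - 0.5)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return X, y
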