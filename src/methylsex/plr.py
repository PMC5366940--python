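"""Penalized logistic regression with supervised feature clustering.

The classifier builds up to ``q`` *meta-features* (clusters).  A cluster
is a set of oriented, standardized features whose arithmetic mean (the
cluster centroid) enters a logistic model as one predictor.  Clusters are
grown greedily: each step appends the single candidate feature (tried in
both orientations, +x and -x) whose addition most lowers the
l2-penalized negative log-likelihood

    J(beta) = -sum_i [ y_i log mu_i + (1 - y_i) log(1 - mu_i) ]
              + lambda * sum_{k >= 1} beta_k^2

refitting all coefficients at every evaluation; after each accepted
addition a pruning pass removes the member whose removal most lowers J,
if any strictly does.  Earlier clusters' centroids stay in the model as
covariates while later clusters grow.  The intercept is unpenalized.
Ridge coefficients are fitted by Newton/IRLS with step-halving,
converged when the penalized-gradient max-norm drops below ``tol``.

All search steps are deterministic: ties are broken by feature order
(features are sorted by id at fit time) with the positive orientation
preferred, and a strict-improvement tolerance prevents add/prune cycling.
Default hyper-parameters are lambda = 1/32 and up to q = 10 clusters.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, DataError
from .tiles import FeatureMatrix

logger = logging.getLogger(__name__)

_STEP_HALVINGS = 30
#: candidate scans run to this gradient norm; the accepted candidate is then
#: refitted to full tolerance, so greedy decisions rest on exact criteria
_SCAN_TOL = 1e-6


@dataclass
class PLRConfig:
    """Hyper-parameters of the clustered ridge-logistic classifier.

    lam
        Ridge penalty on non-intercept coefficients (default 1/32).
    n_clusters
        Maximum number of meta-feature clusters ``q`` (default 10).
    max_cluster_size
        Cap on features per cluster.
    tol / max_iter
        IRLS convergence: penalized-gradient max-norm threshold and
        iteration cap.
    improve_tol
        A greedy step is accepted only if it lowers the criterion by more
        than this (prevents add/prune cycling on ties).
    """

    lam: float = 1.0 / 32.0
    n_clusters: int = 10
    max_cluster_size: int = 15
    tol: float = 1e-8
    max_iter: int = 100
    improve_tol: float = 1e-12

    def __post_init__(self):
        if self.lam <= 0:
            raise ConfigurationError("lam must be > 0")
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")


@dataclass
class FittedPLR:
    """Fitted classifier state.

    ``clusters`` is an ordered list; each cluster is a list of
    (feature id, orientation sign) pairs.  ``coef`` holds the intercept
    followed by one coefficient per cluster.  ``means``/``sds`` are the
    training standardization parameters, reused verbatim at test time.
    A feature may appear in several clusters.
    """

    means: pd.Series
    sds: pd.Series
    clusters: list
    coef: np.ndarray
    criterion: float
    classes: tuple
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def selected_features(self) -> list[str]:
        """Unique feature ids over all clusters, in first-use order."""
        seen: dict[str, None] = {}
        for cl in self.clusters:
            for fid, _ in cl:
                seen.setdefault(fid)
        return list(seen)

    # -- serialization ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "methylsex-plr/1",
                "classes": list(self.classes),
                "means": self.means.to_dict(),
                "sds": self.sds.to_dict(),
                "clusters": [
                    [[fid, int(s)] for fid, s in cl] for cl in self.clusters
                ],
                "coef": self.coef.tolist(),
                "criterion": self.criterion,
                "converged": self.converged,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedPLR":
        d = json.loads(text)
        if d.get("format") != "methylsex-plr/1":
            raise DataError("not a methylsex PLR model document")
        return cls(
            means=pd.Series(d["means"]),
            sds=pd.Series(d["sds"]),
            clusters=[[(fid, int(s)) for fid, s in cl] for cl in d["clusters"]],
            coef=np.asarray(d["coef"], dtype=float),
            criterion=float(d["criterion"]),
            classes=tuple(d["classes"]),
            converged=bool(d["converged"]),
        )


def standardize(
    values: pd.DataFrame, training_ids=None
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center/scale features by their *training* mean and SD.

    Returns the standardized frame plus the parameters; zero-SD features
    are dropped with a warning.  Test samples must be standardized with
    these training parameters, never their own.
    """
    train = values if training_ids is None else values.loc[training_ids]
    arr = train.to_numpy(dtype=float)
    means = pd.Series(arr.mean(axis=0), index=train.columns)
    sds = pd.Series(arr.std(axis=0, ddof=1), index=train.columns)
    zero = sds[sds == 0].index
    if len(zero):
        warnings.warn(f"dropping {len(zero)} zero-variance features")
        values = values.drop(columns=zero)
        means = means.drop(zero)
        sds = sds.drop(zero)
    return (values - means) / sds, means, sds


# ---------------------------------------------------------------------------
# ridge-logistic core


def _criterion(eta: np.ndarray, y: np.ndarray, beta_pen_sq, lam: float):
    # softplus(eta) - y*eta, stable for large |eta|
    nll = np.sum(
        np.logaddexp(0.0, eta) - y * eta, axis=-1
    )
    return nll + lam * beta_pen_sq


def ridge_logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 100,
    penalize: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
):
    """Minimize the l2-penalized logistic negative log-likelihood.

    ``X`` must include the intercept column (first); only columns with
    ``penalize`` True (default: all but the first) are penalized.
    Newton/IRLS with step-halving, optionally warm-started at ``beta0``.
    Returns (beta, criterion, grad_max_norm, converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if penalize is None:
        penalize = np.ones(m, dtype=bool)
        penalize[0] = False
    pen = penalize.astype(float)
    beta = np.zeros(m) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    crit = _criterion(X @ beta, y, np.sum(pen * beta**2), lam)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        g = X.T @ (mu - y) + 2.0 * lam * pen * beta
        gmax = np.max(np.abs(g))
        if gmax < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X + 2.0 * lam * np.diag(pen)
        step = np.linalg.solve(H, g)
        alpha = 1.0
        for _h in range(_STEP_HALVINGS):
            trial = beta - alpha * step
            c_new = _criterion(X @ trial, y, np.sum(pen * trial**2), lam)
            if c_new <= crit + 1e-12:
                break
            alpha *= 0.5
        else:
            break  # cannot improve along the Newton direction
        beta, crit = trial, c_new
    if not converged:
        eta = X @ beta
        g = X.T @ (expit(eta) - y) + 2.0 * lam * pen * beta
        gmax = np.max(np.abs(g))
        converged = gmax < tol
        if not converged:
            logger.warning("ridge IRLS stopped at gradient max-norm %.3g", gmax)
    return beta, float(crit), float(gmax), converged


def _batch_fit(F: np.ndarray, Z: np.ndarray, y: np.ndarray, lam: float,
               tol: float = 1e-8, max_iter: int = 60,
               beta0: np.ndarray | None = None):
    """Ridge-logistic fits for many candidate designs at once.

    Every candidate design is ``[F | z_c]`` where ``F`` (n x k, intercept
    first) is shared and ``z_c`` is row c of ``Z`` (C x n).  ``beta0``
    (length k + 1) warm-starts every candidate, e.g. with the current
    model's coefficients and 0 for the new column.  Returns the
    minimized criterion per candidate and the coefficient matrix.
    Batched Newton with per-candidate step-halving; converged candidates
    drop out of subsequent iterations.
    """
    n, k = F.shape
    C = Z.shape[0]
    m = k + 1
    pen = np.ones(m)
    pen[0] = 0.0
    beta = np.zeros((C, m)) if beta0 is None else np.tile(beta0, (C, 1))
    eye_pen = 2.0 * lam * np.diag(pen)

    def crits(b, z):
        eta = b[:, :k] @ F.T + b[:, k:] * z
        return _criterion(eta, y, np.sum(pen * b**2, axis=1), lam)

    crit = crits(beta, Z)
    idx = np.arange(C)
    for _ in range(max_iter):
        b = beta[idx]
        z = Z[idx]
        eta = b[:, :k] @ F.T + b[:, k:] * z
        mu = expit(eta)
        r = mu - y
        g = np.concatenate([r @ F, np.sum(r * z, axis=1, keepdims=True)], axis=1)
        g += 2.0 * lam * pen * b
        live = np.max(np.abs(g), axis=1) >= tol
        idx = idx[live]
        if idx.size == 0:
            break
        b, z, g, mu = b[live], z[live], g[live], mu[live]
        w = mu * (1.0 - mu)
        H = np.empty((idx.size, m, m))
        H[:, :k, :k] = np.einsum("cn,nj,nk->cjk", w, F, F, optimize=True)
        H[:, :k, k] = np.einsum("cn,nj->cj", w * z, F, optimize=True)
        H[:, k, :k] = H[:, :k, k]
        H[:, k, k] = np.sum(w * z * z, axis=1)
        H += eye_pen
        step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        alpha = np.ones(idx.size)
        cur = crit[idx]
        improved = np.zeros(idx.size, dtype=bool)
        trial = b
        for _h in range(_STEP_HALVINGS):
            trial = b - alpha[:, None] * step
            c_new = crits(trial, z)
            improved = c_new <= cur + 1e-12
            if improved.all():
                break
            alpha[~improved] *= 0.5
        moved = idx[improved]
        beta[moved] = trial[improved]
        crit[moved] = c_new[improved]
        idx = moved  # candidates that stalled drop out
        if idx.size == 0:
            break
    return crit, beta


# ---------------------------------------------------------------------------
# greedy supervised clustering


def grow_cluster(
    X: np.ndarray,
    y: np.ndarray,
    fixed_centroids: np.ndarray,
    base_criterion: float,
    config: PLRConfig,
    base_beta: np.ndarray | None = None,
    exclude: set | None = None,
):
    """Grow one cluster by forward selection with recurrent pruning.

    ``X`` is the standardized n x p feature matrix; ``fixed_centroids``
    (n x k) are earlier clusters' centroids, entering as fixed covariates
    whose coefficients are still refitted at every evaluation.
    ``base_beta`` (coefficients of the model without this cluster)
    warm-starts the candidate refits.  Returns (members, criterion):
    ``members`` is a list of (column index, sign), empty when no single
    feature improves on ``base_criterion``.
    """
    n, p = X.shape
    F = np.column_stack([np.ones(n), fixed_centroids])
    if base_beta is None:
        base_beta = ridge_logistic_fit(F, y, config.lam, config.tol)[0]
    members: list[tuple[int, int]] = []
    S = np.zeros(n)
    crit_cur = base_criterion
    warm = np.append(base_beta, 0.0)
    scan_tol = max(config.tol, _SCAN_TOL)

    def exact(z, beta_start):
        design = np.column_stack([F, z])
        beta, crit, _, _ = ridge_logistic_fit(
            design, y, config.lam, config.tol, config.max_iter, beta0=beta_start
        )
        return beta, crit

    while len(members) < config.max_cluster_size:
        in_cluster = {j for j, _ in members}
        cand = np.array(
            [j for j in range(p) if j not in in_cluster and
             (exclude is None or j not in exclude)],
            dtype=int,
        )
        if cand.size == 0:
            break
        m_new = len(members) + 1
        Zp = (S[None, :] + X[:, cand].T) / m_new
        Zm = (S[None, :] - X[:, cand].T) / m_new
        crits, betas = _batch_fit(
            F, np.vstack([Zp, Zm]), y, config.lam, scan_tol, beta0=warm
        )
        best = int(np.argmin(crits))
        if best < cand.size:
            j, s = int(cand[best]), +1
            z_best = Zp[best]
        else:
            j, s = int(cand[best - cand.size]), -1
            z_best = Zm[best - cand.size]
        beta_x, crit_x = exact(z_best, betas[best])
        if not (crit_x < crit_cur - config.improve_tol):
            break
        members.append((j, s))
        S = S + s * X[:, j]
        crit_cur = crit_x
        warm = beta_x
        # pruning pass: drop the member whose removal most lowers J
        while len(members) >= 2:
            mm = len(members) - 1
            Zr = np.array(
                [(S - s_i * X[:, j_i]) / mm for j_i, s_i in members]
            )
            crits_r, betas_r = _batch_fit(
                F, Zr, y, config.lam, scan_tol, beta0=warm
            )
            best_r = int(np.argmin(crits_r))
            beta_rx, crit_rx = exact(Zr[best_r], betas_r[best_r])
            if crit_rx < crit_cur - config.improve_tol:
                j_i, s_i = members.pop(best_r)
                S = S - s_i * X[:, j_i]
                crit_cur = crit_rx
                warm = beta_rx
            else:
                break
    return members, crit_cur, warm


def _centroid(X: np.ndarray, members) -> np.ndarray:
    cols = np.array([s * X[:, j] for j, s in members])
    return cols.mean(axis=0)


def fit(matrix, labels=None, config: PLRConfig | None = None) -> FittedPLR:
    """Fit the clustered ridge-logistic classifier.

    ``matrix`` is a :class:`~methylsex.tiles.FeatureMatrix` (its ``sex``
    provides the labels) or a samples x features DataFrame with
    ``labels`` given separately.  Requires two classes with >= 2 samples
    each.  Deterministic for a given input and configuration.
    """
    config = config or PLRConfig()
    if isinstance(matrix, FeatureMatrix):
        values, labels = matrix.values, matrix.sex
    else:
        values = matrix
        if labels is None:
            raise ConfigurationError("labels required with a plain DataFrame")
        labels = pd.Series(labels, index=values.index)
    if values.isna().any().any():
        raise DataError("feature matrix contains missing values; impute first")
    classes = tuple(sorted(labels.unique()))
    if len(classes) != 2:
        raise ConfigurationError(f"need exactly 2 classes, got {classes}")
    if (labels.value_counts() < 2).any():
        raise ConfigurationError("need >= 2 samples per class")

    values = values[sorted(values.columns)]  # tie-breaks: lowest feature id
    std, means, sds = standardize(values)
    X = std.to_numpy(dtype=float)
    y = (labels == classes[1]).to_numpy(dtype=float)
    n = len(y)
    feature_ids = list(std.columns)

    beta_cur, crit, _, _ = ridge_logistic_fit(
        np.ones((n, 1)), y, config.lam, config.tol, config.max_iter
    )
    clusters: list[list[tuple[int, int]]] = []
    centroids: list[np.ndarray] = []
    for _c in range(config.n_clusters):
        fixed = (
            np.column_stack(centroids) if centroids else np.empty((n, 0))
        )
        members, new_crit, beta_new = grow_cluster(
            X, y, fixed, crit, config, base_beta=beta_cur
        )
        if not members:
            break
        clusters.append(members)
        centroids.append(_centroid(X, members))
        crit = new_crit
        beta_cur = beta_new
    if not clusters:
        design = np.ones((n, 1))
    else:
        design = np.column_stack([np.ones(n), *centroids])
    coef, crit_final, gmax, converged = ridge_logistic_fit(
        design, y, config.lam, config.tol, config.max_iter
    )
    return FittedPLR(
        means=means,
        sds=sds,
        clusters=[
            [(feature_ids[j], s) for j, s in cl] for cl in clusters
        ],
        coef=coef,
        criterion=float(crit_final),
        classes=classes,
        converged=converged,
    )


def _model_centroids(model: FittedPLR, values: pd.DataFrame) -> np.ndarray:
    missing = [
        fid
        for cl in model.clusters
        for fid, _ in cl
        if fid not in values.columns
    ]
    if missing:
        raise DataError(
            f"input matrix lacks model features: {sorted(set(missing))}"
        )
    cents = []
    for cl in model.clusters:
        cols = []
        for fid, s in cl:
            z = (values[fid] - model.means[fid]) / model.sds[fid]
            cols.append(s * z.to_numpy(dtype=float))
        cents.append(np.mean(cols, axis=0))
    if not cents:
        return np.empty((len(values), 0))
    return np.column_stack(cents)


def predict(model: FittedPLR, matrix) -> pd.DataFrame:
    """Per-sample probability of class ``model.classes[1]`` and the call.

    Centroids are computed with the stored training standardization and
    orientations; probability >= 0.5 yields class 1.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    cents = _model_centroids(model, values)
    eta = model.coef[0] + cents @ model.coef[1:]
    prob = expit(eta)
    return pd.DataFrame(
        {
            "probability": prob,
            "predicted": np.where(prob >= 0.5, model.classes[1], model.classes[0]),
        },
        index=values.index,
    )


def project_centroids(model: FittedPLR, matrix) -> pd.DataFrame:
    """Per-sample coordinates on predictors 1 and 2 (2-D projection).

    With a single-cluster model the second coordinate is 0 for every
    sample.  Coordinates depend only on the model's own features, so
    adding unused features to the matrix leaves them unchanged.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    cents = _model_centroids(model, values)
    n = len(values)
    c1 = cents[:, 0] if cents.shape[1] >= 1 else np.zeros(n)
    c2 = cents[:, 1] if cents.shape[1] >= 2 else np.zeros(n)
    return pd.DataFrame(
        {"predictor_1": c1, "predictor_2": c2}, index=values.index
    )
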