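"""Repeated K-fold cross-validation, feature recurrence and predictor
composition by chromosome.

The classifier is refitted K x R times (default 5 folds x 50 iterations);
each feature's *recurrence frequency* is the fraction of fits that
selected it into any cluster (counted once per fit).  Frequencies are
binned F1-F4 (F4 > 0.80, F3 in (0.20, 0.80], F2 in (0.10, 0.20],
F1 <= 0.10).  Per chromosome, the *relative cluster prevalence* is the
chromosome's share of all selections across fits divided by its share of
input features — the enrichment of predictive signal over uniform
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from . import plr
from .plr import PLRConfig
from .tiles import FeatureMatrix

logger = logging.getLogger(__name__)

RECURRENCE_BINS = ((0.80, "F4"), (0.20, "F3"), (0.10, "F2"), (0.0, "F1"))


@dataclass
class CVPlan:
    """Cross-validation design.

    ``split`` is ``"by-genotype"`` (all samples of a genotype stay in one
    fold) or ``"fully-random"``.  Folds
    are stratified by sex where possible; each of the R iterations
    reshuffles with a seed derived from (seed, iteration).
    """

    k: int = 5
    r: int = 50
    split: str = "by-genotype"
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.r < 1:
            raise ConfigurationError("r must be >= 1")
        if self.split not in ("by-genotype", "fully-random"):
            raise ConfigurationError(f"unknown split strategy {self.split!r}")


def _deal_stratified(rng, units: pd.DataFrame, k: int) -> list[list[str]]:
    """Deal units (rows: id, sex) into k folds, round-robin within sex."""
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for _sex, grp in units.groupby("sex"):
        ids = grp["id"].to_numpy()
        rng.shuffle(ids)
        for i, uid in enumerate(ids):
            folds[(i + offset) % k].append(uid)
        offset += len(ids)
    return folds


def make_folds(metadata: pd.DataFrame, plan: CVPlan) -> list[list[tuple]]:
    """R lists of K (train ids, validation ids) pairs.

    ``metadata`` needs columns sample, sex and (for by-genotype splits)
    genotype.  A draw in which some training split is single-class is
    redrawn, up to 100 attempts.
    """
    need = {"sample", "sex"} | (
        {"genotype"} if plan.split == "by-genotype" else set()
    )
    if not need.issubset(metadata.columns):
        raise DataError(f"metadata must have columns {sorted(need)}")
    n_units = (
        metadata["genotype"].nunique()
        if plan.split == "by-genotype"
        else len(metadata)
    )
    if n_units < plan.k:
        raise ConfigurationError(
            f"{n_units} assignable units cannot fill {plan.k} folds"
        )
    out = []
    for r in range(plan.r):
        rng = np.random.default_rng([plan.seed, r])
        for _attempt in range(100):
            if plan.split == "by-genotype":
                units = (
                    metadata.groupby("genotype")["sex"]
                    .first()
                    .rename_axis("id")
                    .reset_index()
                )
                folds_units = _deal_stratified(rng, units, plan.k)
                folds = [
                    metadata.loc[
                        metadata["genotype"].isin(u), "sample"
                    ].tolist()
                    for u in folds_units
                ]
            else:
                units = metadata.rename(columns={"sample": "id"})[["id", "sex"]]
                folds = _deal_stratified(rng, units, plan.k)
            sex_of = dict(zip(metadata["sample"], metadata["sex"]))
            ok = True
            for i in range(plan.k):
                train = [s for j in range(plan.k) if j != i for s in folds[j]]
                if len({sex_of[s] for s in train}) < 2 or not folds[i]:
                    ok = False
                    break
            if ok:
                break
        else:
            raise ConfigurationError(
                "could not draw folds with two-class training splits"
            )
        out.append(
            [
                (
                    [s for j in range(plan.k) if j != i for s in folds[j]],
                    list(folds[i]),
                )
                for i in range(plan.k)
            ]
        )
    return out


def split_train_test(
    metadata: pd.DataFrame,
    train_fraction: float = 0.7,
    by_genotype: bool = True,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Hold out a test set (default 30%), stratified by sex, optionally
    keeping genotypes intact."""
    rng = np.random.default_rng([seed, 991])
    train, test = [], []
    if by_genotype:
        units = (
            metadata.groupby("genotype")["sex"].first().rename_axis("id").reset_index()
        )
    else:
        units = metadata.rename(columns={"sample": "id"})[["id", "sex"]]
    for _sex, grp in units.groupby("sex"):
        ids = grp["id"].to_numpy()
        rng.shuffle(ids)
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    if by_genotype:
        train = metadata.loc[metadata["genotype"].isin(train), "sample"].tolist()
        test = metadata.loc[metadata["genotype"].isin(test), "sample"].tolist()
    return sorted(train), sorted(test)


@dataclass
class CVResult:
    """Per-fit records plus pooled summaries."""

    records: list
    n_fits: int
    misclassification_pooled: float
    misclassification_mean: float

    def selected_per_fit(self) -> list[set]:
        return [set(rec["selected"]) for rec in self.records]


def run_cv(
    matrix: FeatureMatrix,
    plan: CVPlan,
    config: PLRConfig | None = None,
    metadata: pd.DataFrame | None = None,
) -> CVResult:
    """K x R cross-validated fits with per-fit selected-feature records.

    ``matrix`` must be filtered and imputed.  Returns per-fit records
    (iteration, fold, selected feature ids with cluster index, held-out
    errors) and the overall misclassification both pooled over all
    held-out predictions and as the mean of per-fit rates.
    """
    config = config or PLRConfig()
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "sample": matrix.values.index,
                "sex": matrix.sex.to_numpy(),
                "genotype": matrix.values.index,
            }
        )
    folds = make_folds(metadata, plan)
    records = []
    n_err = n_pred = 0
    for r, fold_set in enumerate(folds):
        for k, (train_ids, val_ids) in enumerate(fold_set):
            sub = matrix.subset_samples(train_ids)
            try:
                model = plr.fit(sub, config=config)
            except Exception as exc:  # recorded, fit skipped
                logger.warning("fit failed (iteration %d fold %d): %s", r, k, exc)
                records.append(
                    {"iteration": r, "fold": k, "failed": True, "selected": []}
                )
                continue
            val = matrix.subset_samples(val_ids)
            pred = plr.predict(model, val)
            errors = int((pred["predicted"] != val.sex).sum())
            selected = model.selected_features()
            per_cluster = [
                [fid for fid, _ in cl] for cl in model.clusters
            ]
            records.append(
                {
                    "iteration": r,
                    "fold": k,
                    "failed": False,
                    "selected": selected,
                    "clusters": per_cluster,
                    "n_errors": errors,
                    "n_val": len(val_ids),
                }
            )
            n_err += errors
            n_pred += len(val_ids)
    good = [rec for rec in records if not rec["failed"]]
    if not good:
        raise DataError("every cross-validation fit failed")
    pooled = n_err / n_pred if n_pred else float("nan")
    mean_rate = float(
        np.mean([rec["n_errors"] / rec["n_val"] for rec in good])
    )
    return CVResult(records, len(good), pooled, mean_rate)


def bin_frequency(freq: float) -> str:
    for lo, name in RECURRENCE_BINS:
        if freq > lo:
            return name
    return "F1"


def recurrence(
    result: CVResult, feature_chroms: pd.Series | None = None
) -> pd.DataFrame:
    """Selection counts, frequencies and F1-F4 bins per selected feature.

    A feature selected into several clusters within one fit counts once
    for that fit.  Never-selected features are absent.
    """
    counts: dict[str, int] = {}
    for sel in result.selected_per_fit():
        for fid in sel:
            counts[fid] = counts.get(fid, 0) + 1
    if not counts:
        return pd.DataFrame(
            columns=["feature", "count", "frequency", "bin", "chrom"]
        )
    df = pd.DataFrame(
        {"feature": list(counts), "count": list(counts.values())}
    )
    df["frequency"] = df["count"] / result.n_fits
    df["bin"] = df["frequency"].map(bin_frequency)
    if feature_chroms is not None:
        df["chrom"] = df["feature"].map(feature_chroms)
    else:
        df["chrom"] = df["feature"].str.split(":").str[0]
    return df.sort_values("frequency", ascending=False).reset_index(drop=True)


def chromosome_summary(
    result: CVResult,
    feature_chroms: pd.Series,
    input_counts: pd.Series,
) -> pd.DataFrame:
    """Predictor composition per chromosome.

    Per fit and chromosome: total selections (a feature in two clusters
    counts twice) and unique selected features; reported as mean (SD)
    over fits.  ``relative_prevalence`` = (chromosome's share of all
    selections over all fits) / (chromosome's share of input features).
    """
    chroms = list(input_counts.index)
    per_fit_total = {c: [] for c in chroms}
    per_fit_unique = {c: [] for c in chroms}
    for rec in result.records:
        if rec["failed"]:
            continue
        tot: dict[str, int] = {c: 0 for c in chroms}
        uni: dict[str, set] = {c: set() for c in chroms}
        for cl in rec.get("clusters", []):
            for fid in cl:
                if fid not in feature_chroms.index:
                    raise DataError(f"feature {fid} has no chromosome mapping")
                c = feature_chroms[fid]
                tot[c] += 1
                uni[c].add(fid)
        for c in chroms:
            per_fit_total[c].append(tot[c])
            per_fit_unique[c].append(len(uni[c]))
    total_selections = sum(sum(v) for v in per_fit_total.values())
    total_input = input_counts.sum()
    rows = []
    for c in chroms:
        sel_share = (
            sum(per_fit_total[c]) / total_selections if total_selections else 0.0
        )
        input_share = input_counts[c] / total_input
        rows.append(
            {
                "chrom": c,
                "mean_features": float(np.mean(per_fit_total[c])),
                "sd_features": float(np.std(per_fit_total[c], ddof=0)),
                "mean_unique": float(np.mean(per_fit_unique[c])),
                "sd_unique": float(np.std(per_fit_unique[c], ddof=0)),
                "selection_share": sel_share,
                "input_share": float(input_share),
                "relative_prevalence": (
                    sel_share / input_share if input_share > 0 else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def evaluate_test_set(
    matrix: FeatureMatrix,
    train_ids: list[str],
    test_ids: list[str],
    config: PLRConfig | None = None,
) -> dict:
    """Refit on all training samples and score the held-out test set.

    Returns the fitted model, per-sample calls, the test
    misclassification rate and the 2-D centroid projection of all
    samples (train and test flagged).
    """
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ConfigurationError(f"train/test overlap: {sorted(overlap)[:5]}")
    if not test_ids:
        raise ConfigurationError("test set is empty")
    model = plr.fit(matrix.subset_samples(train_ids), config=config)
    test = matrix.subset_samples(test_ids)
    pred = plr.predict(model, test)
    miscls = float((pred["predicted"] != test.sex).mean())
    proj = plr.project_centroids(model, matrix)
    proj["role"] = [
        "train" if s in set(train_ids) else "test" for s in proj.index
    ]
    proj["sex"] = matrix.sex
    return {
        "model": model,
        "predictions": pred.assign(true_sex=test.sex),
        "misclassification": miscls,
        "projection": proj,
    }
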