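"""Per-cytosine differential methylation between two groups.

The test is the binomial-GLM likelihood-ratio test of methylation
proportion on group membership, with per-sample binomial totals.  Because
the design holds only the group factor, the maximum-likelihood fit is the
pooled per-group proportion, and the deviance difference between the
group model and the intercept-only model reduces in closed form to the
G-statistic of the pooled 2x2 (group x methylation state) table; that
closed form is what is evaluated, vectorised over sites.  P-values come
from the chi-square distribution with 1 df, q-values from
Benjamini-Hochberg.

Significance follows the standard two-threshold rule: q below a cutoff
*and* an absolute methylation difference of at least a cutoff in
percentage points.  Two presets are shipped: ``methods`` (25 pp, q<0.001)
and ``figure1`` (20 pp, q<0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .annotation import GeneAnnotation
from .errors import ConfigurationError, DataError
from .io import MethylomeSample

logger = logging.getLogger(__name__)

#: significance presets: (diff_threshold in percentage points, q_threshold)
PRESETS = {"methods": (25.0, 0.001), "figure1": (20.0, 0.001)}


def lrt_group_statistic(m1, t1, m2, t2):
    """Deviance difference (group model vs null) for pooled group counts.

    Vectorised; ``m`` = methylated, ``t`` = total per group.  Equals
    ``2 * sum O * ln(O/E)`` over the pooled 2x2 table.  Zero totals in a
    group yield NaN (the site is untestable).
    """
    m1 = np.asarray(m1, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n = t1 + t2
    p0 = np.divide(m1 + m2, n, out=np.zeros_like(n), where=n > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            xlogy(m1, m1) + xlogy(t1 - m1, t1 - m1) - xlogy(t1, t1)
            + xlogy(m2, m2) + xlogy(t2 - m2, t2 - m2) - xlogy(t2, t2)
        )
        ll0 = xlogy(m1 + m2, p0) + xlogy(n - m1 - m2, 1.0 - p0)
    g = 2.0 * (ll - ll0)
    g = np.where(g < 1e-10, 0.0, g)  # clear floating-point residue at equality
    g = np.where((t1 > 0) & (t2 > 0), g, np.nan)
    return g


def dm_test_site(group1_counts, group2_counts) -> tuple[float, float]:
    """Test one site: (difference in percentage points, p-value).

    ``group*_counts`` are per-sample (meth, unmeth) pairs.  The difference
    is pooled ratio(group2) - pooled ratio(group1), in percentage points.
    Raises :class:`DataError` when a group has zero total coverage.
    """
    g1 = np.atleast_2d(np.asarray(group1_counts, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2_counts, dtype=float))
    m1, t1 = g1[:, 0].sum(), g1.sum()
    m2, t2 = g2[:, 0].sum(), g2.sum()
    if t1 == 0 or t2 == 0:
        raise DataError("a group has zero total coverage at this site")
    stat = float(lrt_group_statistic(m1, t1, m2, t2))
    p = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    diff = 100.0 * (m2 / t2 - m1 / t1)
    return diff, p


def adjust_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DMOptions:
    q_threshold: float = 0.001
    diff_threshold: float = 25.0
    min_samples_per_group: int = 2

    @classmethod
    def preset(cls, name: str) -> "DMOptions":
        try:
            diff, q = PRESETS[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
            ) from None
        return cls(q_threshold=q, diff_threshold=diff)


def _pool_group(samples: list[MethylomeSample]) -> pd.DataFrame:
    calls = pd.concat([s.calls for s in samples], ignore_index=True)
    return calls.groupby(["chrom", "pos", "strand", "context"], as_index=False).agg(
        meth=("meth", "sum"),
        total=("meth", "size"),
        cov=("unmeth", "sum"),
    ).rename(columns={"total": "n_samples"}).assign(
        total=lambda d: d["meth"] + d["cov"]
    )[["chrom", "pos", "strand", "context", "meth", "total", "n_samples"]]


def call_dmcs(
    samples: list[MethylomeSample],
    groups: tuple[str, str] = ("F", "M"),
    context: str | None = None,
    options: DMOptions | None = None,
) -> pd.DataFrame:
    """Call differentially methylated cytosines between two sexes.

    Samples should already be coverage-filtered.  A site is testable when
    each group has at least ``options.min_samples_per_group`` covered
    samples.  Returns one row per testable site with columns chrom, pos,
    strand, context, meth/total per group, diff (group2 - group1,
    percentage points), p, q, significant.
    """
    options = options or DMOptions()
    by_group = {g: [s for s in samples if s.sex == g] for g in groups}
    for g, ss in by_group.items():
        if len(ss) < options.min_samples_per_group:
            raise ConfigurationError(
                f"group {g!r} has {len(ss)} samples; "
                f"need >= {options.min_samples_per_group}"
            )
    if context is not None:
        from .io import split_by_context

        by_group = {
            g: [split_by_context(s)[context] for s in ss]
            for g, ss in by_group.items()
        }
    g1, g2 = groups
    a = _pool_group(by_group[g1]).rename(
        columns={"meth": "meth1", "total": "total1", "n_samples": "n1"}
    )
    b = _pool_group(by_group[g2]).rename(
        columns={"meth": "meth2", "total": "total2", "n_samples": "n2"}
    )
    dm = a.merge(b, on=["chrom", "pos", "strand", "context"], how="inner")
    testable = (
        (dm["n1"] >= options.min_samples_per_group)
        & (dm["n2"] >= options.min_samples_per_group)
        & (dm["total1"] > 0)
        & (dm["total2"] > 0)
    )
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("skipping %d sites with insufficient per-group coverage",
                    n_skipped)
    dm = dm[testable].reset_index(drop=True)
    if dm.empty:
        return dm.assign(diff=[], p=[], q=[], significant=[])
    stat = lrt_group_statistic(
        dm["meth1"], dm["total1"], dm["meth2"], dm["total2"]
    )
    dm["diff"] = 100.0 * (dm["meth2"] / dm["total2"] - dm["meth1"] / dm["total1"])
    dm["p"] = np.where(stat > 0, chi2.sf(stat, df=1), 1.0)
    dm["q"] = adjust_qvalues(dm["p"].to_numpy())
    dm["significant"] = (dm["q"] < options.q_threshold) & (
        dm["diff"].abs() >= options.diff_threshold
    )
    return dm


def profile_gene_features(
    samples: list[MethylomeSample],
    annotation: GeneAnnotation,
    gene_id: str,
    dm: pd.DataFrame | None = None,
    sexes: tuple[str, str] = ("F", "M"),
) -> pd.DataFrame:
    """Per-feature, per-sex methylation profile of one gene.

    For each gene feature (promoter, exons, introns) the coverage-weighted
    mean methylation (sum meth / sum total over covered sites, NaN when no
    site is covered), the number of covered sites, and the number of
    significant DMCs overlapping the feature.
    """
    gene = annotation.gene(gene_id)
    sig = None
    if dm is not None and len(dm):
        sig = dm[dm["significant"] & (dm["chrom"] == gene.chrom)]
    rows = []
    for label, start, end in gene.features():
        row = {"gene_id": gene_id, "feature": label, "start": start, "end": end}
        for sex in sexes:
            meth = tot = 0
            positions = set()
            for s in samples:
                if s.sex != sex:
                    continue
                c = s.calls
                in_feat = c[
                    (c["chrom"] == gene.chrom)
                    & (c["pos"] >= start)
                    & (c["pos"] < end)
                ]
                meth += int(in_feat["meth"].sum())
                tot += int((in_feat["meth"] + in_feat["unmeth"]).sum())
                positions.update(in_feat["pos"])
            row[f"mean_{sex}"] = meth / tot if tot > 0 else float("nan")
            row[f"n_sites_{sex}"] = len(positions)
        if sig is not None:
            row["n_dmc"] = int(((sig["pos"] >= start) & (sig["pos"] < end)).sum())
        else:
            row["n_dmc"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def rank_sdr_genes(
    gene_ids: list[str],
    dm: pd.DataFrame,
    annotation: GeneAnnotation,
    include_promoter: bool = True,
) -> pd.DataFrame:
    """Rank candidate genes by overlapping significant-DMC count.

    Ties are broken by the maximum absolute methylation difference among
    the gene's significant DMCs, then by gene id.  Used to single out the
    sex-linked gene from a candidate panel on the SDR chromosome.
    """
    if not gene_ids:
        raise ConfigurationError("gene list is empty")
    sig = dm[dm["significant"]] if len(dm) else dm
    rows = []
    for gid in gene_ids:
        gene = annotation.gene(gid)  # raises KeyError for unknown ids
        s, e = gene.start, gene.end
        if include_promoter:
            ps, pe = gene.promoter
            s, e = min(s, ps), max(e, pe)
        if len(sig):
            hits = sig[
                (sig["chrom"] == gene.chrom) & (sig["pos"] >= s) & (sig["pos"] < e)
            ]
            n = len(hits)
            max_diff = float(hits["diff"].abs().max()) if n else 0.0
        else:
            n, max_diff = 0, 0.0
        rows.append({"gene_id": gid, "n_dmc": n, "max_abs_diff": max_diff})
    out = pd.DataFrame(rows).sort_values(
        ["n_dmc", "max_abs_diff", "gene_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    return out.reset_index(drop=True)


def dm_to_bed(dm: pd.DataFrame, significant_only: bool = True) -> pd.DataFrame:
    """DM results as BED (0-based half-open) for genome-browser loading."""
    d = dm[dm["significant"]] if significant_only else dm
    return pd.DataFrame(
        {
            "chrom": d["chrom"],
            "start": d["pos"],
            "end": d["pos"] + 1,
            "name": d["context"],
            "score": (d["diff"].abs().clip(0, 100) * 10).round().astype(int),
            "strand": d["strand"],
        }
    )
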