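"""Beta-binomial methylome simulation for a two-sex, two-garden cohort.

The generator emulates the statistical structure the downstream analysis
assumes: genome-wide background methylation per context, one planted
sex-linked gene on the SDR chromosome whose promoter and first intron are
strongly male-biased (intron 4 methylated in both sexes, intron 5
unmethylated), and a handful of weak sex-biased tiles scattered over the
rest of the genome.

Per site and sample, read coverage is negative-binomial and the
methylated count is beta-binomial around the applicable effect level,
adjusted on the logit scale by a genotype random effect and a fixed
garden (site) effect.  Levels of exactly 0 or 1 stay degenerate so that a
"fully unmethylated" specification really yields zero methylated reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, DataError
from .genome import CONTEXTS, GenomeLayout
from .io import CALL_COLUMNS, MethylomeSample, write_coverage_file, write_metadata
from .annotation import write_gff3

_EPS = 1e-6


@dataclass(frozen=True)
class EffectSpec:
    """A methylation level assignment for a genomic region.

    ``region`` is either ``None`` (background: applies to every site not
    claimed by a later effect), an interval ``(chrom, start, end)``, or a
    gene-feature reference ``("feature", gene_id, feature_label)``.
    ``levels`` maps sex ('F'/'M') to the mean methylation fraction;
    ``dispersion`` is the beta-binomial intra-class correlation rho.
    Effects later in a list take precedence on overlapping sites.
    """

    label: str
    levels: dict
    region: tuple | None = None
    contexts: tuple = CONTEXTS
    dispersion: float = 0.05

    def __post_init__(self):
        for sex, lv in self.levels.items():
            if not 0.0 <= lv <= 1.0:
                raise ConfigurationError(
                    f"effect {self.label}: level {lv} for {sex} outside [0,1]"
                )
        if self.dispersion <= 0:
            raise ConfigurationError(f"effect {self.label}: dispersion must be > 0")

    def resolve(self, layout: GenomeLayout) -> tuple[str, int, int] | None:
        """Concrete (chrom, start, end) of the region, or None for background."""
        if self.region is None:
            return None
        if self.region[0] == "feature":
            _, gene_id, feat = self.region
            try:
                gene = layout.gene(gene_id)
            except KeyError:
                raise DataError(
                    f"effect {self.label}: unknown gene {gene_id!r}"
                ) from None
            try:
                s, e = gene.feature(feat)
            except KeyError:
                raise DataError(
                    f"effect {self.label}: gene {gene_id} has no feature {feat!r}"
                ) from None
            return (gene.chrom, s, e)
        chrom, start, end = self.region
        if chrom not in layout.chrom_lengths:
            raise DataError(f"effect {self.label}: unknown chromosome {chrom!r}")
        return (chrom, int(start), int(end))


@dataclass
class CohortSpec:
    """Replicate plan and noise model for a simulated cohort.

    Defaults mirror a reduced-scale two-garden common-garden design:
    9 female + 11 male genotypes, each cloned at two sites (40 samples).
    ``genotype_sd`` and ``site_effect`` act on the logit of the
    methylation level; coverage is negative-binomial with the given mean
    and size (inverse-dispersion).
    """

    n_female: int = 9
    n_male: int = 11
    sites: tuple = ("PA", "IH")
    coverage_mean: float = 30.0
    coverage_size: float = 10.0
    genotype_sd: float = 0.3
    site_effect: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be > 0")
        if min(self.n_female, self.n_male) < 1 or (
            len(self.sites) * min(self.n_female, self.n_male) < 2
        ):
            raise ConfigurationError("need at least 2 samples per sex")

    def plan(self) -> pd.DataFrame:
        """One row per sample: sample, sex, genotype, site."""
        rows = []
        for sex, n in (("F", self.n_female), ("M", self.n_male)):
            for i in range(n):
                geno = f"{sex}{i + 1:02d}"
                for site in self.sites:
                    rows.append((f"{geno}_{site}", sex, geno, site))
        return pd.DataFrame(rows, columns=["sample", "sex", "genotype", "site"])


def default_effects(
    layout: GenomeLayout,
    background_levels: dict | None = None,
    sdr_male: tuple[float, float] = (0.65, 0.70),
    sdr_female: tuple[float, float] = (0.15, 0.10),
    n_weak_background: int = 5,
    weak_delta: float = 0.15,
    dispersion: float = 0.05,
    seed: int = 7,
) -> list[EffectSpec]:
    """The standard planted-effect set for the default study design.

    Background methylation per context (CG 0.30, CHG 0.25, CHH 0.10 by
    default); the flagged SDR gene gets a male-biased promoter
    (``sdr_male[0]`` vs ``sdr_female[0]``) and first intron
    (``sdr_male[1]`` vs ``sdr_female[1]``), an intron 4 methylated at 0.9
    in both sexes and an essentially unmethylated intron 5; plus
    ``n_weak_background`` weak sex-biased 500 bp tiles (male-biased by
    ``weak_delta``) on non-SDR chromosomes.
    """
    if background_levels is None:
        background_levels = {"CG": 0.30, "CHG": 0.25, "CHH": 0.10}
    sdr = layout.sdr_gene
    eff = [
        EffectSpec(f"background-{ctx}", {"F": lv, "M": lv}, None, (ctx,), dispersion)
        for ctx, lv in background_levels.items()
    ]
    eff += [
        EffectSpec(
            "SDR-promoter",
            {"F": sdr_female[0], "M": sdr_male[0]},
            ("feature", sdr.gene_id, "promoter"),
            CONTEXTS,
            dispersion,
        ),
        EffectSpec(
            "SDR-intron1",
            {"F": sdr_female[1], "M": sdr_male[1]},
            ("feature", sdr.gene_id, "intron_1"),
            CONTEXTS,
            dispersion,
        ),
        EffectSpec(
            "SDR-intron4",
            {"F": 0.9, "M": 0.9},
            ("feature", sdr.gene_id, "intron_4"),
            CONTEXTS,
            dispersion,
        ),
        EffectSpec(
            "SDR-intron5",
            {"F": 0.02, "M": 0.02},
            ("feature", sdr.gene_id, "intron_5"),
            CONTEXTS,
            dispersion,
        ),
    ]
    rng = np.random.default_rng(seed)
    non_sdr = [c for c, _ in layout.chromosomes if c != sdr.chrom]
    base_cg = background_levels.get("CG", 0.30)
    for i in range(n_weak_background):
        chrom = non_sdr[int(rng.integers(len(non_sdr)))]
        length = layout.chrom_lengths[chrom]
        start = int(rng.integers(0, max(1, length // 500 - 1))) * 500
        eff.append(
            EffectSpec(
                f"weak-sex-tile-{i + 1}",
                {"F": base_cg, "M": min(1.0, base_cg + weak_delta)},
                (chrom, start, start + 500),
                ("CG",),
                dispersion,
            )
        )
    return eff


def _effect_arrays(layout: GenomeLayout, effects: list[EffectSpec]):
    """Per-site level arrays for each sex plus per-site dispersion.

    Sites claimed by no effect get level 0 (and the default dispersion);
    effects later in the list override earlier ones.
    """
    sites = layout.sites
    n = len(sites)
    lv = {"F": np.zeros(n), "M": np.zeros(n)}
    rho = np.full(n, 0.05)
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    ctx = sites["context"].to_numpy()
    for eff in effects:
        reg = eff.resolve(layout)
        mask = np.isin(ctx, np.asarray(eff.contexts))
        if reg is not None:
            c, s, e = reg
            mask &= (chrom == c) & (pos >= s) & (pos < e)
        for sex in ("F", "M"):
            if sex in eff.levels:
                lv[sex][mask] = eff.levels[sex]
        rho[mask] = eff.dispersion
    return lv, rho


def simulate_cohort(
    layout: GenomeLayout,
    cohort: CohortSpec,
    effects: list[EffectSpec],
) -> list[MethylomeSample]:
    """Draw per-cytosine bisulfite calls for every sample of the cohort.

    Deterministic for a fixed ``cohort.seed``: repeated calls return
    byte-identical call sets.
    """
    plan = cohort.plan()
    levels, rho = _effect_arrays(layout, effects)
    sites = layout.sites
    n_sites = len(sites)

    root = np.random.SeedSequence(cohort.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    geno_ids = plan["genotype"].unique()
    geno_eff = dict(
        zip(geno_ids, meta_rng.normal(0.0, cohort.genotype_sd, size=len(geno_ids)))
    )
    site_eff = {s: (i * cohort.site_effect) for i, s in enumerate(cohort.sites)}

    p_nb = cohort.coverage_size / (cohort.coverage_size + cohort.coverage_mean)
    samples = []
    children = root.spawn(len(plan) + 1)[1:]
    for (row, child) in zip(plan.itertuples(index=False), children):
        rng = np.random.default_rng(child)
        cov = rng.negative_binomial(cohort.coverage_size, p_nb, size=n_sites)
        base = levels[row.sex]
        shift = geno_eff[row.genotype] + site_eff[row.site]
        interior = (base > 0.0) & (base < 1.0)
        p = base.copy()
        if shift != 0.0:
            p[interior] = expit(
                logit(np.clip(base[interior], _EPS, 1 - _EPS)) + shift
            )
        # beta-binomial: site- and sample-specific success probability
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        pp = np.where(interior, rng.beta(np.maximum(a, _EPS), np.maximum(b, _EPS)), p)
        meth = rng.binomial(cov, pp)
        calls = pd.DataFrame(
            {
                "chrom": sites["chrom"].to_numpy(),
                "pos": sites["pos"].to_numpy(),
                "strand": sites["strand"].to_numpy(),
                "context": sites["context"].to_numpy(),
                "meth": meth,
                "unmeth": cov - meth,
            },
            columns=CALL_COLUMNS,
        )
        samples.append(
            MethylomeSample(
                row.sample, calls, sex=row.sex, genotype=row.genotype, site=row.site
            )
        )
    return samples


def write_fixture(
    samples: list[MethylomeSample],
    layout: GenomeLayout,
    directory,
    dialect: str = "cx",
) -> list[Path]:
    """Write one call file per sample, a GFF3 annotation and a metadata TSV.

    Returns the manifest (``n_samples + 2`` paths).  Files round-trip
    through :func:`methylsex.io.read_coverage_file` and
    :func:`methylsex.annotation.read_gff3`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in samples:
        manifest.append(
            write_coverage_file(s, directory / f"{s.sample_id}.calls.tsv", dialect)
        )
    manifest.append(write_gff3(layout.genes, directory / "genes.gff3"))
    manifest.append(write_metadata(samples, directory / "samples.tsv"))
    return manifest
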