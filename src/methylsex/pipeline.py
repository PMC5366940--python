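"""High-level orchestration: simulate → differential methylation → classify.

These helpers wire the modules together with the package's default study
design (19-chromosome synthetic genome, 40-sample two-garden cohort, one
planted sex-linked gene) and the standard analysis settings (>10x
coverage filter; q < 0.001 with a >=25 pp difference; 500 bp tiles; 80%
detection + above-median-IQR feature filter; K = 5, R = 50,
lambda = 1/32, q = 10).  The CLI and the worked examples are thin layers
over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cv as cvmod
from . import diffmeth, plr, tiles
from .annotation import GeneAnnotation
from .genome import GenomeLayout, build_genome
from .io import MethylomeSample, filter_coverage, split_by_context
from .simulate import CohortSpec, default_effects, simulate_cohort


@dataclass
class PipelineConfig:
    """Analysis defaults: coverage, significance, tiling and CV settings."""

    min_coverage: int = 10
    context: str = "CG"
    q_threshold: float = 0.001
    diff_threshold: float = 25.0
    tile_length: int = 500
    detection_rate: float = 0.80
    plr: plr.PLRConfig = field(default_factory=plr.PLRConfig)
    cv: cvmod.CVPlan = field(default_factory=cvmod.CVPlan)
    seed: int = 0


def simulate_default(
    seed: int = 0,
    n_chrom: int = 19,
    chrom_length: int = 80_000,
    cytosine_density: float = 24.0,
    cohort: CohortSpec | None = None,
):
    """Build the default study: genome layout, effects and cohort samples."""
    layout = build_genome(
        n_chrom=n_chrom,
        chrom_length=chrom_length,
        cytosine_density=cytosine_density,
        seed=seed,
    )
    effects = default_effects(layout, seed=seed + 1)
    if cohort is None:
        cohort = CohortSpec(seed=seed + 2)
    samples = simulate_cohort(layout, cohort, effects)
    return layout, effects, samples


def coverage_filtered(
    samples: list[MethylomeSample], min_coverage: int = 10
) -> list[MethylomeSample]:
    return [filter_coverage(s, min_coverage) for s in samples]


def run_dmc(
    samples: list[MethylomeSample],
    annotation: GeneAnnotation,
    config: PipelineConfig | None = None,
) -> dict:
    """Coverage-filter, call DMCs per context and rank candidate genes."""
    config = config or PipelineConfig()
    filtered = coverage_filtered(samples, config.min_coverage)
    opts = diffmeth.DMOptions(
        q_threshold=config.q_threshold, diff_threshold=config.diff_threshold
    )
    dm = {
        ctx: diffmeth.call_dmcs(filtered, context=ctx, options=opts)
        for ctx in ("CG", "CHG", "CHH")
    }
    ranking = diffmeth.rank_sdr_genes(
        annotation.gene_ids(), dm[config.context], annotation
    )
    return {"dm": dm, "ranking": ranking, "filtered_samples": filtered}


def build_matrix(
    samples: list[MethylomeSample],
    chrom_lengths: dict[str, int],
    config: PipelineConfig | None = None,
) -> tiles.FeatureMatrix:
    """Coverage-filter, tile, filter features and impute — ready for PLR."""
    config = config or PipelineConfig()
    filtered = coverage_filtered(samples, config.min_coverage)
    per_ctx = [split_by_context(s)[config.context] for s in filtered]
    tiling = tiles.tile_genome(chrom_lengths, config.tile_length)
    matrix = tiles.build_feature_matrix(per_ctx, tiling, config.tile_length)
    matrix = tiles.filter_features(matrix, config.detection_rate)
    return tiles.impute_missing(matrix)


def sample_metadata(samples: list[MethylomeSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.sample_id for s in samples],
            "sex": [s.sex for s in samples],
            "genotype": [s.genotype for s in samples],
            "site": [s.site for s in samples],
        }
    )


def run_classification(
    matrix: tiles.FeatureMatrix,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Train/test split, repeated CV on the training set, recurrence map,
    chromosome composition and held-out evaluation."""
    config = config or PipelineConfig()
    train_ids, test_ids = cvmod.split_train_test(
        metadata,
        train_fraction=config.cv.train_fraction,
        by_genotype=config.cv.split == "by-genotype",
        seed=config.cv.seed,
    )
    train_meta = metadata[metadata["sample"].isin(train_ids)]
    train_matrix = matrix.subset_samples(train_ids)
    result = cvmod.run_cv(train_matrix, config.cv, config.plr, train_meta)
    rec = cvmod.recurrence(result, matrix.feature_chromosomes())
    input_counts = matrix.feature_chromosomes().value_counts()
    chrom = cvmod.chromosome_summary(
        result, matrix.feature_chromosomes(), input_counts
    )
    evaluation = cvmod.evaluate_test_set(matrix, train_ids, test_ids, config.plr)
    return {
        "train_ids": train_ids,
        "test_ids": test_ids,
        "cv": result,
        "recurrence": rec,
        "chromosome_summary": chrom,
        "evaluation": evaluation,
    }


def sdr_tile_ids(layout: GenomeLayout, tile_length: int = 500) -> list[str]:
    """Tiles overlapping the planted sex-biased features (promoter and
    intron 1) of the flagged SDR gene."""
    gene = layout.sdr_gene
    out = []
    for label in ("promoter", "intron_1"):
        s, e = gene.feature(label)
        for start in range((s // tile_length) * tile_length, e, tile_length):
            end = min(start + tile_length, layout.chrom_lengths[gene.chrom])
            out.append(f"{gene.chrom}:{start}-{end}")
    return sorted(set(out))
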