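"""Fixed 500 bp genomic tiles and the classification feature matrix.

Each tile's value for a sample is the coverage-weighted methylation
fraction (sum #Cs / sum coverage) over the sample's covered cytosines in
the tile; a tile with fewer covered sites than ``min_sites`` is missing
for that sample.  Feature filtering keeps tiles detected in at least 80%
of samples whose across-sample inter-quartile range strictly exceeds the
median IQR of the detection-passing tiles; residual missing entries are
imputed with the tile's across-sample median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .io import MethylomeSample

DEFAULT_TILE_LENGTH = 500


def tile_genome(
    chrom_lengths: dict[str, int], tile_length: int = DEFAULT_TILE_LENGTH
) -> pd.DataFrame:
    """Non-overlapping genome tiling: index ``chrom:start-end``.

    Consecutive tiles [0, L), [L, 2L), ...; the terminal tile is truncated
    at the chromosome end.
    """
    if tile_length <= 0:
        raise ConfigurationError("tile_length must be > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, tile_length)
        for s in starts:
            e = min(int(s) + tile_length, length)
            rows.append((f"{chrom}:{s}-{e}", chrom, int(s), e))
    return pd.DataFrame(
        rows, columns=["tile", "chrom", "start", "end"]
    ).set_index("tile")


@dataclass
class FeatureMatrix:
    """Samples x tiles methylation values with metadata.

    ``values``: DataFrame indexed by sample id, columns tile ids, NaN
    marks a tile undetected in a sample.  ``sex``: per-sample label.
    ``tiles``: tile coordinates (index tile id).  ``detected``: the
    pre-imputation detection mask, kept for audit once
    :func:`impute_missing` has run.
    """

    values: pd.DataFrame
    sex: pd.Series
    tiles: pd.DataFrame
    detected: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((v < 0) | (v > 1)):
                raise DataError("feature values outside [0, 1]")
        if not self.values.index.equals(self.sex.index):
            raise DataError("values and sex indexed by different samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """True where a tile is missing for a sample."""
        return self.values.isna()

    def subset_features(self, tile_ids) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[tile_ids],
            self.sex,
            self.tiles.loc[tile_ids],
            None if self.detected is None else self.detected[tile_ids],
        )

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.loc[sample_ids],
            self.sex.loc[sample_ids],
            self.tiles,
            None if self.detected is None else self.detected.loc[sample_ids],
        )

    def feature_chromosomes(self) -> pd.Series:
        return self.tiles["chrom"]

    def to_tsv(self, path) -> None:
        self.values.T.to_csv(path, sep="\t")

    def tiles_to_bed(self) -> pd.DataFrame:
        t = self.tiles.reset_index()
        return t[["chrom", "start", "end", "tile"]]


def summarize_tiles(
    sample: MethylomeSample,
    tiles: pd.DataFrame,
    tile_length: int = DEFAULT_TILE_LENGTH,
    min_sites: int = 1,
) -> pd.Series:
    """Per-tile coverage-weighted methylation for one sample.

    Returns a Series indexed like ``tiles``; NaN where the tile has fewer
    than ``min_sites`` covered cytosines.  The sample should already be
    coverage-filtered.
    """
    c = sample.calls
    if len(c) == 0:
        return pd.Series(np.nan, index=tiles.index, name=sample.sample_id)
    start = (c["pos"] // tile_length) * tile_length
    key = c["chrom"].astype(str) + ":" + start.astype(str)
    tkey = tiles["chrom"].astype(str) + ":" + tiles["start"].astype(str)
    agg = pd.DataFrame(
        {"key": key, "meth": c["meth"], "cov": c["meth"] + c["unmeth"]}
    ).groupby("key").agg(meth=("meth", "sum"), cov=("cov", "sum"), n=("meth", "size"))
    aligned = agg.reindex(tkey.to_numpy())
    with np.errstate(invalid="ignore"):
        vals = aligned["meth"].to_numpy() / aligned["cov"].to_numpy()
    vals = np.where(aligned["n"].to_numpy() >= min_sites, vals, np.nan)
    return pd.Series(vals, index=tiles.index, name=sample.sample_id)


def build_feature_matrix(
    samples: list[MethylomeSample],
    tiles: pd.DataFrame,
    tile_length: int = DEFAULT_TILE_LENGTH,
    min_sites: int = 1,
) -> FeatureMatrix:
    """Stack per-sample tile summaries into a samples x tiles matrix."""
    rows = [summarize_tiles(s, tiles, tile_length, min_sites) for s in samples]
    values = pd.DataFrame(rows)
    sex = pd.Series(
        [s.sex for s in samples], index=[s.sample_id for s in samples], name="sex"
    )
    return FeatureMatrix(values, sex, tiles)


def filter_features(
    matrix: FeatureMatrix,
    detection_rate: float = 0.80,
    iqr_rule: str = "above_median",
) -> FeatureMatrix:
    """Keep variable, well-detected features.

    First keep tiles detected in at least ``detection_rate`` of samples,
    then — among those — keep tiles whose across-sample IQR is strictly
    greater than the median IQR of the detection-passing tiles.  Pass
    ``iqr_rule="none"`` to skip the variability filter.
    """
    if matrix.n_features == 0:
        raise ConfigurationError("empty feature matrix")
    det_frac = matrix.values.notna().mean(axis=0)
    detected = det_frac[det_frac >= detection_rate].index
    sub = matrix.values[detected]
    if iqr_rule == "above_median":
        q75 = sub.quantile(0.75)
        q25 = sub.quantile(0.25)
        iqr = q75 - q25
        keep = iqr[iqr > iqr.median()].index
    elif iqr_rule == "none":
        keep = detected
    else:
        raise ConfigurationError(f"unknown iqr_rule {iqr_rule!r}")
    if len(keep) == 0:
        raise ConfigurationError(
            "feature filtering removed every tile; classifier cannot run"
        )
    return matrix.subset_features(list(keep))


def impute_missing(matrix: FeatureMatrix) -> FeatureMatrix:
    """Median-impute residual missing entries; keeps the detection mask.

    Imputed values are the feature's across-sample median, so they never
    leave the observed range or [0, 1].
    """
    detected = matrix.values.notna()
    filled = matrix.values.fillna(matrix.values.median(axis=0))
    if filled.isna().any().any():
        raise DataError("a feature is missing in every sample; filter first")
    return FeatureMatrix(filled, matrix.sex, matrix.tiles, detected)
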