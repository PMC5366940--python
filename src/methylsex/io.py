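"""Per-cytosine methylation calls: data model, file I/O and filtering.

Two Bismark-style text dialects are supported:

``coverage``
    6 columns: chrom, start (1-based), end (1-based inclusive),
    methylation %, count methylated, count unmethylated.  Carries no
    strand or context, so reading requires a ``context_map``.
``cx``
    7 columns (cytosine-report style): chrom, pos (1-based), strand,
    count methylated, count unmethylated, context, trinucleotide.

Internally every position is 0-based; conversion happens only at the I/O
boundary.  The per-cytosine methylation ratio is #Cs/(#Cs + #Ts) and is
*undefined* (NaN), never 0, at zero coverage.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ParseError
from .genome import CONTEXTS

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]
SEXES = ("F", "M", "unknown")


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine position with methylated (#Cs) / unmethylated (#Ts) counts."""

    chrom: str
    pos: int
    strand: str
    context: str
    meth: int
    unmeth: int

    def __post_init__(self):
        if self.meth < 0 or self.unmeth < 0:
            raise DataError("negative counts")
        if self.context not in CONTEXTS:
            raise DataError(f"bad context {self.context!r}")

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth


def methylation_ratio(call) -> float:
    """#Cs / (#Cs + #Ts); NaN when coverage is zero (undefined, not 0)."""
    cov = call.meth + call.unmeth
    return call.meth / cov if cov > 0 else float("nan")


@dataclass
class MethylomeSample:
    """One sample's cytosine calls plus its metadata.

    ``calls`` is a DataFrame with columns chrom, pos, strand, context,
    meth, unmeth; (chrom, pos, strand) keys are unique.
    """

    sample_id: str
    calls: pd.DataFrame
    sex: str = "unknown"
    genotype: str = ""
    site: str = ""

    def __post_init__(self):
        if self.sex not in SEXES:
            raise DataError(f"sex must be one of {SEXES}, got {self.sex!r}")
        c = self.calls
        missing = [col for col in CALL_COLUMNS if col not in c.columns]
        if missing:
            raise DataError(f"calls missing columns {missing}")
        if c.duplicated(["chrom", "pos", "strand"]).any():
            raise DataError(f"{self.sample_id}: duplicate (chrom, pos, strand) keys")

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def ratios(self) -> pd.Series:
        """Per-call methylation ratio; NaN at zero coverage."""
        cov = self.calls["meth"] + self.calls["unmeth"]
        with np.errstate(invalid="ignore"):
            return self.calls["meth"] / cov.where(cov > 0)

    def with_calls(self, calls: pd.DataFrame) -> "MethylomeSample":
        return replace(self, calls=calls.reset_index(drop=True))


def filter_coverage(sample: MethylomeSample, min_coverage: int = 10) -> MethylomeSample:
    """Retain calls with coverage strictly greater than ``min_coverage``.

    The default reproduces the standard >10x pre-filter: a call covered by
    exactly 10 reads is removed.
    """
    if min_coverage < 0:
        raise ConfigurationError("min_coverage must be >= 0")
    cov = sample.calls["meth"] + sample.calls["unmeth"]
    return sample.with_calls(sample.calls[cov > min_coverage])


def split_by_context(sample: MethylomeSample) -> dict[str, MethylomeSample]:
    """Partition a sample into CG, CHG and CHH sub-samples."""
    if sample.calls["context"].isna().any():
        raise DataError(f"{sample.sample_id}: calls without context label")
    bad = set(sample.calls["context"]) - set(CONTEXTS)
    if bad:
        raise DataError(f"{sample.sample_id}: unknown context labels {sorted(bad)}")
    return {
        ctx: sample.with_calls(sample.calls[sample.calls["context"] == ctx])
        for ctx in CONTEXTS
    }


def merge_symmetric_cpg(sample: MethylomeSample) -> MethylomeSample:
    """Sum the two strands of each CpG dyad into one plus-strand call.

    A dyad is a plus-strand CG at ``pos`` and a minus-strand CG at
    ``pos + 1``.  Non-CG calls and unpaired CG calls pass through
    unchanged.  Off by default throughout the package.
    """
    c = sample.calls
    cg = c[c["context"] == "CG"]
    rest = c[c["context"] != "CG"]
    plus = cg[cg["strand"] == "+"]
    minus = cg[cg["strand"] == "-"].copy()
    minus["pos"] -= 1
    merged = pd.concat([plus, minus], ignore_index=True)
    agg = (
        merged.groupby(["chrom", "pos"], as_index=False)
        .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum"))
        .assign(strand="+", context="CG")
    )
    out = pd.concat([agg[CALL_COLUMNS], rest[CALL_COLUMNS]], ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="stable")
    return sample.with_calls(out)


# ---------------------------------------------------------------------------
# file I/O


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_coverage_file(
    sample: MethylomeSample, path, dialect: str = "cx"
) -> Path:
    """Write a sample's calls in the ``coverage`` or ``cx`` dialect.

    Gzip is used when the path ends in ``.gz``.
    """
    path = Path(path)
    c = sample.calls.sort_values(["chrom", "pos", "strand"], kind="stable")
    with _open(path, "wt") as fh:
        if dialect == "cx":
            for row in c.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.meth}"
                    f"\t{row.unmeth}\t{row.context}\t{row.context}N\n"
                )
        elif dialect == "coverage":
            for row in c.itertuples(index=False):
                cov = row.meth + row.unmeth
                pct = 100.0 * row.meth / cov if cov else 0.0
                fh.write(
                    f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:.6g}"
                    f"\t{row.meth}\t{row.unmeth}\n"
                )
        else:
            raise ConfigurationError(f"unknown dialect {dialect!r}")
    return path


def read_coverage_file(
    path,
    context_map: pd.DataFrame | None = None,
    sample_id: str | None = None,
    sex: str = "unknown",
    genotype: str = "",
    site: str = "",
) -> MethylomeSample:
    """Read a per-cytosine call file, auto-detecting the dialect.

    The dialect is detected from the column count of the first row
    (6 = coverage, 7 = cx).  The coverage dialect carries no strand or
    context, so ``context_map`` (a DataFrame with columns chrom, pos,
    strand, context, e.g. ``GenomeLayout.sites``) is required for it.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    rows = []
    dialect = None
    with _open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if dialect is None:
                if len(parts) == 6:
                    dialect = "coverage"
                elif len(parts) == 7:
                    dialect = "cx"
                else:
                    raise ParseError(
                        f"unrecognised column count {len(parts)}", path, ln
                    )
            try:
                if dialect == "coverage":
                    chrom, start, _end, _pct, meth, unmeth = parts
                    rows.append((chrom, int(start) - 1, None, None,
                                 int(meth), int(unmeth)))
                else:
                    chrom, pos, strand, meth, unmeth, ctx = parts[:6]
                    rows.append((chrom, int(pos) - 1, strand, ctx,
                                 int(meth), int(unmeth)))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"malformed row: {exc}", path, ln) from exc
    if not rows:
        logger.warning("%s: empty call file", path)
        calls = pd.DataFrame(columns=CALL_COLUMNS)
        return MethylomeSample(sample_id, calls, sex=sex, genotype=genotype, site=site)

    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if dialect == "coverage":
        if context_map is None:
            raise ConfigurationError(
                "coverage dialect carries no strand/context; pass context_map"
            )
        cm = context_map[["chrom", "pos", "strand", "context"]]
        calls = calls.drop(columns=["strand", "context"]).merge(
            cm, on=["chrom", "pos"], how="left"
        )[CALL_COLUMNS]
        if calls["context"].isna().any():
            n = int(calls["context"].isna().sum())
            raise DataError(f"{path}: {n} positions absent from context_map")
    calls = calls.sort_values(["chrom", "pos", "strand"], kind="stable")
    return MethylomeSample(
        sample_id, calls.reset_index(drop=True), sex=sex, genotype=genotype, site=site
    )


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata table (TSV: sample, sex, genotype, site)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "sex"}
    if not required.issubset(meta.columns):
        raise DataError(f"metadata must have columns {sorted(required)}")
    bad = set(meta["sex"]) - set(SEXES)
    if bad:
        raise DataError(f"metadata has sex labels outside {SEXES}: {sorted(bad)}")
    return meta


def write_metadata(samples: list[MethylomeSample], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "sample": [s.sample_id for s in samples],
            "sex": [s.sex for s in samples],
            "genotype": [s.genotype for s in samples],
            "site": [s.site for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
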