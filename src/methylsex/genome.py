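"""Synthetic genome layouts: chromosomes, gene models and cytosine sites.

A :class:`GenomeLayout` is the scaffold on which methylomes are simulated:
a set of chromosomes, a collection of gene models (one of which is flagged
as the sex-linked gene on the sex-determining-region chromosome), and a
table of cytosine positions with strand and sequence context (CG, CHG or
CHH).  CG sites are emitted as symmetric dyads (plus-strand cytosine at
``pos``, minus-strand cytosine at ``pos + 1``), mirroring the palindromic
CpG dinucleotide; CHG and CHH sites are placed on a random strand.

All coordinates are 0-based, half-open.  Layout construction is fully
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SizingError

CONTEXTS = ("CG", "CHG", "CHH")

#: default width of the putative promoter window upstream of the TSS (bp)
DEFAULT_PROMOTER_BP = 2000


@dataclass(frozen=True)
class GeneModel:
    """A gene with exons, derived introns and an upstream promoter window.

    Exons are stored in genomic order as 0-based half-open intervals;
    feature numbering (``exon_1``, ``intron_1``, ...) follows the direction
    of transcription, so for a minus-strand gene ``intron_1`` is the last
    genomic gap.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    promoter_bp: int = DEFAULT_PROMOTER_BP

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"bad strand {self.strand!r}")
        ex = self.exons
        if not ex:
            raise ConfigurationError(f"gene {self.gene_id} has no exons")
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ConfigurationError(
                    f"gene {self.gene_id}: exons must be ordered and non-overlapping"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic-order gaps between consecutive exons."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def promoter(self) -> tuple[int, int]:
        """Upstream window of the TSS; clipped at 0 on the plus strand."""
        if self.strand == "+":
            return (max(0, self.start - self.promoter_bp), self.start)
        return (self.end, self.end + self.promoter_bp)

    def features(self) -> list[tuple[str, int, int]]:
        """(label, start, end) for promoter, exons and introns.

        Numbering follows transcription direction.
        """
        ex = list(self.exons)
        intr = list(self.introns)
        if self.strand == "-":
            ex = ex[::-1]
            intr = intr[::-1]
        out = [("promoter", *self.promoter)]
        out += [(f"exon_{i + 1}", s, e) for i, (s, e) in enumerate(ex)]
        out += [(f"intron_{i + 1}", s, e) for i, (s, e) in enumerate(intr)]
        return out

    def feature(self, label: str) -> tuple[int, int]:
        for lab, s, e in self.features():
            if lab == label:
                return (s, e)
        raise KeyError(f"gene {self.gene_id} has no feature {label!r}")


@dataclass
class GenomeLayout:
    """Chromosomes, genes and cytosine sites of a synthetic genome."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]
    sites: pd.DataFrame  # columns: chrom, pos, strand, context
    sdr_gene_id: str | None = None
    seed: int | None = None
    _by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}
        lengths = dict(self.chromosomes)
        for g in self.genes:
            if g.end > lengths[g.chrom]:
                raise SizingError(
                    f"gene {g.gene_id} ends at {g.end} beyond {g.chrom} "
                    f"length {lengths[g.chrom]}"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    @property
    def sdr_gene(self) -> GeneModel:
        if self.sdr_gene_id is None:
            raise ConfigurationError("layout has no flagged SDR gene")
        return self.gene(self.sdr_gene_id)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    n_exons: int,
    strand: str,
) -> GeneModel:
    exon_lens = rng.integers(120, 260, size=n_exons)
    intron_lens = rng.integers(150, 420, size=n_exons - 1)
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        pos = exons[-1][1]
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return GeneModel(gene_id, chrom, strand, tuple(exons))


def build_genome(
    n_chrom: int = 19,
    chrom_length: int = 80_000,
    cytosine_density: float = 24.0,
    genes_per_chrom: int = 2,
    sdr_panel_size: int = 13,
    n_exons: int = 6,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    seed: int = 0,
) -> GenomeLayout:
    """Build a deterministic synthetic genome layout.

    Parameters
    ----------
    n_chrom
        Number of chromosomes (``chr1`` ... ``chrN``); the last one plays
        the role of the sex-determining-region (SDR) chromosome.
    chrom_length
        Length of every chromosome in bp.
    cytosine_density
        Cytosine site events per kb (a CG event contributes the two
        strands of the dyad).
    genes_per_chrom
        Genes placed on each non-SDR chromosome.
    sdr_panel_size
        Genes placed on the SDR chromosome; the middle one is flagged as
        the sex-linked gene.
    n_exons
        Exons per gene; must be >= 5 so introns 1, 4 and 5 exist for the
        sex-linked gene.

    Returns
    -------
    GenomeLayout
        Identical layouts for identical arguments (seeded RNG).
    """
    if min(n_chrom, chrom_length, genes_per_chrom, sdr_panel_size) <= 0:
        raise ConfigurationError("all genome counts must be positive")
    if cytosine_density <= 0:
        raise ConfigurationError("cytosine_density must be positive")
    if n_exons < 5:
        raise ConfigurationError("n_exons must be >= 5 so introns 1/4/5 exist")

    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]
    sdr_chrom = chroms[-1][0]

    genes: list[GeneModel] = []
    sdr_gene_id = None
    for ci, (chrom, length) in enumerate(chroms):
        n_genes = sdr_panel_size if chrom == sdr_chrom else genes_per_chrom
        # tandem placement with promoter-sized leading gaps
        slot = length // n_genes
        for gi in range(n_genes):
            strand = "+" if rng.random() < 0.5 else "-"
            start = gi * slot + promoter_bp + int(rng.integers(0, 200))
            gene = _make_gene(
                rng, f"gene{ci + 1:02d}.{gi + 1:02d}", chrom, start, n_exons, strand
            )
            g = GeneModel(gene.gene_id, chrom, strand, gene.exons, promoter_bp)
            if g.end > (gi + 1) * slot or g.end > length:
                raise SizingError(
                    f"gene {g.gene_id} (span {g.start}-{g.end}) does not fit "
                    f"in its {slot} bp slot on {chrom} (length {length})"
                )
            genes.append(g)
            if chrom == sdr_chrom and gi == n_genes // 2:
                sdr_gene_id = g.gene_id

    frames = []
    for chrom, length in chroms:
        n_events = int(round(cytosine_density * length / 1000))
        # even-grid placement guarantees >=2 bp spacing so CG dyads never collide
        grid = np.arange(0, length - 2, 2)
        if n_events > grid.size:
            raise ConfigurationError(
                f"cytosine_density {cytosine_density} too high for length {length}"
            )
        pos = np.sort(rng.choice(grid, size=n_events, replace=False))
        ctx = rng.choice(CONTEXTS, size=n_events, p=(0.35, 0.30, 0.35))
        strand = np.where(rng.random(n_events) < 0.5, "+", "-")
        strand[ctx == "CG"] = "+"
        df = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "strand": strand, "context": ctx}
        )
        cg = df[df["context"] == "CG"].copy()
        cg["pos"] += 1
        cg["strand"] = "-"
        frames.append(pd.concat([df, cg], ignore_index=True))
    sites = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["chrom", "pos", "strand"], kind="stable")
        .reset_index(drop=True)
    )
    return GenomeLayout(chroms, genes, sites, sdr_gene_id=sdr_gene_id, seed=seed)
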