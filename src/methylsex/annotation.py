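"""Gene annotation: GFF3 reading/writing and interval queries.

GFF3 coordinates are 1-based inclusive; everything in memory is 0-based
half-open.  Introns are derived as the gaps between consecutive exons and
the promoter as a fixed window upstream of the TSS, exactly as in
:mod:`methylsex.genome`.
"""

from __future__ import annotations

from pathlib import Path

import gffutils

from .errors import DataError
from .genome import DEFAULT_PROMOTER_BP, GeneModel

__all__ = ["GeneAnnotation", "read_gff3", "write_gff3"]


class GeneAnnotation:
    """A queryable collection of :class:`GeneModel`.

    Query results are independent of insertion order (genes are kept
    sorted by id).
    """

    def __init__(self, genes: list[GeneModel]):
        self.genes = sorted(genes, key=lambda g: g.gene_id)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise DataError("duplicate gene ids in annotation")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def overlapping(self, chrom: str, start: int, end: int,
                    include_promoter: bool = True) -> list[GeneModel]:
        """Genes whose span (optionally including the promoter) overlaps
        [start, end) on ``chrom``."""
        out = []
        for g in self.genes:
            if g.chrom != chrom:
                continue
            s, e = g.start, g.end
            if include_promoter:
                ps, pe = g.promoter
                s, e = min(s, ps), max(e, pe)
            if s < end and start < e:
                out.append(g)
        return out


def write_gff3(genes: list[GeneModel], path) -> Path:
    """Write gene/mRNA/exon features in GFF3 (1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            base = f"{g.chrom}\tmethylsex\t"
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{base}gene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.gene_id}.mRNA"
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={mid}\n"
                )
    return path


def read_gff3(path, promoter_bp: int = DEFAULT_PROMOTER_BP) -> GeneAnnotation:
    """Read gene/mRNA/exon features into a :class:`GeneAnnotation`.

    Exons are collected per gene (via their mRNA parent when present);
    an exon outside its gene's span is a structural error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons = []
        for exon in db.children(gene, featuretype="exon"):
            s, e = exon.start - 1, exon.end  # to 0-based half-open
            if s < gene.start - 1 or e > gene.end:
                raise DataError(
                    f"exon {s}-{e} outside gene {gene.id} span "
                    f"{gene.start - 1}-{gene.end}"
                )
            exons.append((s, e))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        exons = sorted(set(exons))
        genes.append(
            GeneModel(gene.id, gene.seqid, gene.strand, tuple(exons), promoter_bp)
        )
    return GeneAnnotation(genes)
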