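"""TSS-relative coordinate system for a single gene locus.

Positions are signed base offsets from the transcription start site, with
positive values running 5'->3' into (and beyond) the gene body and negative
values on the promoter side. On a minus-strand gene such as MECP2 this means
``relative = TSS - genomic``; on a plus-strand gene ``relative = genomic - TSS``.

This convention is fixed by the published segment coordinates themselves:
the accessibility fragment containing the MECP2 core promoter and exon 1
sits at -0.5-0.1 kb while the fragment containing the IRAK1 promoter (a gene
3' of MECP2) sits at +77.7-77.9 kb; both are consistent only with
positive = transcription direction.

Relative positions are reported in kb at 0.1 kb precision where the
fragment catalogue is concerned; all arithmetic is in integer bases.
"""

from __future__ import annotations

from dataclasses import dataclass

from .locus import GeneModel


@dataclass(frozen=True)
class RelativeInterval:
    """A TSS-relative interval in signed kilobases, e.g. the S/A/B/H fragments."""

    start_kb: float
    end_kb: float
    label: str
    assembly: str

    def __post_init__(self) -> None:
        if self.start_kb > self.end_kb:
            raise ValueError(f"{self.label}: start_kb > end_kb after normalization")

    @property
    def start_b(self) -> int:
        return int(round(self.start_kb * 1000))

    @property
    def end_b(self) -> int:
        return int(round(self.end_kb * 1000))

    @property
    def length_b(self) -> int:
        return self.end_b - self.start_b


def genomic_to_relative(coord: int, gene: GeneModel, assembly: str) -> int:
    """Signed base offset of a genomic position from the gene's TSS anchor."""
    tss = gene.tss_for(assembly)
    return tss - coord if gene.strand == "-" else coord - tss


def relative_to_genomic(rel: int, gene: GeneModel, assembly: str) -> int:
    """Exact inverse of :func:`genomic_to_relative`."""
    tss = gene.tss_for(assembly)
    return tss - rel if gene.strand == "-" else tss + rel


def classify_position(interval: RelativeInterval, gene: GeneModel) -> str:
    """Locate a TSS-relative interval against the gene body.

    Returns one of ``intragenic`` (fully within [0, gene length)),
    ``upstream_of_tss`` (fully negative), ``beyond_gene_3prime`` (fully past
    the 3' end), or ``spanning`` (crosses the TSS or the 3' boundary).
    """
    gene_len = gene.length
    start, end = interval.start_b, interval.end_b
    if end <= 0:
        return "upstream_of_tss"
    if start >= gene_len:
        return "beyond_gene_3prime"
    if start >= 0 and end <= gene_len:
        return "intragenic"
    return "spanning"
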