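"""Gene locus model, cis-regulatory elements, and transcript-catalogue tables.

The central object is :class:`GeneModel`: an ordered multi-exon gene with
per-assembly transcription start site (TSS) anchors. For the human MECP2
locus the anchors are the first nucleotide of exon 1: hg19 chrX:153,363,188
and hg38 chrX:154,097,717. MECP2 is transcribed from the minus strand, so
exon 1 carries the greatest genomic coordinates.

Transcript catalogue mirrors (NCBI mRNA variants, UniProt/Ensembl protein
isoform entries) are shipped as TSV fixtures under ``mecp2locus/data`` and
parsed into :class:`TranscriptRecord`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .io import FormatError, read_fasta

VALID_ROLES = {"enhancer", "silencer", "promoter"}
VALID_REVIEW = {"reviewed", "unreviewed"}
VALID_BIOTYPES = {"protein coding", "nonsense mediated decay", "other"}
VALID_CDS_INCOMPLETE = {"none", "5prime", "3prime", "both"}
VALID_SOURCES = {"NCBI", "UniProt/Ensembl"}

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

REQUIRED_TABLE_COLUMNS = [
    "accession",
    "source_db",
    "product_isoform",
    "review_status",
    "evidence",
    "biotype",
    "tsl",
    "cds_incomplete",
]


@dataclass(frozen=True)
class GeneModel:
    """A multi-exon gene with TSS anchors.

    ``exons`` are (start, end) 1-based inclusive genomic intervals, ordered
    5'->3' in transcription direction (descending genomic position on the
    minus strand). ``tss_by_assembly`` maps assembly name to the genomic
    coordinate of the transcription-direction first nucleotide of exon 1.
    """

    name: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    tss_by_assembly: dict[str, int] = field(default_factory=dict)
    exon_assembly: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon with start > end: ({start}, {end})")
        ordered = list(self.exons)
        if self.strand == "+":
            ok = all(a[1] < b[0] for a, b in zip(ordered, ordered[1:]))
        else:
            ok = all(a[0] > b[1] for a, b in zip(ordered, ordered[1:]))
        if not ok:
            raise ValueError("exons must be non-overlapping and ordered 5'->3' in transcription direction")

    @property
    def tss(self) -> int:
        """TSS in exon coordinates: transcription-direction first base of exon 1."""
        first = self.exons[0]
        return first[1] if self.strand == "-" else first[0]

    def tss_for(self, assembly: str) -> int:
        try:
            return self.tss_by_assembly[assembly]
        except KeyError:
            raise KeyError(
                f"gene {self.name!r} has no TSS anchor for assembly {assembly!r}; "
                f"known: {sorted(self.tss_by_assembly)}"
            ) from None

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min, max) over all exons."""
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def length(self) -> int:
        """Gene span length in bases (TSS-relative 0 .. length-1 is intragenic)."""
        lo, hi = self.span
        return hi - lo + 1

    def intron(self, k: int) -> tuple[int, int]:
        """Genomic interval of intron k (between exon k and exon k+1), 1-based."""
        if not 1 <= k < len(self.exons):
            raise ValueError(f"gene has {len(self.exons)} exons; no intron {k}")
        a, b = self.exons[k - 1], self.exons[k]
        if self.strand == "-":
            return (b[1] + 1, a[0] - 1)
        return (a[1] + 1, b[0] - 1)


@dataclass(frozen=True)
class CisRegulatoryElement:
    name: str
    role: str
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {sorted(VALID_ROLES)}, got {self.role!r}")
        if self.interval[0] > self.interval[1]:
            raise ValueError(f"interval start > end: {self.interval}")


@dataclass(frozen=True)
class TranscriptRecord:
    accession: str
    source_db: str
    product_isoform: str | None
    review_status: str
    evidence: str
    biotype: str
    tsl: int | None
    cds_incomplete: str
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source_db not in VALID_SOURCES:
            raise ValueError(f"unknown source_db {self.source_db!r}")
        if self.review_status not in VALID_REVIEW:
            raise ValueError(f"unknown review_status {self.review_status!r}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.cds_incomplete not in VALID_CDS_INCOMPLETE:
            raise ValueError(f"unknown cds_incomplete {self.cds_incomplete!r}")
        if self.review_status == "reviewed" and not self.evidence:
            raise ValueError(f"{self.accession}: reviewed record with empty evidence")
        if self.tsl is not None and not 1 <= self.tsl <= 5:
            raise ValueError(f"{self.accession}: TSL must be 1..5, got {self.tsl}")


@dataclass(frozen=True)
class ProteinIsoform:
    id: str
    sequence: str
    source_db: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"isoform {self.id!r} has an empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"isoform {self.id!r} contains non-amino-acid symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Transcript catalogue tables


def _parse_cell(value: str) -> str | None:
    value = value.strip()
    return None if value in {"-", ""} else value


def parse_transcript_table(path_or_handle) -> list[TranscriptRecord]:
    """Parse a TSV transcript-catalogue mirror into TranscriptRecords.

    The header row is required; ``-`` cells parse as missing. Extra columns
    are preserved in ``record.extra`` so re-serialization is lossless.
    """
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        lines = Path(path_or_handle).read_text().splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise FormatError("transcript table has no header row")
    header = rows[0].rstrip("\n").split("\t")
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in header:
            raise FormatError(f"transcript table is missing required column {col!r}")
    extras = [c for c in header if c not in REQUIRED_TABLE_COLUMNS]
    records: list[TranscriptRecord] = []
    for n, raw in enumerate(rows[1:], start=2):
        cells = raw.rstrip("\n").split("\t")
        if len(cells) != len(header):
            raise FormatError(f"row {n}: expected {len(header)} columns, got {len(cells)}")
        row = dict(zip(header, cells))
        tsl_cell = _parse_cell(row["tsl"])
        try:
            tsl = int(tsl_cell) if tsl_cell is not None else None
            record = TranscriptRecord(
                accession=row["accession"].strip(),
                source_db=row["source_db"].strip(),
                product_isoform=_parse_cell(row["product_isoform"]),
                review_status=row["review_status"].strip(),
                evidence=_parse_cell(row["evidence"]) or "",
                biotype=row["biotype"].strip(),
                tsl=tsl,
                cds_incomplete=_parse_cell(row["cds_incomplete"]) or "none",
                extra={c: row[c] for c in extras},
            )
        except ValueError as exc:
            raise FormatError(f"row {n}: {exc}") from exc
        records.append(record)
    return records


def write_transcript_table(path_or_handle, records: list[TranscriptRecord]) -> None:
    """Serialize records back to TSV, field-for-field inverse of the parser."""
    extras = sorted({k for rec in records for k in rec.extra})
    header = REQUIRED_TABLE_COLUMNS + extras

    def _cell(value) -> str:
        if value is None or value == "" or value == "none":
            return "-"
        return str(value)

    def _emit(handle) -> None:
        handle.write("\t".join(header) + "\n")
        for rec in records:
            row = [
                rec.accession,
                rec.source_db,
                _cell(rec.product_isoform),
                rec.review_status,
                _cell(rec.evidence),
                rec.biotype,
                _cell(rec.tsl),
                _cell(rec.cds_incomplete),
            ] + [rec.extra.get(c, "-") for c in extras]
            handle.write("\t".join(row) + "\n")

    if hasattr(path_or_handle, "write"):
        _emit(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _emit(fh)


def summarize_products(records: list[TranscriptRecord]) -> tuple[dict[str, int], list[str]]:
    """Count transcripts per protein-isoform product.

    Returns ``(counts, without_product)`` where ``counts`` maps each product
    isoform to the number of transcripts encoding it and ``without_product``
    lists accessions that declare no product (excluded from the counts).
    """
    sources = {rec.source_db for rec in records}
    if len(sources) > 1:
        raise ValueError(f"records from multiple source databases: {sorted(sources)}")
    counts: Counter[str] = Counter()
    without: list[str] = []
    for rec in records:
        if rec.product_isoform is None:
            without.append(rec.accession)
        else:
            counts[rec.product_isoform] += 1
    return dict(counts), without


def read_protein_fasta(path_or_handle, source_db: str = "") -> list[ProteinIsoform]:
    """FASTA -> ProteinIsoform list (validates the 20-letter alphabet)."""
    return [
        ProteinIsoform(id=rec.id, sequence=rec.sequence, source_db=source_db)
        for rec in read_fasta(path_or_handle)
    ]


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_path(name: str):
    return resources.files("mecp2locus.data").joinpath(name)


def load_ncbi_transcripts() -> list[TranscriptRecord]:
    """The packaged NCBI MECP2 mRNA variant catalogue (10 records)."""
    with _data_path("ncbi_transcripts.tsv").open() as fh:
        return parse_transcript_table(fh)


def load_uniprot_isoform_records() -> list[TranscriptRecord]:
    """The packaged UniProt/Ensembl MeCP2 isoform catalogue (10 records)."""
    with _data_path("uniprot_isoforms.tsv").open() as fh:
        return parse_transcript_table(fh)


def mecp2_gene_model() -> GeneModel:
    """Human MECP2 gene model with the hg19/hg38 TSS anchors.

    Exon intervals are approximate (the package only relies on the TSS
    anchors and the overall gene span); both TSS anchors are the display
    coordinates of the first nucleotide of exon 1.
    """
    return GeneModel(
        name="MECP2",
        chromosome="chrX",
        strand="-",
        exons=(
            (153_362_839, 153_363_188),  # exon 1 (5'UTR + CDS start)
            (153_361_100, 153_361_224),
            (153_359_800, 153_360_124),
            (153_287_263, 153_295_800),  # exon 4 incl. long 3'UTR
        ),
        tss_by_assembly={"hg19": 153_363_188, "hg38": 154_097_717},
        exon_assembly="hg19",
    )
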