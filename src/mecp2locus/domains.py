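"""Projection of reference functional domains onto isoforms.

Each functional domain is an interval in reference-isoform protein
coordinates (MBD, TRD, the HMG-like domains, NLS1/2, the AT-hooks, the
interaction sequences, and the C-terminal domains). A domain's status in a
query isoform is read off the global alignment: a reference position counts
as matched only when the aligned query residue is identical and - when exon
provenance is available for both sequences - derives from the same exon as
the reference position. This provenance gate prevents residues of a novel
(e.g. intron-translated) fragment from masquerading as domain sequence
through chance identities.

Status vocabulary mirrors the isoform-catalogue summary tables: complete,
missing, N-/C-terminally incomplete, internal gap, and "possible different
N-terminus" for domains whose N-terminal part is replaced by alternative
sequence rather than deleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import PairwiseAlignment, ProvenanceTrack, exon_provenance, global_align
from .locus import ProteinIsoform

CATEGORY_VOCAB = {
    "complete": "✓",
    "missing": "-",
    "n_incomplete": "N-term. incompl.",
    "c_incomplete": "C-term. incompl.",
    "n_and_c_incomplete": "N-term. and C-term. incompl.",
    "internal_gap": "missing fragment inside",
    "internal_gap_c_incomplete": "C-term. incompl., missing fragment inside",
    "alternative_n_terminus": "Possible different N-terminus",
}

# exon_presence uses the same geometry; only the words differ
PRESENCE_VOCAB = {**CATEGORY_VOCAB, "complete": "✓", "missing": "-"}


@dataclass(frozen=True)
class FunctionalDomain:
    name: str
    ref_isoform: str
    start: int  # 1-based inclusive, reference protein coordinates
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.name}: invalid domain interval ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainStatus:
    category: str
    coverage: float
    matched_span: tuple[int, int] | None

    @property
    def cell(self) -> str:
        return CATEGORY_VOCAB[self.category]


def _status_from_matched(
    matched: set[int],
    start: int,
    end: int,
    missing_threshold: float,
    has_alternative_n: bool = False,
) -> DomainStatus:
    """Shared geometry rule: classify an interval from its matched positions."""
    length = end - start + 1
    coverage = len(matched) / length
    span = (min(matched), max(matched)) if matched else None
    if coverage == 1.0:
        return DomainStatus("complete", 1.0, span)
    if coverage <= missing_threshold:
        return DomainStatus("missing", coverage, span)
    unmatched = [p for p in range(start, end + 1) if p not in matched]
    runs: list[tuple[int, int]] = []
    run_start = prev = unmatched[0]
    for p in unmatched[1:]:
        if p != prev + 1:
            runs.append((run_start, prev))
            run_start = p
        prev = p
    runs.append((run_start, prev))
    has_prefix = runs[0][0] == start
    has_suffix = runs[-1][1] == end
    interior = [r for r in runs if not (r[0] == start or r[1] == end)]
    if interior:
        category = "internal_gap_c_incomplete" if has_suffix else "internal_gap"
    elif has_prefix and has_suffix:
        category = "n_and_c_incomplete"
    elif has_prefix:
        category = "alternative_n_terminus" if has_alternative_n else "n_incomplete"
    else:
        category = "c_incomplete"
    return DomainStatus(category, coverage, span)


def classify_domain(
    aln: PairwiseAlignment,
    domain: FunctionalDomain,
    missing_threshold: float = 0.1,
    ref_provenance: ProvenanceTrack | None = None,
    query_provenance: ProvenanceTrack | None = None,
) -> DomainStatus:
    """Completeness status of one reference domain in the aligned query."""
    if aln.ref_id != domain.ref_isoform:
        raise ValueError(
            f"alignment reference {aln.ref_id!r} does not carry domain annotation "
            f"reference {domain.ref_isoform!r}"
        )
    ref_seq = aln.ref_sequence
    if domain.end > len(ref_seq):
        raise ValueError(f"domain {domain.name} extends past the reference ({domain.end} > {len(ref_seq)})")
    query_seq = aln.query_sequence

    def _exon_of(track: ProvenanceTrack | None, pos: int) -> int | None:
        if track is None or pos is None:
            return None
        return track.labels[pos - 1][0]

    matched: set[int] = set()
    col_of_ref: dict[int, int] = {}
    for col, (rp, qp) in enumerate(aln.column_map):
        if rp is not None:
            col_of_ref[rp] = col
        if rp is None or qp is None or not domain.start <= rp <= domain.end:
            continue
        if ref_seq[rp - 1] != query_seq[qp - 1]:
            continue
        if ref_provenance is not None and query_provenance is not None:
            if _exon_of(ref_provenance, rp) != _exon_of(query_provenance, qp):
                continue
        matched.add(rp)

    # Alternative-N detection: does the query place residues in the columns of
    # the unmatched domain prefix (substituted or inserted ahead of the first
    # match), rather than simply starting at the first matched position?
    has_alt_n = False
    if matched and domain.start not in matched:
        first_match = min(matched)
        lo = col_of_ref.get(domain.start, 0)
        hi = col_of_ref[first_match]
        for col in range(lo, hi):
            rp, qp = aln.column_map[col]
            if qp is not None and rp not in matched:
                has_alt_n = True
                break
    return _status_from_matched(matched, domain.start, domain.end, missing_threshold, has_alt_n)


def exon_presence(
    provenance: ProvenanceTrack,
    exon_peptides: dict[int, str],
    missing_threshold: float = 0.1,
) -> dict[int, DomainStatus]:
    """Per-exon presence status of an isoform from its provenance track.

    Coverage is measured over the full exon peptide: an isoform carrying
    only a suffix of an exon's translation is N-terminally incomplete for
    that exon, a prefix C-terminally incomplete, and so on.
    """
    out: dict[int, DomainStatus] = {}
    for exon, peptide in sorted(exon_peptides.items()):
        covered = provenance.exon_peptide_positions(exon)
        out[exon] = _status_from_matched(covered, 1, len(peptide), missing_threshold)
    return out


def build_domain_table(
    isoforms: list[ProteinIsoform],
    domains: list[FunctionalDomain],
    reference: ProteinIsoform,
    exon_peptides: dict[int, str],
    missing_threshold: float = 0.1,
    min_anchor: int = 6,
) -> pd.DataFrame:
    """Isoform x (exon/domain) status matrix in the table vocabulary.

    Rows are ``Exon 1..n`` followed by the domain names; columns are isoform
    ids; cells use the summary-table vocabulary ("✓", "-", "N-term.
    incompl.", ...). Exon rows come from provenance, domain rows from the
    provenance-gated alignment against the annotated reference.
    """
    for domain in domains:
        if domain.ref_isoform != reference.id:
            raise ValueError(f"domain {domain.name} annotated on {domain.ref_isoform!r}, not {reference.id!r}")
    ref_provenance = exon_provenance(reference, exon_peptides, min_anchor=min_anchor)
    exon_rows = [f"Exon {k}" for k in sorted(exon_peptides)]
    rows = exon_rows + [d.name for d in domains]
    table = pd.DataFrame(index=rows, columns=[iso.id for iso in isoforms], dtype=object)
    for iso in isoforms:
        prov = exon_provenance(iso, exon_peptides, min_anchor=min_anchor)
        presence = exon_presence(prov, exon_peptides, missing_threshold)
        for k, status in presence.items():
            table.loc[f"Exon {k}", iso.id] = status.cell
        aln = global_align(reference, iso)
        for domain in domains:
            status = classify_domain(
                aln,
                domain,
                missing_threshold=missing_threshold,
                ref_provenance=ref_provenance,
                query_provenance=prov,
            )
            table.loc[domain.name, iso.id] = status.cell
    return table


def discrepancy_report(computed: pd.DataFrame, expected: pd.DataFrame) -> list[tuple[str, str, str, str]]:
    """Cells where the computed matrix differs from an expectation matrix.

    Returns (row, column, expected, computed) tuples; empty means exact
    cell-for-cell agreement.
    """
    if list(computed.index) != list(expected.index) or list(computed.columns) != list(expected.columns):
        raise ValueError("computed and expected matrices must share row/column layout")
    out = []
    for row in expected.index:
        for col in expected.columns:
            exp, got = expected.loc[row, col], computed.loc[row, col]
            if exp != got:
                out.append((row, col, exp, got))
    return out
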