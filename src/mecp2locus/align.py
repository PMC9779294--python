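"""Protein isoform alignment and sequence provenance.

Isoform-versus-reference comparison is done with global pairwise alignment
(Gotoh affine-gap dynamic programming via Bio.Align, BLOSUM62, gap open -10
/ extend -1, so a gap of length k costs 10 + k). Per-residue exon provenance
is assigned by maximal exact matches against the translated exon peptides,
and novel (non-matching) fragments are located in the gene locus by scanning
all six frame translations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .locus import AMINO_ACIDS, GeneModel, ProteinIsoform

Sequence_like = ProteinIsoform | str


def _seq(obj: Sequence_like) -> str:
    return obj.sequence if isinstance(obj, ProteinIsoform) else str(obj)


def _sid(obj: Sequence_like, default: str) -> str:
    return obj.id if isinstance(obj, ProteinIsoform) else default


@dataclass
class PairwiseAlignment:
    """A global alignment of a query isoform against a reference isoform.

    ``column_map`` holds, per alignment column, the 1-based reference and
    query positions (``None`` in a gapped row).
    """

    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float
    column_map: list[tuple[int | None, int | None]] = field(repr=False, default_factory=list)

    @property
    def ref_sequence(self) -> str:
        return self.aligned_ref.replace("-", "")

    @property
    def query_sequence(self) -> str:
        return self.aligned_query.replace("-", "")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # first gap residue costs open+extend, each further residue costs extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    ref: Sequence_like,
    query: Sequence_like,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of ``query`` against ``ref``."""
    ref_seq, query_seq = _seq(ref), _seq(query)
    if not ref_seq or not query_seq:
        raise ValueError("cannot align empty sequences")
    for name, seq in (("ref", ref_seq), ("query", query_seq)):
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{name} contains non-amino-acid symbols: {sorted(bad)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(ref_seq, query_seq)[0]
    aligned_ref, aligned_query = str(alignment[0]), str(alignment[1])
    column_map: list[tuple[int | None, int | None]] = []
    ri = qi = 0
    for a, b in zip(aligned_ref, aligned_query):
        rp = qp = None
        if a != "-":
            ri += 1
            rp = ri
        if b != "-":
            qi += 1
            qp = qi
        column_map.append((rp, qp))
    return PairwiseAlignment(
        ref_id=_sid(ref, "ref"),
        query_id=_sid(query, "query"),
        aligned_ref=aligned_ref,
        aligned_query=aligned_query,
        score=float(alignment.score),
        column_map=column_map,
    )


# ---------------------------------------------------------------------------
# Exon provenance


@dataclass
class ProvenanceTrack:
    """Per-residue exon-of-origin labels for one isoform.

    ``labels[i]`` is ``(exon, peptide_pos)`` for residue i+1, or
    ``(None, None)`` for residues matching no exon peptide ("novel").
    ``novel_segments`` are the maximal novel runs in 1-based isoform
    coordinates.
    """

    isoform_id: str
    labels: list[tuple[int | None, int | None]]

    @property
    def novel_segments(self) -> list[tuple[int, int]]:
        segments = []
        start = None
        for i, (exon, _) in enumerate(self.labels, start=1):
            if exon is None and start is None:
                start = i
            elif exon is not None and start is not None:
                segments.append((start, i - 1))
                start = None
        if start is not None:
            segments.append((start, len(self.labels)))
        return segments

    def exon_peptide_positions(self, exon: int) -> set[int]:
        """1-based positions of the exon peptide covered by this isoform."""
        return {pp for ex, pp in self.labels if ex == exon and pp is not None}


def _maximal_matches(s: str, p: str, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal common substrings of s and p with length >= min_len.

    Returns (s_start, p_start, length) with 0-based starts.
    """
    if not s or not p:
        return []
    s_arr = np.frombuffer(s.encode(), dtype=np.uint8)
    p_arr = np.frombuffer(p.encode(), dtype=np.uint8)
    eq = s_arr[:, None] == p_arr[None, :]
    matches = []
    n, m = len(s), len(p)
    for d in range(-(m - 1), n):  # diagonal offset: s_index - p_index
        diag = np.diagonal(eq, offset=-d)
        if not diag.any():
            continue
        # run-length encode the boolean diagonal
        idx = np.flatnonzero(np.diff(np.concatenate(([0], diag.view(np.int8), [0]))))
        for start, stop in zip(idx[::2], idx[1::2]):
            length = int(stop - start)
            if length < min_len:
                continue
            if d >= 0:
                matches.append((d + int(start), int(start), length))
            else:
                matches.append((int(start), int(start) - d, length))
    return matches


def exon_provenance(
    isoform: Sequence_like,
    exon_peptides: dict[int, str],
    min_anchor: int = 6,
) -> ProvenanceTrack:
    """Label each residue of an isoform with its exon of origin.

    Residues covered by maximal exact matches (>= ``min_anchor`` residues)
    to an exon peptide are labeled with that exon; overlapping candidates are
    resolved by longest match first, then 5'-most exon, then position.
    Unlabeled runs are the novel segments.
    """
    seq = _seq(isoform)
    labels: list[tuple[int | None, int | None]] = [(None, None)] * len(seq)
    candidates: list[tuple[int, int, int, int]] = []  # (length, exon, s_start, p_start)
    for exon in sorted(exon_peptides):
        for s_start, p_start, length in _maximal_matches(seq, exon_peptides[exon], min_anchor):
            candidates.append((length, exon, s_start, p_start))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    for length, exon, s_start, p_start in candidates:
        span = range(s_start, s_start + length)
        if all(labels[i][0] is None for i in span):
            for k, i in enumerate(span):
                labels[i] = (exon, p_start + k + 1)
    return ProvenanceTrack(isoform_id=_sid(isoform, "isoform"), labels=labels)


def format_annotated_alignment(
    aln: PairwiseAlignment,
    query_provenance: ProvenanceTrack,
    width: int = 60,
) -> str:
    """Plain-text alignment with a per-residue exon-provenance annotation line.

    The annotation row marks each query residue with its exon of origin
    (``1``-``9``) or ``*`` for novel residues; gap columns are blank.
    """
    marks = []
    for _, qp in aln.column_map:
        if qp is None:
            marks.append(" ")
        else:
            exon, _ = query_provenance.labels[qp - 1]
            marks.append("*" if exon is None else str(exon))
    lines = [f"# {aln.ref_id} (ref) vs {aln.query_id} (query), score {aln.score:g}"]
    for start in range(0, len(aln.aligned_ref), width):
        end = min(start + width, len(aln.aligned_ref))
        lines.append(f"ref   {start + 1:>5} {aln.aligned_ref[start:end]}")
        lines.append(f"query {start + 1:>5} {aln.aligned_query[start:end]}")
        lines.append(f"exon        {''.join(marks[start:end])}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Terminal comparisons


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _common_suffix_len(a: str, b: str) -> int:
    return _common_prefix_len(a[::-1], b[::-1])


def terminal_diff(iso_a: Sequence_like, iso_b: Sequence_like) -> tuple[int, int, str]:
    """Count the distinctive terminal residues of two isoforms.

    If the sequences share a common suffix at least as long as any common
    prefix, the difference is at the N terminus and the counts are the
    residues of each sequence outside the longest common suffix; the C case
    is symmetric. Two isoforms sharing no terminus at all are an error.
    """
    a, b = _seq(iso_a), _seq(iso_b)
    suf = _common_suffix_len(a, b)
    pre = _common_prefix_len(a, b)
    if suf == 0 and pre == 0:
        raise ValueError("isoforms share no common terminus")
    if suf >= pre:
        return (len(a) - suf, len(b) - suf, "N")
    return (len(a) - pre, len(b) - pre, "C")


def shared_terminal_fragment(iso_a: Sequence_like, iso_b: Sequence_like, terminus: str) -> int:
    """Length of the longest common prefix (N) or suffix (C) of two isoforms."""
    a, b = _seq(iso_a), _seq(iso_b)
    if terminus == "N":
        return _common_prefix_len(a, b)
    if terminus == "C":
        return _common_suffix_len(a, b)
    raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")


# ---------------------------------------------------------------------------
# Locating novel fragments in the locus


@dataclass
class FragmentOrigin:
    """Best genomic origin of a novel peptide fragment.

    ``locus_feature`` is ``("exon", k)`` / ``("intron", k)`` when the best
    six-frame translation hit reaches ``min_identity`` and overlaps that gene
    feature, else ``None``. ``frame`` is 0-2 forward, 3-5 reverse-complement.
    """

    segment: tuple[int, int]
    locus_feature: tuple[str, int] | None
    frame: int
    match_identity: float
    genomic_interval: tuple[int, int] | None = None


def _frame_translations(dna: str) -> list[tuple[int, str]]:
    out = []
    rc = str(Seq(dna).reverse_complement())
    for f in range(3):
        for frame_id, src in ((f, dna), (f + 3, rc)):
            sub = src[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append((frame_id, str(Seq(sub).translate())))
    return sorted(out)


def _hit_genomic_interval(frame: int, aa_offset: int, aa_len: int, locus_len: int) -> tuple[int, int]:
    if frame < 3:
        start = frame + 3 * aa_offset + 1
        return (start, start + 3 * aa_len - 1)
    f = frame - 3
    rc_start = f + 3 * aa_offset  # 0-based on reverse complement
    end = locus_len - rc_start
    return (end - 3 * aa_len + 1, end)


def locate_novel_fragment(
    peptide: str,
    gene: GeneModel,
    dna: str,
    min_identity: float = 0.9,
) -> FragmentOrigin:
    """Find the best gap-free match of a peptide in the six-frame locus translation.

    Identity is exact per-position (Hamming) at each offset; ties are broken
    by the 5'-most genomic start of the hit. The overlapped gene feature
    (exon/intron index, by largest overlap) is reported when identity reaches
    ``min_identity``.
    """
    if len(peptide) < 6:
        raise ValueError("peptide must be at least 6 residues")
    pep = np.frombuffer(peptide.encode(), dtype=np.uint8)
    best = None  # (identity, genomic_start, frame, genomic_interval)
    for frame, trans in _frame_translations(dna):
        if len(trans) < len(pep):
            continue
        t_arr = np.frombuffer(trans.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(t_arr, len(pep))
        identities = (windows == pep).mean(axis=1)
        for off in np.flatnonzero(identities >= identities.max() - 1e-12):
            interval = _hit_genomic_interval(frame, int(off), len(pep), len(dna))
            cand = (float(identities[off]), -interval[0], frame, interval)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    if best is None:
        return FragmentOrigin((1, len(peptide)), None, 0, 0.0)
    identity, _, frame, interval = best
    feature = None
    if identity >= min_identity:
        overlaps: list[tuple[int, tuple[str, int]]] = []
        for k, (s, e) in enumerate(gene.exons, start=1):
            overlaps.append((_overlap(interval, (s, e)), ("exon", k)))
        for k in range(1, len(gene.exons)):
            overlaps.append((_overlap(interval, gene.intron(k)), ("intron", k)))
        ov, feat = max(overlaps, key=lambda t: t[0])
        if ov > 0:
            feature = feat
    return FragmentOrigin(
        segment=(1, len(peptide)),
        locus_feature=feature,
        frame=frame,
        match_identity=identity,
        genomic_interval=interval,
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
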