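"""Synthetic locus, isoform, and track generation with known ground truth.

Everything downstream of the parsers can be validated against data whose
truth is known by construction: a multi-exon gene with translatable exons,
splice-variant protein isoforms built from declarative edit specifications
(so per-residue exon-of-origin and per-domain completeness are exact), and
multi-sample signal/methylation tracks with planted enriched or
hypomethylated segments over Poisson/Beta noise.

Noise models: per-bin Poisson counts for ChIP/DNase/ATAC-style density
tracks (bin size 200 bp by default), with the planted fold applied in
proportion to how much of a bin a planted segment covers; per-bin Beta-
distributed methylation fractions, drawn independently per sample. Variant
edits are declarative, never random, so truth labels are exact.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .domains import DomainStatus, FunctionalDomain, _status_from_matched
from .locus import GeneModel, ProteinIsoform
from .segments import MethylationTrack, SignalTrack

_FORWARD = CodonTable.unambiguous_dna_by_id[1].forward_table
SENSE_CODONS = sorted(_FORWARD)
CODONS_BY_AA: dict[str, list[str]] = {}
for codon in SENSE_CODONS:
    CODONS_BY_AA.setdefault(_FORWARD[codon], []).append(codon)


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class PlantedSegment:
    start: int  # 1-based inclusive, locus coordinates
    end: int
    fold: float
    carried_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ConfigurationError(f"planted segment inverted: ({self.start}, {self.end})")
        if self.fold < 1.0:
            raise ConfigurationError(f"enrichment fold must be >= 1, got {self.fold}")
        if not 0.0 < self.carried_fraction <= 1.0:
            raise ConfigurationError(f"carried_fraction must be in (0, 1], got {self.carried_fraction}")


@dataclass(frozen=True)
class VariantSpec:
    """Declarative splice-variant edit description.

    ``use_exons``: exons contributing coding sequence, in transcription
    order. ``start_met``: begin translation at the n-th Met of an exon's
    peptide (exon, occurrence); default is the first residue of the first
    used exon. ``truncate_after``: stop after a given position of an exon's
    peptide (exon, peptide_pos). ``delete``: drop a peptide-position range
    of one exon (exon, from_pos, to_pos). ``novel_c_term``: append the
    translation of a locus feature ("intron"/"exon", index, frame 0-2 in
    transcription orientation, aa offset, aa length) — or an explicit
    peptide via ``novel_c_peptide``.
    """

    name: str
    use_exons: tuple[int, ...]
    start_met: tuple[int, int] | None = None
    truncate_after: tuple[int, int] | None = None
    delete: tuple[tuple[int, int, int], ...] = ()
    novel_c_term: tuple[str, int, int, int, int] | None = None
    novel_c_peptide: str | None = None


@dataclass
class SimulationConfig:
    seed: int = 0
    locus_length: int = 150_000
    n_exons: int = 4
    strand: str = "-"
    n_tracks: int = 8
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    background_rate: float = 5.0
    bin_size: int = 200
    hmr_regions: list[tuple[int, int]] = field(default_factory=list)
    meth_background_beta: tuple[float, float] = (8.0, 2.0)
    meth_hmr_beta: tuple[float, float] = (1.0, 9.0)
    variant_specs: list[VariantSpec] = field(default_factory=list)
    exon_cds_lengths: tuple[int, ...] | None = None
    utr5_length: int = 20
    min_intron: int = 300

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ConfigurationError(f"strand must be '+' or '-', got {self.strand!r}")
        for alpha, beta in (self.meth_background_beta, self.meth_hmr_beta):
            if alpha <= 0 or beta <= 0:
                raise ConfigurationError("Beta parameters must be positive")
        for seg in self.planted_segments:
            if not 1 <= seg.start <= seg.end <= self.locus_length:
                raise ConfigurationError(f"planted segment {seg} outside locus 1..{self.locus_length}")
        for s, e in self.hmr_regions:
            if not 1 <= s <= e <= self.locus_length:
                raise ConfigurationError(f"HMR region ({s}, {e}) outside locus")

    def cds_lengths(self) -> tuple[int, ...]:
        if self.exon_cds_lengths is not None:
            lengths = self.exon_cds_lengths
        else:
            # first two exons short (alternative N-termini), then long exons
            base = [63, 27, 540, 900]
            lengths = tuple(base[i] if i < 4 else 300 for i in range(self.n_exons))
        if len(lengths) != self.n_exons:
            raise ConfigurationError("exon_cds_lengths does not match n_exons")
        if any(l <= 0 or l % 3 for l in lengths):
            raise ConfigurationError("exon CDS lengths must be positive multiples of 3")
        return lengths


# ---------------------------------------------------------------------------
# Locus


def random_coding_dna(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(CODONS_BY_AA[aa]) for aa in peptide)


def simulate_locus(config: SimulationConfig) -> tuple[GeneModel, str]:
    """Generate a multi-exon gene model and its locus DNA.

    Exon coding sequences are stop-free codon runs in one transcript-order
    frame, so any subset of downstream exons is translatable. On the minus
    strand the locus DNA is the plus-strand sequence; transcript segments
    are its reverse complement.
    """
    rng = np.random.default_rng([config.seed, 0])
    cds = config.cds_lengths()
    exon_lengths = [config.utr5_length + cds[0]] + list(cds[1:])
    needed = sum(exon_lengths) + (config.n_exons - 1) * config.min_intron + 2_000
    if config.locus_length < needed:
        raise ConfigurationError(
            f"locus_length {config.locus_length} too short for exon layout (needs >= {needed})"
        )
    slack = config.locus_length - sum(exon_lengths) - 1_000
    cuts = np.sort(rng.integers(0, slack - config.n_exons * config.min_intron + 1, size=config.n_exons))
    gaps = np.diff(np.concatenate(([0], cuts))) + config.min_intron
    # transcript-order layout in "transcription distance" from locus 5' end
    starts_td = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(exon_lengths[:-1])))
    dna = "".join(rng.choice(["A", "C", "G", "T"], size=config.locus_length))
    exon_seqs = []
    for i, length in enumerate(exon_lengths):
        n_cds = cds[i] // 3
        seq = random_coding_dna(n_cds, rng)
        if i == 0:
            seq = "".join(rng.choice(["A", "C", "G", "T"], size=config.utr5_length)) + seq
        exon_seqs.append(seq)
    # place exons into the locus; for '-' strand the transcript reads from
    # high to low plus-strand coordinates
    exons: list[tuple[int, int]] = []
    arr = list(dna)
    for start_td, seq in zip(starts_td, exon_seqs):
        if config.strand == "+":
            g_start = int(start_td) + 1
            g_end = g_start + len(seq) - 1
            arr[g_start - 1 : g_end] = list(seq)
        else:
            g_end = config.locus_length - int(start_td)
            g_start = g_end - len(seq) + 1
            arr[g_start - 1 : g_end] = list(str(Seq(seq).reverse_complement()))
        if g_start < 1 or g_end > config.locus_length:
            raise ConfigurationError("exon layout escapes the locus")
        exons.append((g_start, g_end))
    gene = GeneModel(
        name="synthetic_gene",
        chromosome="chrS",
        strand=config.strand,
        exons=tuple(exons),
        tss_by_assembly={"synthetic": exons[0][1] if config.strand == "-" else exons[0][0]},
        exon_assembly="synthetic",
    )
    return gene, "".join(arr)


def transcript_sequence(gene: GeneModel, dna: str, exon: int) -> str:
    """Exon sequence in transcription orientation (1-based exon index)."""
    s, e = gene.exons[exon - 1]
    seq = dna[s - 1 : e]
    return str(Seq(seq).reverse_complement()) if gene.strand == "-" else seq


def intron_sequence(gene: GeneModel, dna: str, intron: int) -> str:
    s, e = gene.intron(intron)
    seq = dna[s - 1 : e]
    return str(Seq(seq).reverse_complement()) if gene.strand == "-" else seq


def exon_peptides(gene: GeneModel, dna: str, utr5_length: int = 20) -> dict[int, str]:
    """Translate each exon's CDS portion in transcript order.

    Exon 1 has its 5'UTR stripped; translation of the last exon stops at the
    first stop codon (the remainder is 3'UTR).
    """
    out = {}
    for k in range(1, len(gene.exons) + 1):
        seq = transcript_sequence(gene, dna, k)
        if k == 1:
            seq = seq[utr5_length:]
        seq = seq[: len(seq) - len(seq) % 3]
        out[k] = str(Seq(seq).translate()).split("*")[0]
    return out


# ---------------------------------------------------------------------------
# Isoforms


@dataclass
class IsoformTruth:
    """Construction-time truth for one simulated isoform."""

    isoform_id: str
    labels: list[tuple[int | None, int | None]]  # (exon, peptide_pos) per residue
    novel_origin: tuple[str, int, int] | None = None  # (feature, index, frame)

    def exon_peptide_positions(self, exon: int) -> set[int]:
        return {pp for ex, pp in self.labels if ex == exon and pp is not None}


def simulate_isoforms(
    gene: GeneModel,
    dna: str,
    specs: list[VariantSpec],
    utr5_length: int = 20,
) -> list[tuple[ProteinIsoform, IsoformTruth]]:
    """Build splice-variant isoforms from declarative edit specs, with truth."""
    peptides = exon_peptides(gene, dna, utr5_length)
    out = []
    for spec in specs:
        for exon in spec.use_exons:
            if not 1 <= exon <= len(gene.exons):
                raise ConfigurationError(f"{spec.name}: exon {exon} not in gene")
        residues: list[tuple[str, int | None, int | None]] = []
        started = spec.start_met is None
        stopped = False
        for exon in spec.use_exons:
            pep = peptides[exon]
            met_seen = 0
            for pos, aa in enumerate(pep, start=1):
                if stopped:
                    break
                if not started:
                    if spec.start_met[0] == exon and aa == "M":
                        met_seen += 1
                        if met_seen == spec.start_met[1]:
                            started = True
                    if not started:
                        continue
                if any(d[0] == exon and d[1] <= pos <= d[2] for d in spec.delete):
                    continue
                residues.append((aa, exon, pos))
                if spec.truncate_after == (exon, pos):
                    stopped = True
        if not started:
            raise ConfigurationError(f"{spec.name}: start Met {spec.start_met} not found")
        novel_origin = None
        if spec.novel_c_peptide is not None:
            for aa in spec.novel_c_peptide:
                residues.append((aa, None, None))
        elif spec.novel_c_term is not None:
            feature, idx, frame, aa_off, aa_len = spec.novel_c_term
            src = (
                intron_sequence(gene, dna, idx)
                if feature == "intron"
                else transcript_sequence(gene, dna, idx)
            )
            sub = src[frame:]
            trans = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
            window = trans[aa_off : aa_off + aa_len]
            if "*" in window or len(window) < aa_len:
                raise ConfigurationError(f"{spec.name}: novel fragment window contains a stop or is short")
            for aa in window:
                residues.append((aa, None, None))
            novel_origin = (feature, idx, frame)
        if not residues:
            raise ConfigurationError(f"{spec.name}: edits produce an empty protein")
        sequence = "".join(r[0] for r in residues)
        iso = ProteinIsoform(id=spec.name, sequence=sequence, source_db="synthetic")
        truth = IsoformTruth(spec.name, [(r[1], r[2]) for r in residues], novel_origin)
        out.append((iso, truth))
    return out


def true_domain_statuses(
    truth: IsoformTruth,
    reference_truth: IsoformTruth,
    domains: list[FunctionalDomain],
    missing_threshold: float = 0.1,
) -> dict[str, DomainStatus]:
    """Ground-truth domain status from construction labels (no alignment)."""
    ref_pos_of = {
        (ex, pp): i + 1
        for i, (ex, pp) in enumerate(reference_truth.labels)
        if ex is not None
    }
    covered = {ref_pos_of[(ex, pp)] for ex, pp in truth.labels if (ex, pp) in ref_pos_of}
    out = {}
    for domain in domains:
        matched = {p for p in covered if domain.start <= p <= domain.end}
        has_alt_n = False
        if matched and domain.start not in matched:
            first_match = min(matched)
            first_res = next(
                i
                for i, (ex, pp) in enumerate(truth.labels)
                if (ex, pp) in ref_pos_of and ref_pos_of[(ex, pp)] == first_match
            )
            # alternative N-terminus: the isoform carries non-reference
            # residues ahead of the domain's first matched position
            has_alt_n = any(
                (ex, pp) not in ref_pos_of for ex, pp in truth.labels[:first_res]
            )
        out[domain.name] = _status_from_matched(
            matched, domain.start, domain.end, missing_threshold, has_alt_n
        )
    return out


# ---------------------------------------------------------------------------
# Tracks


def simulate_tracks(gene: GeneModel, config: SimulationConfig) -> list[SignalTrack]:
    """Poisson-noise density tracks with planted enriched segments.

    Each planted segment is carried by a seeded random subset of tracks of
    size ``round(carried_fraction * n_tracks)``; within a carrying track the
    Poisson rate is multiplied by ``fold`` in proportion to the fraction of
    the bin covered by the segment.
    """
    if config.n_tracks < 1:
        raise ConfigurationError("n_tracks must be >= 1")
    rng = np.random.default_rng([config.seed, 1])
    edges = np.arange(1, config.locus_length + 2, config.bin_size)
    if edges[-1] != config.locus_length + 1:
        edges = np.append(edges, config.locus_length + 1)
    n_bins = len(edges) - 1
    widths = np.diff(edges)
    carriers: list[np.ndarray] = []
    for seg in config.planted_segments:
        k = max(1, int(round(seg.carried_fraction * config.n_tracks)))
        carriers.append(rng.permutation(config.n_tracks)[:k])
    tracks = []
    for t in range(config.n_tracks):
        rate = np.full(n_bins, config.background_rate, dtype=float)
        for seg, carrier in zip(config.planted_segments, carriers):
            if t not in carrier:
                continue
            ov = np.maximum(
                0.0,
                np.minimum(edges[1:] - 1, seg.end) - np.maximum(edges[:-1], seg.start) + 1,
            )
            frac = ov / widths
            rate *= 1.0 + (seg.fold - 1.0) * frac
        values = rng.poisson(rate).astype(float)
        intervals = [
            (int(edges[b]), int(edges[b + 1]) - 1, float(values[b])) for b in range(n_bins)
        ]
        tracks.append(SignalTrack(sample_id=f"track{t + 1}", assay="ChIP", intervals=intervals))
    return tracks


def simulate_methylation(
    gene: GeneModel,
    config: SimulationConfig,
    n_samples: int,
) -> list[MethylationTrack]:
    """Beta-noise methylation fraction tracks with planted hypomethylation.

    Per CpG bin and sample, fractions are Beta(background) outside the
    planted HMR regions and Beta(hmr) inside (bins assigned by midpoint),
    independent across samples.
    """
    rng = np.random.default_rng([config.seed, 2])
    edges = np.arange(1, config.locus_length + 2, config.bin_size)
    if edges[-1] != config.locus_length + 1:
        edges = np.append(edges, config.locus_length + 1)
    mids = (edges[:-1] + edges[1:] - 1) / 2
    in_hmr = np.zeros(len(mids), dtype=bool)
    for s, e in config.hmr_regions:
        in_hmr |= (mids >= s) & (mids <= e)
    a0, b0 = config.meth_background_beta
    a1, b1 = config.meth_hmr_beta
    tracks = []
    for i in range(n_samples):
        fractions = np.where(
            in_hmr,
            rng.beta(a1, b1, size=len(mids)),
            rng.beta(a0, b0, size=len(mids)),
        )
        intervals = [
            (int(edges[b]), int(edges[b + 1]) - 1, float(fractions[b]))
            for b in range(len(mids))
        ]
        tracks.append(MethylationTrack(sample_id=f"sample{i + 1}", intervals=intervals, age_label=f"age{i + 1}"))
    return tracks


# ---------------------------------------------------------------------------
# Serialization


def write_simulation(
    outdir: str | Path,
    gene: GeneModel,
    dna: str,
    isoforms: list[tuple[ProteinIsoform, IsoformTruth]],
    tracks: list[SignalTrack],
    methylation: list[MethylationTrack],
) -> None:
    """Write DNA/protein FASTA, bedGraph tracks, and a truth JSON."""
    from .io import FastaRecord, write_bedgraph, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "locus.fa", [FastaRecord(gene.chromosome, dna)])
    write_fasta(
        outdir / "isoforms.fa",
        [FastaRecord(iso.id, iso.sequence) for iso, _ in isoforms],
    )
    for track in tracks:
        write_bedgraph(
            outdir / f"{track.sample_id}.bedGraph",
            [(gene.chromosome, s, e, v) for s, e, v in track.intervals],
        )
    for track in methylation:
        write_bedgraph(
            outdir / f"meth_{track.sample_id}.bedGraph",
            [(gene.chromosome, s, e, v) for s, e, v in track.intervals],
        )
    truth = {
        "gene": {
            "name": gene.name,
            "strand": gene.strand,
            "exons": list(map(list, gene.exons)),
            "tss": gene.tss_by_assembly,
        },
        "isoforms": {
            t.isoform_id: {
                "labels": t.labels,
                "novel_origin": t.novel_origin,
            }
            for _, t in isoforms
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
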