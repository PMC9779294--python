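"""Synthetic reference isoform panel (constructed stand-in sequences).

This module builds a deterministic, fully synthetic analogue of the MeCP2
isoform catalogue for testing and worked examples: real database protein
sequences are not redistributed here, so the panel constructs stand-in
sequences (ids carry a ``_syn`` suffix) that reproduce the catalogued
*relations* by construction:

* the two established isoforms differ only at the N terminus, with 21
  (E1-type, exon-1-encoded) versus 9 (E2-type, exon-2-encoded) distinctive
  residues — the real distinctive N-termini are used verbatim, everything
  downstream is generated sequence;
* two shorter NCBI-style isoforms start at alternative internal Met codons
  in exons 3 and 4;
* eight UniProt-style isoforms carry the catalogued truncations, internal
  deletions, and novel C-terminal fragments translated from intron 2 or
  from exon 4 in a shifted reading frame, including the 14-residue shared
  C-terminus of the two NMD-product analogues;
* fifteen functional-domain intervals are laid out on the E2-type reference
  so that the domain-completeness matrix of the panel equals the packaged
  expectation tables cell for cell.

The panel gene is a minus-strand four-exon gene (~4 kb locus) built from
the same primitives as the random simulator, but with fixed content.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from .domains import FunctionalDomain
from .locus import GeneModel, ProteinIsoform
from .simulate import (
    IsoformTruth,
    VariantSpec,
    exon_peptides,
    reverse_translate,
    simulate_isoforms,
    transcript_sequence,
)

PANEL_SEED = 20221015
UTR5_LEN = 20

# Real distinctive N-termini of the two established isoforms; the shared
# body downstream is generated.
EXON1_PEPTIDE = "MAAAAAAAPSGGGGGGEEERL"  # 21 aa, E1-type start
EXON2_PEPTIDE = "MVAGMLGLR"  # 9 aa, E2-type start

_NO_MET = "ACDEFGHIKLNPQRSTVWY"  # Met positions are placed explicitly

E3_LEN = 180  # reference positions 10..189
E4_LEN = 297  # reference positions 190..486
ALT_MET_E3 = 91  # exon-3 peptide position -> reference position 100
ALT_MET_E4 = 111  # exon-4 peptide position -> reference position 300

REFERENCE_ID = "isoform1_E2_syn"

# Display order follows the catalogue summary tables.
DOMAIN_LAYOUT: list[tuple[str, int, int]] = [
    ("HMGD1", 1, 60),
    ("HMGD2", 248, 277),
    ("MBD", 65, 260),
    ("aDBD", 290, 380),
    ("TRD", 285, 400),
    ("NLS1", 265, 280),
    ("NLS2", 302, 312),
    ("AT-hook 1", 282, 291),
    ("AT-hook 2", 314, 323),
    ("H3-M-T IS", 70, 120),
    ("NID", 350, 372),
    ("TBL1XR1 IS", 348, 370),
    ("WW-2 IS", 325, 345),
    ("CTDα", 405, 440),
    ("CTDβ", 445, 486),
]

NCBI_IDS = ["isoform1_E2_syn", "isoform2_E1_syn", "isoform3_syn", "isoform4_syn"]
UNIPROT_IDS = [
    "B5MCB4_syn",
    "A0A0D9SFX7_syn",
    "C9JH89_syn",
    "A0A1B0GTV0_syn",
    "A0A0D9SEX1_syn",
    "H7BY72_syn",
    "A0A6Q8PHQ3_syn",
    "A0A6Q8PF93_syn",
]


@dataclass
class Panel:
    gene: GeneModel
    dna: str
    exon_peptides: dict[int, str]
    isoforms: dict[str, ProteinIsoform]
    truths: dict[str, IsoformTruth]
    domains: list[FunctionalDomain]

    @property
    def reference(self) -> ProteinIsoform:
        return self.isoforms[REFERENCE_ID]

    def ncbi_isoforms(self) -> list[ProteinIsoform]:
        return [self.isoforms[i] for i in NCBI_IDS]

    def uniprot_isoforms(self) -> list[ProteinIsoform]:
        return [self.isoforms[i] for i in UNIPROT_IDS]


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NO_MET), size=n))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=n))


def _build_locus(rng: np.random.Generator) -> tuple[GeneModel, str, dict[int, str], dict[str, tuple[int, int]]]:
    """Assemble the panel gene: transcript-order segments, then minus strand."""
    e3 = list(_random_peptide(rng, E3_LEN))
    e3[ALT_MET_E3 - 1] = "M"
    e3_pep = "".join(e3)
    e4 = list(_random_peptide(rng, E4_LEN))
    e4[ALT_MET_E4 - 1] = "M"
    e4_pep = "".join(e4)

    # novel peptides planted in intron 2 (NMD-product analogues); the two
    # sharing a 14-residue C-terminus differ at the 15th-from-last residue
    pf93_novel = _random_peptide(rng, 30)
    h7_prefix = _random_peptide(rng, 6)
    while h7_prefix[-1] == pf93_novel[-15]:
        h7_prefix = h7_prefix[:-1] + _random_peptide(rng, 1)
    h7_novel = h7_prefix + pf93_novel[-14:]
    phq3_novel = _random_peptide(rng, 25)

    exon1 = _rand_dna(rng, UTR5_LEN) + reverse_translate(EXON1_PEPTIDE, rng)
    exon2 = reverse_translate(EXON2_PEPTIDE, rng)
    exon3 = reverse_translate(e3_pep, rng)
    exon4 = reverse_translate(e4_pep, rng) + "TAA" + _rand_dna(rng, 30)
    intron1 = _rand_dna(rng, 450)
    intron2 = (
        _rand_dna(rng, 150)
        + reverse_translate(phq3_novel, rng)
        + _rand_dna(rng, 33)
        + reverse_translate(pf93_novel, rng)
        + _rand_dna(rng, 33)
        + reverse_translate(h7_novel, rng)
        + _rand_dna(rng, 150)
    )
    intron3 = _rand_dna(rng, 400)

    segments = [
        ("margin5", _rand_dna(rng, 400)),
        ("exon1", exon1),
        ("intron1", intron1),
        ("exon2", exon2),
        ("intron2", intron2),
        ("exon3", exon3),
        ("intron3", intron3),
        ("exon4", exon4),
        ("margin3", _rand_dna(rng, 400)),
    ]
    transcript_order = "".join(seq for _, seq in segments)
    locus_len = len(transcript_order)
    dna = str(Seq(transcript_order).reverse_complement())  # plus strand, gene on '-'

    exons: list[tuple[int, int]] = []
    offset = 0
    for name, seq in segments:
        span_td = (offset + 1, offset + len(seq))
        offset += len(seq)
        if name.startswith("exon"):
            exons.append((locus_len - span_td[1] + 1, locus_len - span_td[0] + 1))
    gene = GeneModel(
        name="MECP2_syn",
        chromosome="chrS",
        strand="-",
        exons=tuple(exons),
        tss_by_assembly={"synthetic": exons[0][1]},
        exon_assembly="synthetic",
    )
    peptides = exon_peptides(gene, dna, utr5_length=UTR5_LEN)
    novel_info = {
        "phq3": (50, 25),  # (aa offset in intron-2 frame-0 translation, length)
        "pf93": (86, 30),
        "h7": (127, 20),
    }
    assert peptides == {1: EXON1_PEPTIDE, 2: EXON2_PEPTIDE, 3: e3_pep, 4: e4_pep}
    return gene, dna, peptides, novel_info


def _find_shifted_window(gene: GeneModel, dna: str, min_len: int = 25, want: int = 40) -> tuple[int, int, int]:
    """Longest stop-free window of exon 4 translated in a shifted frame.

    Returns (frame, aa_offset, aa_length) for the novel C-terminal fragment
    of the exon-4-alternative-site analogues.
    """
    best = (0, 0, 0)
    seq = transcript_sequence(gene, dna, 4)
    for frame in (1, 2):
        sub = seq[frame:]
        trans = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
        start = 0
        for chunk in trans.split("*"):
            if len(chunk) > best[2]:
                best = (frame, start, len(chunk))
            start += len(chunk) + 1
    frame, off, length = best
    if length < min_len:
        raise RuntimeError("panel construction: no usable stop-free shifted-frame window in exon 4")
    if length > want:
        off += (length - want) // 2
        length = want
    return frame, off, length


@lru_cache(maxsize=1)
def build_panel() -> Panel:
    rng = np.random.default_rng(PANEL_SEED)
    gene, dna, peptides, novel_info = _build_locus(rng)
    b5_frame, b5_off, b5_len = _find_shifted_window(gene, dna)
    specs = [
        VariantSpec(REFERENCE_ID, use_exons=(2, 3, 4)),
        VariantSpec("isoform2_E1_syn", use_exons=(1, 3, 4)),
        VariantSpec("isoform3_syn", use_exons=(3, 4), start_met=(3, 1)),
        VariantSpec("isoform4_syn", use_exons=(4,), start_met=(4, 1)),
        VariantSpec(
            "B5MCB4_syn",
            use_exons=(1, 3, 4),
            truncate_after=(4, 56),
            novel_c_term=("exon", 4, b5_frame, b5_off, b5_len),
        ),
        VariantSpec(
            "A0A0D9SFX7_syn",
            use_exons=(2, 3, 4),
            truncate_after=(4, 67),
            novel_c_term=("exon", 4, b5_frame, b5_off, b5_len),
        ),
        VariantSpec("C9JH89_syn", use_exons=(2, 3), truncate_after=(3, 31)),
        VariantSpec(
            "A0A1B0GTV0_syn",
            use_exons=(4,),
            delete=((4, 27, 165),),
            truncate_after=(4, 231),
        ),
        VariantSpec("A0A0D9SEX1_syn", use_exons=(2, 3), truncate_after=(3, 39)),
        VariantSpec(
            "H7BY72_syn",
            use_exons=(2,),
            delete=((2, 9, 9),),
            novel_c_term=("intron", 2, 0, novel_info["h7"][0], novel_info["h7"][1]),
        ),
        VariantSpec(
            "A0A6Q8PHQ3_syn",
            use_exons=(2,),
            novel_c_term=("intron", 2, 0, novel_info["phq3"][0], novel_info["phq3"][1]),
        ),
        VariantSpec(
            "A0A6Q8PF93_syn",
            use_exons=(2,),
            novel_c_term=("intron", 2, 0, novel_info["pf93"][0], novel_info["pf93"][1]),
        ),
    ]
    built = simulate_isoforms(gene, dna, specs, utr5_length=UTR5_LEN)
    isoforms = {iso.id: iso for iso, _ in built}
    truths = {iso.id: truth for iso, truth in built}
    domains = [
        FunctionalDomain(name=name, ref_isoform=REFERENCE_ID, start=s, end=e, source="synthetic")
        for name, s, e in DOMAIN_LAYOUT
    ]
    panel = Panel(gene, dna, peptides, isoforms, truths, domains)
    _validate(panel)
    return panel


def _validate(panel: Panel) -> None:
    """Construction sanity: unambiguous provenance and catalogued relations."""
    peps = panel.exon_peptides
    ref = panel.isoforms[REFERENCE_ID].sequence
    if len(ref) != 9 + E3_LEN + E4_LEN:
        raise RuntimeError("panel reference has unexpected length")
    # exon peptides must not share 6-mers (provenance anchors stay unambiguous)
    kmers: dict[str, int] = {}
    for exon, pep in peps.items():
        for i in range(len(pep) - 5):
            k = pep[i : i + 6]
            if kmers.setdefault(k, exon) != exon:
                raise RuntimeError("panel exon peptides share a 6-mer")
    for iso_id in ("H7BY72_syn", "A0A6Q8PHQ3_syn", "A0A6Q8PF93_syn", "B5MCB4_syn"):
        seq = panel.isoforms[iso_id].sequence
        truth = panel.truths[iso_id]
        novel = "".join(
            seq[i] for i, (ex, _) in enumerate(truth.labels) if ex is None
        )
        for i in range(len(novel) - 5):
            if novel[i : i + 6] in kmers:
                raise RuntimeError("novel fragment shares a 6-mer with an exon peptide")
    h7 = panel.isoforms["H7BY72_syn"].sequence
    pf93 = panel.isoforms["A0A6Q8PF93_syn"].sequence
    if h7[-14:] != pf93[-14:] or h7[-15] == pf93[-15]:
        raise RuntimeError("shared 14-residue C-terminus not constructed correctly")
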