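"""Interval co-localization among fragment sets and cis-regulatory elements.

Fragment sets are named collections of labeled intervals — the consensus
segment catalogues (S: histone-PTM enrichment, A: DNase accessibility,
B: ATAC accessibility, H: hypomethylation), cis-RE fixtures (F elements,
promoter elements), or any user set. Intervals are half-open in bases,
either TSS-relative or genomic; sets must share a coordinate space before
comparison, with conversion through the gene's TSS anchor.

Reported quantities are pairwise overlap lengths, Jaccard indices, and
containment relations; "most regions overlap"-style statements are always
reported as counts and fractions, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coordinates import RelativeInterval
from .locus import GeneModel


@dataclass
class FragmentSet:
    """Labeled half-open intervals in one coordinate space."""

    name: str
    fragments: list[tuple[str, int, int]]  # (label, start, end) half-open, bases
    assembly: str = ""
    space: str = "relative"  # "relative" (TSS-anchored) or "genomic"

    def __post_init__(self) -> None:
        if self.space not in {"relative", "genomic"}:
            raise ValueError(f"space must be 'relative' or 'genomic', got {self.space!r}")
        labels = [lab for lab, _, _ in self.fragments]
        if len(labels) != len(set(labels)):
            raise ValueError(f"fragment set {self.name!r} has duplicate labels")
        for lab, s, e in self.fragments:
            if e <= s:
                raise ValueError(f"{self.name}/{lab}: empty interval ({s}, {e})")

    @classmethod
    def from_relative_intervals(cls, name: str, intervals: list[RelativeInterval]) -> "FragmentSet":
        assemblies = {iv.assembly for iv in intervals}
        if len(assemblies) > 1:
            raise ValueError(f"mixed assemblies in one set: {sorted(assemblies)}")
        return cls(
            name=name,
            fragments=[(iv.label, iv.start_b, iv.end_b) for iv in intervals],
            assembly=assemblies.pop() if assemblies else "",
            space="relative",
        )

    def to_relative(self, gene: GeneModel, assembly: str | None = None) -> "FragmentSet":
        """Re-anchor a genomic set to TSS-relative coordinates."""
        if self.space == "relative":
            return self
        assembly = assembly or self.assembly
        tss = gene.tss_for(assembly)
        fragments = []
        for lab, s, e in self.fragments:
            if gene.strand == "-":
                fragments.append((lab, tss - e + 1, tss - s + 1))
            else:
                fragments.append((lab, s - tss, e - tss))
        fragments.sort(key=lambda f: f[1])
        return FragmentSet(self.name, fragments, assembly=assembly, space="relative")

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.fragments)


def _check_space(set_a: FragmentSet, set_b: FragmentSet) -> None:
    if set_a.space != set_b.space:
        raise ValueError(
            f"sets {set_a.name!r} and {set_b.name!r} are in different coordinate spaces "
            f"({set_a.space} vs {set_b.space}); convert with FragmentSet.to_relative first"
        )
    if set_a.assembly and set_b.assembly and set_a.assembly != set_b.assembly:
        raise ValueError(
            f"sets {set_a.name!r} ({set_a.assembly}) and {set_b.name!r} ({set_b.assembly}) "
            "are anchored to different assemblies"
        )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlap_matrix(set_a: FragmentSet, set_b: FragmentSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise (overlap bases, Jaccard index) matrices between two sets."""
    _check_space(set_a, set_b)
    labels_a = [lab for lab, _, _ in set_a.fragments]
    labels_b = [lab for lab, _, _ in set_b.fragments]
    bases = pd.DataFrame(0, index=labels_a, columns=labels_b, dtype=int)
    jaccard = pd.DataFrame(0.0, index=labels_a, columns=labels_b, dtype=float)
    for la, sa, ea in set_a.fragments:
        for lb, sb, eb in set_b.fragments:
            inter = _overlap((sa, ea), (sb, eb))
            union = (ea - sa) + (eb - sb) - inter
            bases.loc[la, lb] = inter
            jaccard.loc[la, lb] = inter / union if union else 0.0
    return bases, jaccard


def containment_report(fragments: FragmentSet, features: FragmentSet) -> dict[str, list[tuple[str, str]]]:
    """Per fragment, the features it contains or partially overlaps.

    Each fragment label maps to a position-ordered list of
    ``(feature_label, relation)`` with relation ``contained`` (feature fully
    inside the fragment) or ``partial``; features overlapping no fragment do
    not appear.
    """
    _check_space(fragments, features)
    report: dict[str, list[tuple[str, str]]] = {}
    for lab, s, e in fragments.fragments:
        hits = []
        for flab, fs, fe in sorted(features.fragments, key=lambda f: f[1]):
            inter = _overlap((s, e), (fs, fe))
            if inter == 0:
                continue
            hits.append((flab, "contained" if (fs >= s and fe <= e) else "partial"))
        report[lab] = hits
    return report


def intersect_sets(set_a: FragmentSet, set_b: FragmentSet, min_overlap: int = 1) -> FragmentSet:
    """Pairwise intersections of at least ``min_overlap`` bases.

    Labels concatenate the contributing fragment labels ("A4∩H3"); a
    fragment intersected with an identically-labeled fragment keeps its
    label, so a set intersected with itself returns itself.
    """
    _check_space(set_a, set_b)
    fragments: list[tuple[str, int, int]] = []
    seen: set[tuple[str, int, int]] = set()
    for la, sa, ea in set_a.fragments:
        for lb, sb, eb in set_b.fragments:
            inter = _overlap((sa, ea), (sb, eb))
            if inter < min_overlap:
                continue
            frag = (la if la == lb else f"{la}∩{lb}", max(sa, sb), min(ea, eb))
            if frag not in seen:
                seen.add(frag)
                fragments.append(frag)
    return FragmentSet(
        name=f"{set_a.name}∩{set_b.name}",
        fragments=fragments,
        assembly=set_a.assembly or set_b.assembly,
        space=set_a.space,
    )


def colocalization_summary(set_a: FragmentSet, set_b: FragmentSet, min_overlap: int = 1) -> dict:
    """Counts and fractions of fragments in ``set_a`` overlapped by ``set_b``."""
    bases, _ = overlap_matrix(set_a, set_b)
    overlapped = (bases >= min_overlap).any(axis=1)
    return {
        "n_fragments": int(len(set_a.fragments)),
        "n_overlapped": int(overlapped.sum()),
        "fraction_overlapped": float(overlapped.mean()) if len(set_a.fragments) else 0.0,
    }
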