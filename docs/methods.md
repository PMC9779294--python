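# Methods

This note documents the models and procedures implemented in `mecp2locus`,
the parameter choices that matter, what the synthetic data do and do not
emulate, and the design decisions taken where the problem was genuinely
open.

## Coordinate system

All genomic coordinates are 1-based inclusive internally (genome-browser
display convention); bedGraph/BED I/O converts to 0-based half-open at the
file boundary and nowhere else. TSS-relative positions are signed base
offsets from the transcription start site of the gene (the
transcription-direction first nucleotide of exon 1), **positive in the
transcription direction**: on the minus-strand *MECP2* gene,
`relative = TSS − genomic`. This orientation is forced by the fragment
catalogue itself — the accessibility fragment containing the core promoter
and exon 1 sits at −0.5–0.1 kb while the fragment containing the *IRAK1*
promoter (3′ of *MECP2*) sits at +77.7–77.9 kb — and an automated test
pins it. Catalogue coordinates are expressed in kb at 0.1 kb precision;
arithmetic is integer bases (kb × 1000).

## Isoform alignment and provenance

Isoform-versus-reference comparison uses optimal global pairwise alignment
with affine gaps (Gotoh algorithm via `Bio.Align.PairwiseAligner`), BLOSUM62
scoring, gap open −10 and extend −1, so a gap of length *k* costs 10 + *k*.
These are the standard defaults for global protein alignment; no parameters
are fitted. End gaps are penalised (true global mode). Outputs are
deterministic (the aligner's first optimal traceback); the optimal *score*
is additionally verified in the test suite against an independent
brute-force oracle that enumerates every monotone alignment of short
sequences. Pairwise alignment to the reference suffices for every output
the package produces; no multiple-sequence alignment is attempted.

Per-residue **exon provenance** is assigned by maximal exact substring
matches between an isoform and the translated exon peptides. Matches
shorter than `min_anchor = 6` residues are ignored as ambiguous; candidate
matches are applied longest-first, ties broken toward the 5′-most exon and
then position. Residues covered by no anchor form the *novel segments* of
the isoform. Exact (identity) matching is appropriate because splice
variants of one gene share their sequence verbatim with the translated
exons; a 6-mer chance match against an unrelated peptide has probability
20⁻⁶ per position.

**Terminal differences** between two isoforms are measured with longest
common prefixes/suffixes: if the common suffix is at least as long as the
common prefix, the difference is N-terminal and each isoform's distinctive
count is its length minus the common suffix length (symmetrically for the
C case). On the E1/E2-type pair this yields (21, 9) by construction of the
alternative starts.

**Novel-fragment localisation** scans all six frame translations of the
locus for the best gap-free (Hamming) match of the fragment, reporting the
overlapped gene feature (exon or intron, by largest overlap) when identity
reaches `min_identity = 0.9`, with ties broken by 5′-most genomic start.
Gap-free scanning suffices because the fragments in question are contiguous
alternative-frame or intronic translations; the test suite confirms that a
seeded random peptide stays far below the identity threshold.

## Domain projection

A functional domain is an interval in reference-isoform protein
coordinates. Its status in a query isoform is read off the global
alignment: a reference position is **matched** when the aligned query
residue is identical *and*, when exon provenance is available for both
sequences, derives from the same exon as the reference position. The
provenance gate prevents residues of novel fragments from masquerading as
domain sequence through chance identities. Coverage is |matched| / domain
length and the category follows the geometry of the unmatched positions:

| geometry of unmatched positions | category |
|---|---|
| none | complete |
| coverage ≤ 0.1 | missing |
| prefix only, query truncated | N-terminally incomplete |
| prefix only, query substitutes alternative residues | possible different N-terminus |
| suffix only | C-terminally incomplete |
| prefix and suffix | N- and C-terminally incomplete |
| interior run with matched flanks | missing fragment inside (± C-term) |

`missing_threshold = 0.1` is the single global threshold separating
"missing" from "incomplete" across every isoform × domain cell; the same
rule (on exon-peptide coverage from the provenance track) produces the
per-exon presence rows. The serialisation vocabulary ("✓", "-", "N-term.
incompl.", …) mirrors the conventional summary-table wording. Domains are
annotated on the E2-type reference only and every isoform is classified
against that one annotated reference; alternative (E1-type) starts are
handled by the different-N-terminus category rather than by re-annotating
domains on a second reference.

## Consensus segment calling

Signal tracks (ChIP/DNase/ATAC densities) are averaged onto a fixed bin
grid (`bin_size = 200` bp, coverage-weighted; bases without data count as
zero with a logged warning). Within the analysis region each track gets its
own enrichment threshold — the `enrich_quantile = 0.75` quantile of its bin
means — which normalises sequencing-depth differences between samples the
way per-track display auto-scaling does. A bin is *enriched* in a track
when its value reaches the track threshold and is positive (the positivity
condition makes all-zero tracks yield nothing, while a constant positive
track degenerates to one region-spanning segment — both covered by tests).
Bins enriched in ≥ `consensus_fraction = 0.7` of tracks are merged across
gaps ≤ `merge_gap = 2000` bp and calls shorter than `min_length = 500` bp
are dropped. Calls are labelled in transcription-direction order. The
published segments of this kind were identified visually with no stated
thresholds; these defaults were chosen once to make that judgement
reproducible at the kb scale of the catalogued fragments and were
calibrated only on synthetic data. Exact reproduction of the published
segment boundaries from the public tracks is therefore not claimed; the
recovery properties below are.

Hypomethylated regions (HMRs) are, per sample, maximal runs of
≥ `hmr_min_cpg_bins = 3` bins with mean methylation fraction
≤ `hmr_threshold = 0.3`, merged across gaps ≤ `merge_gap`. Consistent HMRs
are maximal intervals covered by per-sample HMRs in ≥ `min_samples`
samples (default: all, matching the "consistent at every age" reading),
additionally requiring 0.5 reciprocal overlap with a contributing HMR in
that many samples so that thin slivers of deeply stacked but misaligned
HMRs are not reported.

Monotonicity (raising either threshold never increases called length),
idempotence on the caller's own output mask, and track-order invariance
are property-tested.

## Synthetic data

The generator emulates the statistical structure of browser-track data at
desk scale, not read-level sequencing: per-bin Poisson counts
(`background_rate = 5` per 200 bp bin) multiplied inside planted segments
by an enrichment fold in a seeded subset of tracks (fold 8 and full
carriage in the recovery studies); per-bin Beta-distributed methylation
fractions, Beta(8, 2) background (mean 0.8) versus Beta(1, 9) inside
planted HMRs (mean 0.1), independent across samples. Splice variants are
built from declarative edit specifications (exon choice, internal-Met
start, truncation, internal deletion, novel C-terminus translated from a
named intron/exon frame), so per-residue exon-of-origin and per-domain
completeness truths are exact, never estimated. It does not model
mappability or GC bias, fragment-length effects, correlated noise between
samples, single-CpG resolution, or diploid methylation — so passing
recovery tests demonstrate correctness of the calling logic under the
stated noise model, not performance on real tracks.

The recovery studies use a 120 kb region, three planted segments of 3–5 kb
at fold 8 carried by all of 6–12 tracks, two planted HMRs of 2.4–3 kb, and
20 simulation seeds; these sizes keep each study to seconds while giving
~600 bins per track and ≥ 50 in-segment bins, ample for median-based
checks (median truth-overlap Jaccard ≥ 0.8; at fold 1 the median called
length stays ≤ 2% of the region; the exact null medians fluctuate between
roughly 0 and 3% across seed choices because spurious consensus bins are
rare and lumpy).

### Synthetic reference isoform panel

Real database protein sequences are not redistributed in this repository,
so the isoform catalogue is represented by a constructed stand-in panel
(`panel.py`, ids suffixed `_syn`, fully deterministic). The panel fixes the
catalogued *relations* by construction: exon peptide lengths 21 / 9 / 180 /
297 with the real distinctive N-termini of the E1/E2-type starts; internal
start codons at reference positions 100 (exon 3) and 300 (exon 4); eight
predicted-isoform analogues with the catalogued truncations, the internal
deletion, intron-2-derived novel C-termini (including the 14-residue shared
C-terminus of the two NMD-product analogues), and an exon-4
shifted-reading-frame C-terminus; and a fifteen-domain layout on the
E2-type reference arranged so the computed completeness matrices equal the
packaged expectation tables cell for cell. Construction is validated at
build time (no shared 6-mers between exon peptides or with novel
fragments, correct shared-suffix structure). Conclusions about the real
sequences transfer exactly insofar as the catalogued relations the panel
encodes are the quantities under test; the panel is not a source of new
biological claims.

## Fragment catalogue and cis-RE fixture

The packaged S/A/B/H fragment catalogue transcribes the TSS-relative
consensus-segment coordinates derived from public multi-sample data series
(GSE17312 histone PTMs and methylation, GSE18927 DNase, GSE211822 ATAC; S/A/H
anchored at hg19, B at hg38). The cis-regulatory-element fixture (F
elements, promoter elements) is synthetic: those elements' plain
coordinates are not published, so the fixture places them consistently with
the catalogued containment statements and is intended to be replaced by
user-supplied intervals where real ones are available. Co-localization
claims involving F elements are therefore tested only against this fixture.
The packaged *MECP2* gene model carries the two published TSS anchors
exactly; its exon intervals are approximate and nothing in the package
depends on them beyond the overall gene span.

## Numerical and degenerate-input choices

* Quantiles use numpy's default linear interpolation; with integer-valued
  Poisson bins the effective per-track enrichment probability therefore
  sits between the neighbouring tail probabilities.
* Empty regions, bins larger than the region, methylation fractions
  outside [0, 1], inverted intervals, non-amino-acid symbols, duplicate
  FASTA ids, and unknown assemblies raise typed errors rather than being
  coerced.
* Interval sets intersected with themselves return themselves; Jaccard of
  two empty intervals is defined as 0.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global random state is touched.

## Known limitations

* The segment caller is a thresholding method, not an HMM or peak model;
  it targets kb-scale consensus segments, not narrow peaks, and performs
  no differential testing between groups of tracks.
* Domain classification requires positional identity through the
  alignment; genuinely divergent-but-homologous domain copies would be
  reported as missing.
* Only re-anchoring between assemblies at the published TSS values is
  supported — no general liftover.
* The CLI's `coloc` command compares BED files in genomic space; TSS
  re-anchoring across assemblies is available through the library
  (`FragmentSet.to_relative`).
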