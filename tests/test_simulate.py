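import numpy as np
import pytest

from mecp2locus.simulate import (
    ConfigurationError,
    PlantedSegment,
    SimulationConfig,
    VariantSpec,
    exon_peptides,
    simulate_isoforms,
    simulate_locus,
    simulate_methylation,
    simulate_tracks,
)


def _base_config(**kwargs):
    defaults = dict(seed=1, locus_length=60_000)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestLocus:
    def test_minus_strand_tss_is_max_coordinate_of_first_exon(self):
        gene, dna = simulate_locus(_base_config(strand="-"))
        assert gene.strand == "-"
        assert len(gene.exons) == 4
        assert gene.tss == gene.exons[0][1] == max(e for _, e in gene.exons)
        assert set(dna) <= set("ACGT")

    def test_plus_strand_layout(self):
        gene, _ = simulate_locus(_base_config(strand="+"))
        assert gene.tss == gene.exons[0][0] == min(s for s, _ in gene.exons)

    def test_same_seed_reproduces_identical_dna(self):
        gene_a, dna_a = simulate_locus(_base_config())
        gene_b, dna_b = simulate_locus(_base_config())
        assert dna_a == dna_b
        assert gene_a.exons == gene_b.exons

    def test_downstream_exons_are_translatable(self):
        cfg = _base_config()
        gene, dna = simulate_locus(cfg)
        peps = exon_peptides(gene, dna)
        for exon in (3, 4):
            assert "*" not in peps[exon]
            assert len(peps[exon]) > 0

    def test_too_short_locus_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError, match="too short"):
            simulate_locus(_base_config(locus_length=3_000))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            _base_config(meth_hmr_beta=(0.0, 9.0))
        with pytest.raises(ConfigurationError):
            _base_config(planted_segments=[PlantedSegment(1, 70_000, 8.0)])
        with pytest.raises(ConfigurationError):
            PlantedSegment(10, 20, 0.5)


class TestIsoforms:
    def test_truth_labels_match_exon_translations(self):
        """Every residue labeled with an exon equals that exon's peptide residue."""
        gene, dna = simulate_locus(_base_config())
        peps = exon_peptides(gene, dna)
        specs = [
            VariantSpec("full", use_exons=(2, 3, 4)),
            VariantSpec("skip2", use_exons=(1, 3, 4)),
        ]
        for iso, truth in simulate_isoforms(gene, dna, specs):
            for residue, (exon, pos) in zip(iso.sequence, truth.labels):
                if exon is not None:
                    assert peps[exon][pos - 1] == residue

    def test_distinct_n_termini_identical_elsewhere(self):
        gene, dna = simulate_locus(_base_config())
        built = simulate_isoforms(
            gene,
            dna,
            [VariantSpec("e1_like", use_exons=(1, 3, 4)), VariantSpec("e2_like", use_exons=(2, 3, 4))],
        )
        (a, _), (b, _) = built
        peps = exon_peptides(gene, dna)
        shared = peps[3] + peps[4]
        assert a.sequence.endswith(shared) and b.sequence.endswith(shared)
        assert a.sequence[: len(peps[1])] == peps[1]
        assert b.sequence[: len(peps[2])] == peps[2]

    def test_internal_met_start_marks_prefix_truth_missing(self):
        gene, dna = simulate_locus(_base_config())
        peps = exon_peptides(gene, dna)
        met_positions = [i + 1 for i, aa in enumerate(peps[3]) if aa == "M"]
        if not met_positions:
            pytest.skip("seed produced no internal Met in exon 3")
        (iso, truth), = simulate_isoforms(gene, dna, [VariantSpec("alt", use_exons=(3, 4), start_met=(3, 1))])
        assert truth.labels[0] == (3, met_positions[0])
        assert truth.exon_peptide_positions(3) == set(range(met_positions[0], len(peps[3]) + 1))

    def test_empty_protein_is_an_error(self):
        gene, dna = simulate_locus(_base_config())
        with pytest.raises(ConfigurationError, match="empty protein"):
            simulate_isoforms(gene, dna, [VariantSpec("empty", use_exons=(2,), delete=((2, 1, 10_000),))])

    def test_unknown_start_met_is_an_error(self):
        gene, dna = simulate_locus(_base_config())
        with pytest.raises(ConfigurationError, match="start Met"):
            simulate_isoforms(gene, dna, [VariantSpec("x", use_exons=(2,), start_met=(2, 99))])


class TestTracks:
    def test_fixed_seed_reproduces_identical_tracks(self):
        cfg = _base_config(n_tracks=3)
        gene, _ = simulate_locus(cfg)
        a = simulate_tracks(gene, cfg)
        b = simulate_tracks(gene, cfg)
        assert [t.intervals for t in a] == [t.intervals for t in b]

    def test_planted_fold_reflected_in_bin_means(self):
        """In-segment mean is ~fold x background (Poisson expectation, >=50 bins)."""
        seg = PlantedSegment(20_001, 40_000, 8.0)  # 100 bins of 200 bp
        cfg = _base_config(n_tracks=4, planted_segments=[seg], background_rate=5.0)
        gene, _ = simulate_locus(cfg)
        values = np.array([[v for _, _, v in t.intervals] for t in simulate_tracks(gene, cfg)])
        starts = np.array([s for s, _, _ in simulate_tracks(gene, cfg)[0].intervals])
        inside = (starts >= seg.start) & (starts + 199 <= seg.end)
        outside = ~((starts >= seg.start - 400) & (starts <= seg.end + 400))
        ratio = values[:, inside].mean() / values[:, outside].mean()
        assert ratio == pytest.approx(8.0, rel=0.1)

    def test_carried_fraction_splits_tracks(self):
        seg = PlantedSegment(20_001, 40_000, 8.0, carried_fraction=0.5)
        cfg = _base_config(n_tracks=8, planted_segments=[seg])
        gene, _ = simulate_locus(cfg)
        tracks = simulate_tracks(gene, cfg)
        means = []
        for t in tracks:
            vals = [(s, v) for s, _, v in t.intervals]
            means.append(np.mean([v for s, v in vals if seg.start <= s <= seg.end - 200]))
        enriched = sum(m > 20 for m in means)
        assert enriched == 4


class TestMethylation:
    def test_beta_means_inside_and_outside_hmrs(self):
        cfg = _base_config(
            hmr_regions=[(10_001, 20_000)],
            meth_background_beta=(8.0, 2.0),
            meth_hmr_beta=(1.0, 9.0),
        )
        gene, _ = simulate_locus(cfg)
        tracks = simulate_methylation(gene, cfg, 4)
        inside, outside = [], []
        for t in tracks:
            for s, e, v in t.intervals:
                (inside if 10_001 <= s and e <= 20_000 else outside).append(v)
        assert np.mean(inside) == pytest.approx(1 / 10, abs=0.03)
        assert np.mean(outside) == pytest.approx(8 / 10, abs=0.03)
        assert all(0 <= v <= 1 for v in inside + outside)

    def test_no_hmr_regions_leaves_no_low_band(self):
        cfg = _base_config()
        gene, _ = simulate_locus(cfg)
        tracks = simulate_methylation(gene, cfg, 2)
        values = [v for t in tracks for _, _, v in t.intervals]
        assert np.mean(values) > 0.7

    def test_samples_are_independent_draws(self):
        cfg = _base_config()
        gene, _ = simulate_locus(cfg)
        a, b = simulate_methylation(gene, cfg, 2)
        assert [v for *_, v in a.intervals] != [v for *_, v in b.intervals]
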