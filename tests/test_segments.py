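import numpy as np
import pytest

from mecp2locus.segments import (
    CallerParams,
    MethylationTrack,
    SignalTrack,
    call_consensus_segments,
    call_hmrs,
    consistent_hmrs,
)
from mecp2locus.simulate import PlantedSegment, SimulationConfig, simulate_locus, simulate_methylation, simulate_tracks

REGION = (1, 120_000)


def _flat_track(sample_id, value, region=REGION, step=200):
    intervals = [(s, min(s + step - 1, region[1]), value) for s in range(region[0], region[1] + 1, step)]
    return SignalTrack(sample_id=sample_id, assay="ChIP", intervals=intervals)


def _interval_jaccard(calls, truth):
    inter = sum(
        max(0, min(e, te) - max(s, ts) + 1) for s, e in calls for ts, te in truth
    )
    union = sum(e - s + 1 for s, e in calls) + sum(e - s + 1 for s, e in truth) - inter
    return inter / union if union else 1.0


def _planted_setup(seed, n_tracks=8, fold=8.0):
    truth = [(20_000, 24_000), (60_000, 63_000), (90_000, 95_000)]
    cfg = SimulationConfig(
        seed=seed,
        locus_length=REGION[1],
        n_tracks=n_tracks,
        planted_segments=[PlantedSegment(s, e, fold) for s, e in truth],
    )
    gene, _ = simulate_locus(cfg)
    return gene, cfg, truth


class TestConsensusSegments:
    def test_all_zero_tracks_yield_no_segments(self):
        tracks = [_flat_track(f"t{i}", 0.0) for i in range(4)]
        assert call_consensus_segments(tracks, REGION) == []

    def test_constant_tracks_yield_one_region_spanning_segment(self):
        tracks = [_flat_track(f"t{i}", 5.0) for i in range(4)]
        calls = call_consensus_segments(tracks, REGION)
        assert [c.interval for c in calls] == [REGION]
        assert calls[0].support == 1.0

    def test_planted_segments_recovered(self):
        jaccards = []
        for seed in range(5):
            gene, cfg, truth = _planted_setup(seed)
            calls = call_consensus_segments(simulate_tracks(gene, cfg), REGION)
            jaccards.append(_interval_jaccard([c.interval for c in calls], truth))
        assert np.median(jaccards) >= 0.8

    def test_null_model_calls_almost_nothing(self):
        fractions = []
        for seed in range(5):
            gene, cfg, _ = _planted_setup(seed)
            null_cfg = SimulationConfig(seed=seed + 500, locus_length=REGION[1], n_tracks=8)
            calls = call_consensus_segments(simulate_tracks(gene, null_cfg), REGION)
            fractions.append(sum(c.length for c in calls) / REGION[1])
        assert np.median(fractions) <= 0.02

    def test_raising_thresholds_never_increases_called_length(self):
        gene, cfg, _ = _planted_setup(3)
        tracks = simulate_tracks(gene, cfg)

        def total(quantile, consensus):
            params = CallerParams(enrich_quantile=quantile, consensus_fraction=consensus)
            return sum(c.length for c in call_consensus_segments(tracks, REGION, params))

        assert total(0.75, 0.7) >= total(0.9, 0.7) >= total(0.9, 0.9)
        assert total(0.75, 0.7) >= total(0.75, 0.9)

    def test_idempotent_on_own_output_mask(self):
        gene, cfg, _ = _planted_setup(4)
        calls = call_consensus_segments(simulate_tracks(gene, cfg), REGION)
        intervals = [c.interval for c in calls]
        mask_tracks = []
        for i in range(4):
            vals = []
            for s in range(REGION[0], REGION[1] + 1, 200):
                e = min(s + 199, REGION[1])
                inside = any(ts <= s and e <= te for ts, te in intervals)
                vals.append((s, e, 8.0 if inside else 0.0))
            mask_tracks.append(SignalTrack(sample_id=f"m{i}", assay="ChIP", intervals=vals))
        recalled = call_consensus_segments(mask_tracks, REGION)
        assert [c.interval for c in recalled] == intervals

    def test_track_order_invariance(self):
        gene, cfg, _ = _planted_setup(5)
        tracks = simulate_tracks(gene, cfg)
        a = call_consensus_segments(tracks, REGION)
        b = call_consensus_segments(tracks[::-1], REGION)
        assert [(c.interval, c.label) for c in a] == [(c.interval, c.label) for c in b]

    def test_minus_strand_labels_run_in_transcription_direction(self):
        tracks = [_flat_track(f"t{i}", 0.0) for i in range(3)]
        for s, e, v in [(10_000, 12_000, 9.0), (50_000, 53_000, 9.0)]:
            for i, track in enumerate(tracks):
                track.intervals = [
                    (a, b, v if s <= a and b <= e else val) for a, b, val in track.intervals
                ]
        calls = call_consensus_segments(tracks, REGION, strand="-", label_prefix="S")
        assert [c.label for c in calls] == ["S1", "S2"]
        assert calls[0].interval[0] > calls[1].interval[0]

    def test_errors(self):
        with pytest.raises(ValueError, match="at least one track"):
            call_consensus_segments([], REGION)
        tracks = [_flat_track("t", 1.0)]
        with pytest.raises(ValueError, match="empty region"):
            call_consensus_segments(tracks, (10, 5))
        with pytest.raises(ValueError, match="bin_size"):
            call_consensus_segments(tracks, (1, 100), CallerParams(bin_size=200))


class TestHmrs:
    def test_fully_methylated_has_no_hmrs_and_unmethylated_spans_region(self):
        high = MethylationTrack("hi", [(s, s + 199, 1.0) for s in range(1, 120_000, 200)])
        low = MethylationTrack("lo", [(s, s + 199, 0.0) for s in range(1, 120_000, 200)])
        result = call_hmrs([high, low], REGION)
        assert result["hi"] == []
        assert result["lo"] == [(1, 120_000)]

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            MethylationTrack("bad", [(1, 100, 1.5)])

    def test_planted_hmrs_recovered_per_sample(self):
        truth = [(30_000, 33_000), (70_000, 72_400)]
        jaccards = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, locus_length=REGION[1], hmr_regions=truth)
            gene, _ = simulate_locus(cfg)
            tracks = simulate_methylation(gene, cfg, 6)
            for sample, hmrs in call_hmrs(tracks, REGION).items():
                jaccards.append(_interval_jaccard(hmrs, truth))
        assert np.median(jaccards) >= 0.8

    def test_consistent_hmrs_identical_inputs_returned_verbatim(self):
        hmrs = [(1_000, 3_000), (10_000, 12_000)]
        per_sample = {f"s{i}": list(hmrs) for i in range(6)}
        calls = consistent_hmrs(per_sample)
        assert [c.interval for c in calls] == hmrs
        assert all(c.support == 1.0 for c in calls)

    def test_hmr_in_single_sample_excluded(self):
        per_sample = {f"s{i}": [] for i in range(5)}
        per_sample["s5"] = [(1_000, 2_000)]
        assert consistent_hmrs(per_sample, min_samples=6) == []

    def test_planted_hmrs_survive_consistency_filter(self):
        truth = [(30_000, 33_000), (70_000, 72_400)]
        cfg = SimulationConfig(seed=9, locus_length=REGION[1], hmr_regions=truth)
        gene, _ = simulate_locus(cfg)
        per_sample = call_hmrs(simulate_methylation(gene, cfg, 6), REGION)
        calls = consistent_hmrs(per_sample)
        assert len(calls) == len(truth)
        assert _interval_jaccard([c.interval for c in calls], truth) >= 0.8
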