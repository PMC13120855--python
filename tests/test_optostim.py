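"""Photostimulation protocols, segment aggregation, and PS-locked curves."""

import numpy as np
import pytest

from dyadica import (
    ActionParams,
    BehaviorProfile,
    BoutTable,
    aggregate_by_segment,
    make_ramp_protocol,
    penetrance_expressivity,
    ps_locked_fraction,
    segment_masks,
    sham_persistence_baseline,
    simulate_ps_trial,
    suppression_summary,
)
from dyadica.optostim import PSProtocol

from conftest import make_table

FR = 30.0
N = int(720 * FR)


@pytest.fixture(scope="module")
def ramp():
    return make_ramp_protocol()


class TestProtocol:
    def test_canonical_onsets(self, ramp):
        assert [b.onset_s for b in ramp.blocks] == [120, 210, 300, 390, 480, 570]
        assert [b.freq_hz for b in ramp.blocks] == [1, 2, 5, 10, 20, 40]

    def test_empty_frequency_list_is_sham(self):
        p = make_ramp_protocol(frequencies=[])
        assert p.sham and p.blocks == ()

    def test_unsorted_frequencies_rejected(self):
        with pytest.raises(ValueError):
            make_ramp_protocol(frequencies=[1, 5, 2])

    def test_json_round_trip(self, ramp, tmp_path):
        ramp.to_json(tmp_path / "p.json")
        assert PSProtocol.from_json(tmp_path / "p.json") == ramp


class TestSegments:
    def test_masks_partition_every_frame(self, ramp):
        masks = segment_masks(ramp, N, FR)
        masks.assert_partition()
        assert masks.baseline.sum() == 120 * FR
        assert len(masks.on_blocks) == 6 and len(masks.ibis) == 5
        assert masks.post.sum() == 120 * FR

    def test_protocol_exceeding_trial_rejected(self, ramp):
        with pytest.raises(ValueError):
            segment_masks(ramp, int(300 * FR), FR)

    def test_lunges_in_ibis_pool_into_ps_plus_off(self, ramp):
        masks = segment_masks(ramp, N, FR)
        # one lunge per IBI, none elsewhere
        rows = [("A", "lunge", int((240 + k * 90) * FR), int((240 + k * 90) * FR) + 5)
                for k in range(5)]
        agg = aggregate_by_segment(make_table(rows), masks, "lunge", FR)
        get = lambda s: agg.set_index("segment").loc[s]
        assert get("PS+off")["count"] == 5
        assert get("PS-")["count"] == 0
        assert get("PS+on")["count"] == 0

    def test_uwe_only_during_blocks(self, ramp):
        masks = segment_masks(ramp, N, FR)
        rows = [("A", "UWE", int(b.onset_s * FR), int(b.offset_s * FR)) for b in ramp.blocks]
        agg = aggregate_by_segment(make_table(rows), masks, "UWE", FR)
        get = lambda s: agg.set_index("segment").loc[s]
        assert get("PS+on")["time_fraction"] == 1.0
        assert get("PS-")["time_fraction"] == 0.0

    def test_simulated_offset_persistence_fills_ibis(self, ramp):
        profile = BehaviorProfile(
            actions={"lunge": ActionParams(rate=0.02, dwell_mean=0.3)},
            ps_off_amp=5.0,
            ps_off_tau=30.0,
        )
        masks = segment_masks(ramp, N, FR)
        wins = 0
        n_seeds = 200
        for s in range(n_seeds):
            _, table = simulate_ps_trial(profile, ramp, pair=False, seed=s, duration_s=720)
            agg = aggregate_by_segment(table, masks, "lunge", FR).set_index("segment")
            # compare per-second rates: IBIs total 300 s vs 120 s baseline
            ibi_rate = agg.loc["PS+off", "count"] / agg.loc["PS+off", "seconds"]
            base_rate = agg.loc["PS-", "count"] / agg.loc["PS-", "seconds"]
            if ibi_rate > base_rate:
                wins += 1
        assert wins >= 0.95 * n_seeds


def step_table(fly, onsets, offsets, lead=3.0, fr=FR):
    """Bouts spanning [onset-lead, offset) for each block."""
    rows = [
        (fly, "UWE", int((a - lead) * fr), int(b * fr))
        for a, b in zip(onsets, offsets)
    ]
    return make_table(rows)


class TestLockedFraction:
    def test_step_curve_when_all_cease_at_offset(self, ramp):
        onsets = [b.onset_s for b in ramp.blocks]
        offsets = [b.offset_s for b in ramp.blocks]
        table = step_table("A", onsets, offsets)
        curve = ps_locked_fraction(
            [(table, ["A"])], ramp, N, FR, window_s=(-1.0, 31.0)
        )
        assert not curve.empty and curve.n_events == 6
        assert np.all(curve.fraction[curve.times_s < 30.0] == 1.0)
        assert np.all(curve.fraction[curve.times_s > 30.0] == 0.0)

    def test_persistent_sham_bouts_give_flat_high_curve(self, ramp):
        table = make_table([("A", "UWE", 0, N)])
        curve = ps_locked_fraction([(table, ["A"])], ramp, N, FR)
        assert np.all(curve.fraction == 1.0)

    def test_no_qualifying_blocks_flagged_empty(self, ramp):
        table = make_table([("A", "UWE", 0, 30)])  # far from any onset
        curve = ps_locked_fraction([(table, ["A"])], ramp, N, FR)
        assert curve.empty and curve.n_events == 0

    def test_equals_brute_force_indicator_average(self, ramp):
        rng = np.random.default_rng(0)
        rows = []
        t = 5.0
        while t < 700:
            d = rng.uniform(0.2, 8.0)
            rows.append(("A", "UWE", int(t * FR), int((t + d) * FR)))
            t += d + rng.uniform(0.2, 5.0)
        table = make_table(rows)
        curve = ps_locked_fraction([(table, ["A"])], ramp, N, FR)

        # independent brute-force: per-frame indicator, explicit scan
        ind = np.zeros(N)
        for _, _, a, b in rows:
            ind[a:b] = 1
        lo, hi = -int(1.0 * FR), int(5.0 * FR)
        filt = int(0.5 * FR)
        segs = []
        for blk in ramp.blocks:
            onset = int(round(blk.onset_s * FR))
            if ind[onset - filt : onset + filt + 1].any():
                segs.append(ind[onset + lo : onset + hi + 1])
        assert len(segs) == curve.n_events
        if segs:
            assert np.array_equal(np.mean(segs, axis=0), curve.fraction)


class TestPersistenceBaseline:
    def test_fraction_strictly_above_two_seconds(self):
        durs = [1.0, 3.0, 2.5, 0.8]
        table = make_table(
            [("A", "UWE", int(i * 200), int(i * 200 + d * FR)) for i, d in enumerate(durs)]
        )
        assert sham_persistence_baseline([table], "UWE", FR) == 0.5

    def test_boundary_duration_not_counted(self):
        table = make_table([("A", "UWE", 0, int(2.0 * FR))])
        assert sham_persistence_baseline([table], "UWE", FR) == 0.0

    def test_all_long_gives_one_and_empty_errors(self):
        table = make_table([("A", "UWE", 0, int(5 * FR))])
        assert sham_persistence_baseline([table], "UWE", FR) == 1.0
        with pytest.raises(ValueError):
            sham_persistence_baseline([BoutTable("t1")], "UWE", FR)


class TestSuppressionSummary:
    def test_full_and_zero_suppression_limits(self, ramp):
        onsets = [b.onset_s for b in ramp.blocks]
        offsets = [b.offset_s for b in ramp.blocks]
        persist = step_table("A", onsets, offsets)          # runs through ON
        cut = step_table("A", onsets, [o + 1 for o in onsets])  # stops 1 s in
        out = suppression_summary(
            {"low": [(persist, ["A"])], "high": [(cut, ["A"])]},
            ramp, N, FR, baseline=0.4,
        )
        out = out.set_index("condition")
        assert out.loc["low", "persisting_fraction"] == 1.0
        assert out.loc["high", "persisting_fraction"] == 0.0
        assert (out["sham_baseline"] == 0.4).all()


class TestPenetranceExpressivity:
    def test_full_responders_saturate_on_bins(self):
        proto = make_ramp_protocol(
            frequencies=[10, 20], block_s=15, baseline_s=30, ibi_s=30, intensity=50
        )
        n = int(120 * FR)
        tables = []
        for i in range(4):
            rows = [
                (f"f{i}", "threat", int(b.onset_s * FR), int(b.offset_s * FR))
                for b in proto.blocks
            ]
            tables.append((make_table(rows), f"f{i}"))
        bins, pen, mean_tr, sem_tr = penetrance_expressivity(
            tables, n, FR, action="threat", window_s=5.0
        )
        on = (bins > 30) & (bins < 45)
        off = bins < 29
        assert np.all(pen[on] == 1.0)
        assert np.all(pen[off] == 0.0)
        assert mean_tr.max() == 1.0

    def test_no_responders_flat_zero(self):
        tables = [(BoutTable("t1"), "f0"), (BoutTable("t1"), "f1")]
        bins, pen, mean_tr, sem_tr = penetrance_expressivity(tables, 3000, FR)
        assert pen.max() == 0.0 and mean_tr.max() == 0.0

    def test_mixed_responders_give_intermediate_penetrance(self):
        n = int(60 * FR)
        tables = []
        for i in range(10):
            if i % 2:
                rows = [(f"f{i}", "threat", int(30 * FR), int(40 * FR))]
                tables.append((make_table(rows), f"f{i}"))
            else:
                tables.append((BoutTable("t1"), f"f{i}"))
        bins, pen, _, _ = penetrance_expressivity(tables, n, FR)
        window = (bins > 31) & (bins < 39)
        assert np.allclose(pen[window], 0.5)
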