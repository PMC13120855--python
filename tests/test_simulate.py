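"""Generator contracts: determinism, degenerate limits, and renewal oracles."""

import numpy as np
import pytest

from dyadica import (
    ActionParams,
    ArenaSpec,
    BehaviorProfile,
    DEFAULT_CATALOG,
    SongSynthSpec,
    make_ramp_protocol,
    refine_peak,
    render_frames,
    santomea_like_profile,
    segment_trains,
    simulate_dyad,
    simulate_ps_trial,
    simulate_trio,
    simulate_walk,
    synthesize_song,
)


def uwe_profile(rate=0.05, mean=2.0, **kw):
    return BehaviorProfile(
        actions={"UWE": ActionParams(rate=rate, dwell_mean=mean)}, **kw
    )


class TestBoutGeneration:
    def test_seed_determinism(self):
        p = santomea_like_profile(dominance=0.4)
        a = simulate_dyad(p, p, 600, seed=11)
        b = simulate_dyad(p, p, 600, seed=11)
        assert a == b
        c = simulate_dyad(p, p, 600, seed=12)
        assert a[1].bouts != c[1].bouts

    def test_generated_tables_satisfy_core_invariants(self):
        p = santomea_like_profile(dominance=0.3, copulation_hazard=0.05)
        for seed in range(20):
            trial, table = simulate_dyad(p, p, 900, seed=seed)
            table.validate_against(trial, DEFAULT_CATALOG)  # raises on violation

    def test_zero_aggression_rates_give_no_aggression_bouts(self):
        p = BehaviorProfile(
            actions={
                "UWE": ActionParams(rate=0.1, dwell_mean=1.0),
                "lunge": ActionParams(rate=0.0),
            }
        )
        _, table = simulate_dyad(p, p, 1200, seed=3)
        assert len(table) > 0
        assert not any(DEFAULT_CATALOG.is_aggression(b.action) for b in table)

    def test_full_dominance_silences_fly_b(self):
        p = uwe_profile(rate=0.1, dominance=1.0)
        _, table = simulate_dyad(p, p, 1200, seed=5)
        assert len(table.for_fly("A")) > 0
        assert len(table.for_fly("B")) == 0

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            ActionParams(rate=float("nan"))
        with pytest.raises(ValueError):
            ActionParams(rate=-1.0)
        with pytest.raises(ValueError):
            uwe_profile(dominance=1.5)
        with pytest.raises(ValueError):
            BehaviorProfile(
                actions={"UWE": ActionParams(rate=0.1)},
                kernel={"UWE": {"UWE": 0.5, "circle": 0.2}},
            )

    def test_mean_bout_count_matches_renewal_oracle(self):
        # alternating renewal: cycle length 1/lam + mu, so expected bouts
        # per trial = T * lam / (1 + lam * mu)
        lam, mu, T = 0.05, 2.0, 1200.0
        p = uwe_profile(rate=lam, mean=mu)
        counts = [
            len(simulate_dyad(p, p, T, seed=s)[1].for_fly("A"))
            for s in range(400)
        ]
        expected = T * lam / (1 + lam * mu)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 1.0

    def test_dwell_means_recovered(self):
        lam, mu = 0.1, 2.0
        p = uwe_profile(rate=lam, mean=mu)
        durations = []
        for s in range(60):
            trial, table = simulate_dyad(p, p, 600, seed=s)
            durations += [
                b.duration_s(trial.frame_rate)
                for b in table
                if b.end < trial.duration  # drop trial-end-censored bouts
            ]
        se = np.std(durations, ddof=1) / np.sqrt(len(durations))
        assert abs(np.mean(durations) - mu) < 3 * se + 1.0 / 30

    def test_kernel_chain_frequencies_converge(self):
        kernel = {
            "UWE": {"UWE": 0.2, "circle": 0.8},
            "circle": {"UWE": 0.7, "circle": 0.3},
        }
        p = BehaviorProfile(
            actions={
                "UWE": ActionParams(rate=0.02, dwell_mean=1.0),
                "circle": ActionParams(rate=0.02, dwell_mean=1.0),
            },
            kernel=kernel,
            chain_prob=0.7,
        )
        counts = {a: {b: 0 for b in kernel} for a in kernel}
        n_pairs = 0
        seed = 0
        while n_pairs < 5000:
            trial, table = simulate_dyad(p, p, 3000, seed=seed)
            seed += 1
            for fly in ("A", "B"):
                seq = sorted(table.for_fly(fly), key=lambda b: b.start)
                for a, b in zip(seq, seq[1:]):
                    # chained successors start within the 0.5 s gap ceiling
                    if 0 <= b.start - a.end <= int(0.5 * trial.frame_rate):
                        counts[a.action][b.action] += 1
                        n_pairs += 1
        for a, row in kernel.items():
            tot = sum(counts[a].values())
            tv = 0.5 * sum(
                abs(counts[a][b] / tot - row[b]) for b in row
            )
            assert tv < 0.05

    def test_copulation_truncates_trial(self):
        p = BehaviorProfile(
            actions={"copulation attempt": ActionParams(rate=0.05, dwell_mean=2.0)},
            copulation_hazard=1.0,
        )
        hit = 0
        for s in range(20):
            trial, table = simulate_dyad(p, p, 1200, seed=s)
            if trial.copulation_onset is not None:
                hit += 1
                assert all(b.end <= trial.copulation_onset for b in table)
        assert hit > 10


class TestTrio:
    def test_symmetric_rates_give_zero_mean_preference(self):
        diffs = []
        for s in range(100):
            trial, table = simulate_trio(
                uwe_profile(), {"female": 0.02, "male": 0.02}, 1200, seed=s
            )
            tf = sum(b.frames for b in table if b.target == "female")
            tm = sum(b.frames for b in table if b.target == "male")
            if tf + tm:
                diffs.append((tf - tm) / (tf + tm))
        assert abs(np.mean(diffs)) < 0.05

    def test_zero_male_rate_gives_pi_one(self):
        trial, table = simulate_trio(
            uwe_profile(), {"female": 0.05, "male": 0.0}, 1200, seed=2
        )
        assert len(table) > 0
        assert all(b.target == "female" for b in table)


class TestPSTrial:
    def test_null_modulation_reproduces_protocol_free_stream(self):
        proto = make_ramp_protocol()
        p = uwe_profile(rate=0.05, ps_on_gain=1.0, ps_off_amp=0.0)
        t1, b1 = simulate_ps_trial(p, proto, seed=9, duration_s=720)
        p2 = uwe_profile(rate=0.05)
        t2, b2 = simulate_ps_trial(
            p2, make_ramp_protocol(sham=True), seed=9, duration_s=720
        )
        assert b1.bouts == b2.bouts

    def test_on_gain_concentrates_courtship_in_blocks(self):
        proto = make_ramp_protocol()
        p = uwe_profile(rate=0.005, mean=1.0, ps_on_gain=10.0)
        on_t = off_t = 0
        fr = 30.0
        on_frames = off_frames = 0
        for s in range(200):
            trial, table = simulate_ps_trial(p, proto, pair=False, seed=s, duration_s=720)
            ind = np.zeros(trial.duration, dtype=bool)
            for b in table:
                ind[b.start : b.end] = True
            mask = np.zeros(trial.duration, dtype=bool)
            for blk in proto.blocks:
                mask[int(blk.onset_s * fr) : int(blk.offset_s * fr)] = True
            on_t += ind[mask].sum()
            off_t += ind[~mask].sum()
            on_frames += mask.sum()
            off_frames += (~mask).sum()
        on_rate = on_t / on_frames
        off_rate = off_t / off_frames
        # occupancy ratio oracle: lam*g*mu/(1+..) vs lam*mu/(1+..);
        # at low rates the ratio approaches the gain
        assert on_rate / off_rate > 5

    def test_offset_persistence_boosts_attack_then_decays(self):
        proto = make_ramp_protocol()
        p = BehaviorProfile(
            actions={"lunge": ActionParams(rate=0.01, dwell_mean=0.3)},
            ps_off_amp=5.0,
            ps_off_tau=30.0,
        )
        early = late = base = 0
        for s in range(150):
            trial, table = simulate_ps_trial(p, proto, pair=False, seed=s, duration_s=720)
            for b in table:
                t = b.start / 30.0
                if t < 120:
                    base += 1
                for blk in proto.blocks:
                    if blk.offset_s <= t < blk.offset_s + 30:
                        early += 1
                    elif blk.offset_s + 30 <= t < blk.offset_s + 60:
                        late += 1
        # six 30 s early-IBI windows vs the 120 s baseline, per trial
        early_rate = early / (150 * 6 * 30)
        late_rate = late / (150 * 5 * 30)
        base_rate = base / (150 * 120)
        assert early_rate > 2 * base_rate
        assert early_rate > late_rate > base_rate * 0.5

    def test_overlapping_blocks_rejected(self):
        from dyadica import PSBlock, PSProtocol

        with pytest.raises(ValueError):
            PSProtocol(
                blocks=(
                    PSBlock(100, 30, 1.0),
                    PSBlock(110, 30, 2.0),
                )
            )


class TestSongSynthesis:
    def test_noiseless_peaks_recovered_exactly(self):
        spec = SongSynthSpec(noise_sd=0.0)
        wave, truth = synthesize_song(spec, {"pulse": 4, "clack": 3}, seed=1)
        for e in truth.events:
            t, a = refine_peak(wave, spec.sample_rate, e.time_s + 0.004)
            assert abs(t - e.time_s) <= 1.0 / spec.sample_rate
            assert abs(abs(a) - e.amplitude) < 0.05 * e.amplitude

    def test_ground_truth_trains_recovered_by_segmentation(self):
        spec = SongSynthSpec()
        wave, truth = synthesize_song(spec, {"pulse": 6, "clack": 4}, seed=2)
        seg = segment_trains(truth)
        truth_sets = sorted(
            [set(t.member_indices) for t in truth.trains], key=min
        )
        seg_sets = sorted([set(t.member_indices) for t in seg.trains], key=min)
        assert truth_sets == seg_sets

    def test_zero_trains_give_pure_noise(self):
        spec = SongSynthSpec(noise_sd=0.01)
        wave, truth = synthesize_song(spec, {"pulse": 0, "clack": 0}, seed=3)
        assert len(truth.events) == 0
        assert np.abs(wave).max() < 0.1


class TestWalks:
    def test_strong_bias_reaches_odor_arm(self):
        from dyadica import occupancy_index

        arena = ArenaSpec()
        trace = simulate_walk(arena, 3.0, 5000, seed=1)
        res = occupancy_index(trace, arena.masks())
        assert res["index"] > 0.95

    def test_scoring_masks_disjoint(self):
        masks = ArenaSpec().masks()
        total = sum(m.astype(int) for m in masks.values())
        assert total.max() <= 1

    def test_render_detect_recovers_positions_within_one_pixel(self):
        from dyadica import detect_positions, estimate_background

        arena = ArenaSpec()
        trace = simulate_walk(arena, 0.5, 150, seed=4)
        frames = render_frames(arena, trace)
        positions = detect_positions(frames, np.full(frames.shape[1:], 0.9), 0.3)
        for i, cents in enumerate(positions):
            assert len(cents) == 1
            x, y = cents[0]
            assert abs(x - trace[i, 0, 0]) <= 1.0
            assert abs(y - trace[i, 0, 1]) <= 1.0

    def test_detection_robust_to_pixel_noise(self):
        from dyadica import detect_positions

        arena = ArenaSpec()
        trace = simulate_walk(arena, 0.5, 60, seed=6)
        frames = render_frames(arena, trace, noise_sd=0.04, seed=6)
        positions = detect_positions(
            frames, np.full(frames.shape[1:], 0.9), 0.35
        )
        for i, cents in enumerate(positions):
            assert len(cents) >= 1
            x, y = min(
                cents,
                key=lambda c: (c[0] - trace[i, 0, 0]) ** 2 + (c[1] - trace[i, 0, 1]) ** 2,
            )
            assert abs(x - trace[i, 0, 0]) <= 2.0
            assert abs(y - trace[i, 0, 1]) <= 2.0
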