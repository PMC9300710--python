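import numpy as np
import pytest

from spinetrack.errors import ParameterError
from spinetrack.simulator import (DEFAULT_DENSITY_PER_UM, RenderParams,
                                  TurnoverParams, keyframe_states,
                                  make_phantom_zstack, patch_training_set,
                                  place_synapses, simulate_states,
                                  simulate_timeseries)


class TestPlaceSynapses:
    def test_zero_density_zero_synapses(self):
        assert len(place_synapses(30.0, 0.0, rng=0)) == 0

    def test_poisson_mean_recovered(self):
        # density 2.56/μm on 30 μm over many draws: pooled mean within 3 SE
        counts = [len(place_synapses(30.0, rng=seed)) for seed in range(1000)]
        expected = DEFAULT_DENSITY_PER_UM * 30.0
        se = np.sqrt(expected / 1000)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_sorted_and_in_range(self):
        pos = place_synapses(12.0, 3.0, rng=7)
        assert (np.diff(pos) >= 0).all()
        assert pos.min() >= 0 and pos.max() <= 12.0


class TestTurnover:
    def test_absorbing_off_state(self):
        p = TurnoverParams(p_on=0.0, p_off=0.5, steps=50)
        states = simulate_states(20, p, rng=0)
        assert states[:, -1].sum() == 0  # off is absorbing once reached
        # and no off->on transition ever occurs
        turned_on = (np.diff(states.astype(int), axis=1) > 0).any()
        assert not turned_on

    def test_deterministic_flip(self):
        p = TurnoverParams(p_on=1.0, p_off=1.0, steps=10)
        states = simulate_states(5, p, rng=1)
        diffs = np.abs(np.diff(states.astype(int), axis=1))
        assert (diffs == 1).all()

    def test_stationary_on_fraction(self):
        p = TurnoverParams()
        states = simulate_states(500, p, rng=2)
        per_chain = states.mean(axis=1)
        se = per_chain.std(ddof=1) / np.sqrt(len(per_chain))
        assert abs(per_chain.mean() - p.stationary_on_fraction) < 3 * se
        assert p.stationary_on_fraction == pytest.approx(0.19608, abs=1e-4)

    def test_transition_rates_match_parameters(self):
        # 500 chains × 2000 steps ≈ 1e6 exposures
        p = TurnoverParams()
        states = simulate_states(500, p, rng=3).astype(int)
        prev, nxt = states[:, :-1], states[:, 1:]
        n_off = (prev == 0).sum()
        n_on = (prev == 1).sum()
        p_on_hat = ((prev == 0) & (nxt == 1)).sum() / n_off
        p_off_hat = ((prev == 1) & (nxt == 0)).sum() / n_on
        assert abs(p_on_hat - p.p_on) < 3 * np.sqrt(p.p_on * (1 - p.p_on) / n_off)
        assert abs(p_off_hat - p.p_off) < 3 * np.sqrt(p.p_off * (1 - p.p_off) / n_on)


class TestKeyframes:
    def test_identity_sampling(self):
        states = simulate_states(4, TurnoverParams(steps=10), rng=0)
        np.testing.assert_array_equal(keyframe_states(states, 10), states)

    def test_default_indices_are_eighty_spaced(self):
        states = np.tile(np.arange(2000, dtype=np.uint8) % 2, (1, 1))
        kf = keyframe_states(states, 26)
        expected_idx = np.minimum(np.arange(26) * 80, 1999)
        np.testing.assert_array_equal(kf[0], states[0, expected_idx])

    def test_static_chain_constant_columns(self):
        states = np.ones((3, 100), dtype=np.uint8)
        kf = keyframe_states(states, 5)
        assert (kf == 1).all()

    def test_too_few_keyframes_rejected(self):
        with pytest.raises(ParameterError):
            keyframe_states(np.zeros((2, 10), np.uint8), 1)


class TestRendering:
    def test_no_synapses_dendrite_only(self):
        sim = simulate_timeseries(seed=0, density_per_um=0.0,
                                  turnover=TurnoverParams(steps=10, n_keyframes=2))
        truth = sim.truths[0]
        assert truth["spine_mask"].sum() == 0
        assert truth["dendrite_mask"].sum() > 0
        assert len(truth["centers_px"]) == 0

    def test_prenoise_intensity_bounds(self, noiseless_sim):
        for truth in noiseless_sim.truths[:3]:
            assert truth["noiseless"].max() <= 2000.0 + 1e-9
            assert truth["noiseless"].min() >= 0.0

    def test_dendrite_paint_mean(self):
        # mean painted intensity inside the true tube ≈ 1000 (±3 SE of N(1000,100))
        from spinetrack.simulator import (_dendrite_mask,
                                          make_dendrite_geometry)
        rng = np.random.default_rng(0)
        params = RenderParams()
        geom = make_dendrite_geometry(params, rng)
        dend = _dendrite_mask(geom, params)
        n = int(dend.sum())
        assert n > 4_000
        paint = rng.normal(params.dendrite_mean, params.dendrite_sd, n)
        assert abs(paint.mean() - 1000.0) < 3 * 100.0 / np.sqrt(n)

    def test_isolated_centers_are_local_maxima(self, noiseless_sim):
        # geometric consistency: spine centers coincide with local intensity
        # maxima of the noiseless render; asserted for spines without another
        # spine within 12 px (overlapping blobs legitimately merge peaks)
        from scipy import ndimage as ndi
        total, ok = 0, 0
        for truth in noiseless_sim.truths:
            img = truth["noiseless"]
            centers = truth["centers_px"]
            mx = (ndi.maximum_filter(img, size=5) == img) & (img > 0)
            pr, pc = np.nonzero(mx)
            for i, (r, c) in enumerate(centers):
                others = np.delete(centers, i, axis=0)
                if len(others) and np.sqrt(
                        ((others - [r, c]) ** 2).sum(1)).min() < 12:
                    continue
                total += 1
                d = np.sqrt((pr - r) ** 2 + (pc - c) ** 2).min()
                ok += d <= 2.0
        assert total > 100
        assert ok / total >= 0.95

    def test_seed_reproducibility_bit_exact(self):
        t = TurnoverParams(steps=50, n_keyframes=3)
        a = simulate_timeseries(seed=11, turnover=t)
        b = simulate_timeseries(seed=11, turnover=t)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.data, fb.data)

    def test_counts_vary_over_keyframes(self):
        varying = 0
        for seed in range(5):
            sim = simulate_timeseries(seed=seed,
                                      turnover=TurnoverParams(n_keyframes=10))
            varying += len(np.unique(sim.true_counts)) > 1
        assert varying >= 4


class TestPhantom:
    def test_zero_neck_tangent_sphere(self):
        _, truth = make_phantom_zstack(neck_length_um=0.0)
        assert truth["neck_length_um"] == 0.0
        assert truth["neck_mask"].sum() == 0

    def test_constructive_neck_length(self):
        _, truth = make_phantom_zstack(neck_length_um=1.5, shape=(96, 96, 16))
        assert truth["neck_length_um"] == 1.5
        # gap between surfaces equals the stated length by construction
        head_c = truth["head_center_um"]
        surf = truth["surface_point_um"]
        gap = np.linalg.norm(head_c - surf) - 0.4  # minus head radius
        assert gap == pytest.approx(1.5, abs=1e-9)

    def test_overlap_beyond_tangency_rejected(self):
        with pytest.raises(ParameterError):
            make_phantom_zstack(neck_length_um=-0.5)

    def test_registration_cross_module_shift_recovery(self):
        from scipy import ndimage as ndi

        from spinetrack.registration import global_register
        stack, _ = make_phantom_zstack(neck_length_um=1.0, seed=2)
        shifted = np.stack([np.clip(np.fft.ifftn(ndi.fourier_shift(
            np.fft.fftn(stack.data[:, :, z]), (1.5, -0.75))).real, 0, None)
            for z in range(stack.data.shape[2])], axis=-1)
        from spinetrack.imgio import ZStack
        est, _ = global_register(stack, ZStack(shifted, stack.geometry))
        assert abs(est.dy - 1.5) < 0.05 and abs(est.dx + 0.75) < 0.05


class TestPatchTrainingSet:
    def test_class1_centered_on_true_spines_and_class9_clean(self, lownoise_sim):
        X, y = patch_training_set(lownoise_sim, n_per_class=20, seed=0)
        assert X.shape[1] == X.shape[2] == 47  # 3.4 μm at 72 nm/px, forced odd
        assert len(np.unique(y)) >= 8
        half = X.shape[1] // 2
        # class-9 patches: central region darker than class-1 centers
        c1 = X[y == 1][:, half - 2:half + 3, half - 2:half + 3].mean()
        c9 = X[y == 9][:, half - 2:half + 3, half - 2:half + 3].mean()
        assert c1 > 3 * c9

    def test_deterministic_given_seed(self, lownoise_sim):
        X1, y1 = patch_training_set(lownoise_sim, n_per_class=10, seed=4)
        X2, y2 = patch_training_set(lownoise_sim, n_per_class=10, seed=4)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)


def test_density_recovered_across_simulations():
    total, length = 0, 0.0
    for seed in range(50):
        pos = place_synapses(30.0, rng=1000 + seed)
        total += len(pos)
        length += 30.0
    density = total / length
    se = np.sqrt(DEFAULT_DENSITY_PER_UM / length)
    assert abs(density - DEFAULT_DENSITY_PER_UM) < 3 * se
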