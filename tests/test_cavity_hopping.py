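"""Trajectory analysis: MSD, HMM, PMF, TST, hop statistics, slicing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavitydiff import cavity_hopping as ch
from cavitydiff import synthetic_data as sd
from cavitydiff.trajectory import Trajectory


def _static_traj(n=1000, pos=(1.0, 1.0, 1.0)):
    x = np.tile(np.asarray(pos), (n, 1))
    return Trajectory(
        times=np.arange(n, dtype=float),
        positions=x,
        unwrapped=x.copy(),
        box=np.array([2.0, 2.0, 2.0]),
    )


class TestMSD:
    def test_brownian_recovery(self, brownian_traj):
        res = ch.msd_diffusion(brownian_traj, fit_window=(10.0, 200.0))
        assert abs(res.d - 1e-9) / 1e-9 < 0.05
        assert res.diffusive

    def test_static_zero(self):
        res = ch.msd_diffusion(_static_traj(), fit_window=(10.0, 100.0))
        assert res.d == 0.0

    def test_wrapped_only_guard(self):
        traj = _static_traj()
        traj.unwrapped = None
        with pytest.raises(ValueError, match="unwrapped"):
            ch.msd_diffusion(traj)

    def test_confined_flagged_subdiffusive(self):
        # bounded jitter around a fixed point: MSD plateaus at 2*sigma^2*3
        rng = np.random.default_rng(5)
        x = 1.0 + 0.1 * rng.standard_normal((20_000, 3))
        traj = Trajectory(
            times=np.arange(20_000.0),
            positions=np.mod(x, 2.0),
            unwrapped=x,
            box=np.array([2.0, 2.0, 2.0]),
        )
        with pytest.warns(UserWarning, match="sub-diffusive"):
            res = ch.msd_diffusion(traj, fit_window=(100.0, 2000.0))
        assert not res.diffusive

    def test_window_beyond_lags(self):
        with pytest.raises(ValueError, match="beyond sampled lags"):
            ch.msd_diffusion(_static_traj(100), fit_window=(10.0, 1e6))


class TestFitHMM:
    def test_two_state_timescale(self, two_state_traj):
        traj, _ = two_state_traj
        model = ch.fit_hmm(traj, n_states=2, lag=10.0, n_bootstrap=20, seed=0)
        truth = 1.0 / (1.0 + 4.0)  # 0.2 ns
        assert abs(model.timescales_ns[0] - truth) / truth < 0.10
        lo, hi = model.timescale_ci_ns[:, 0]
        assert lo <= truth <= hi

    def test_rows_stochastic_and_stationary(self, two_state_traj):
        traj, _ = two_state_traj
        model = ch.fit_hmm(traj, n_states=2, lag=10.0, n_bootstrap=0)
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-10)
        pi = model.stationary
        np.testing.assert_allclose(pi @ model.transmat, pi, atol=1e-10)
        # occupancies ~ k21/(k12+k21) = 0.8 / 0.2 (order-free check)
        assert np.isclose(sorted(pi)[1], 0.8, atol=0.05)

    def test_state_assignment_matches_truth(self, two_state_traj):
        traj, states = two_state_traj
        model = ch.fit_hmm(traj, n_states=2, lag=1.0, n_bootstrap=0)
        path = model.state_sequence
        agreement = max(
            np.mean(path == states), np.mean(path == 1 - states)
        )
        assert agreement > 0.99

    def test_single_state_no_timescale(self, boltzmann_traj):
        model = ch.fit_hmm(boltzmann_traj, n_states=1, lag=10.0, n_bootstrap=0)
        assert model.n_states == 1
        assert len(model.timescales_ns) == 0

    def test_overfit_states_still_stochastic(self, two_state_traj):
        # asking for 3 states on 2-state data: either an empty state is
        # dropped (with a warning) or a cluster is split; both are valid
        traj, _ = two_state_traj
        model = ch.fit_hmm(traj, n_states=3, lag=10.0, n_bootstrap=0, seed=1)
        assert model.n_states in (2, 3)
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="50"):
            ch.fit_hmm(_static_traj(100), n_states=2, lag=10.0)

    def test_timescale_error_shrinks_with_length(self):
        truth = 0.2
        errs = []
        for n_steps in (20_000, 180_000):
            traj, _ = sd.gen_two_state_jump(
                1.0, 4.0, emission_sd=0.08, dt=1.0, n_steps=n_steps, seed=42
            )
            model = ch.fit_hmm(traj, n_states=2, lag=10.0, n_bootstrap=0)
            errs.append(abs(model.timescales_ns[0] - truth))
        assert errs[-1] < errs[0]

    def test_three_well_occupancies_boltzmann(self):
        wells = [
            ((0.64, 1.28, 1.28), 12.0, 0.42),
            ((1.92, 1.28, 1.28), 11.0, 0.42),
            ((3.20, 1.28, 1.28), 12.0, 0.42),
        ]
        traj = sd.gen_langevin_trajectory(
            wells=wells,
            box=(3.84, 2.56, 2.56),
            friction=10.0,
            dt=0.01,
            n_steps=8_000_000,
            sample_stride=10,
            seed=21,
        )
        model = ch.fit_hmm(traj, n_states=3, lag=10.0, n_bootstrap=0, seed=0)
        assert model.n_states == 3
        # Boltzmann oracle by quadrature, partitioned by nearest well center
        pot = traj.meta["potential"]
        g = [np.linspace(0, b, 65)[:-1] + b / 128 for b in (3.84, 2.56, 2.56)]
        xx, yy, zz = np.meshgrid(*g, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
        w = np.exp(-pot.energy(pts))
        centers = np.array([c for c, _, _ in wells])
        nearest = np.argmin(
            np.linalg.norm(pts[:, None, :] - centers, axis=2), axis=1
        )
        expected = np.array([w[nearest == i].sum() for i in range(3)])
        expected /= expected.sum()
        # match HMM states to well centers
        order = np.argmin(
            np.linalg.norm(model.means[:, None, :] - centers, axis=2), axis=1
        )
        pi = np.empty(3)
        pi[order] = model.stationary
        np.testing.assert_allclose(pi, expected, atol=0.06)


class TestSelectNStates:
    def test_two_state_selected(self, two_state_traj):
        traj, _ = two_state_traj
        n, diag = ch.select_n_states(traj, lag=10.0, candidates=(1, 2, 3, 4))
        assert n == 2
        assert set(diag["scores"]) == {1, 2, 3, 4}

    def test_brownian_selects_one(self):
        traj = sd.gen_langevin_trajectory(
            wells=[((500.0, 500.0, 500.0), 0.0, 1.0)],
            box=(1000, 1000, 1000),
            friction=10.0,
            dt=0.1,
            n_steps=50_000,
            sample_stride=5,
            x0=np.array([500.0, 500.0, 500.0]),
            seed=0,
        )
        n, _ = ch.select_n_states(traj, lag=10.0, candidates=(1, 2, 3, 4))
        assert n == 1

    def test_shallow_third_well_documented_ambiguity(self):
        wells = [
            ((0.64, 1.28, 1.28), 10.0, 0.42),
            ((1.92, 1.28, 1.28), 10.0, 0.42),
            ((3.20, 1.28, 1.28), 3.0, 0.42),
        ]
        traj = sd.gen_langevin_trajectory(
            wells=wells,
            box=(3.84, 2.56, 2.56),
            friction=10.0,
            dt=0.01,
            n_steps=2_000_000,
            sample_stride=10,
            seed=5,
        )
        n, diag = ch.select_n_states(traj, lag=10.0, candidates=(1, 2, 3, 4))
        # the 3 kBT well is barely metastable: 2 or 3 are both defensible
        assert n in (2, 3)
        assert len(diag["scores"]) == 4

    def test_bad_candidates(self):
        with pytest.raises(ValueError, match="1..8"):
            ch.select_n_states(_static_traj(), candidates=(0, 9))


class TestPMF:
    def test_uniform_flat(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2, size=(200_000, 3))
        grid = ch.compute_pmf(x, bin_width=0.25, box=np.array([2.0, 2.0, 2.0]))
        assert grid.sampled_fraction == 1.0
        assert np.nanmax(grid.values) < 0.1

    def test_two_bin_log_identity(self):
        n2 = 10_000
        n1 = int(round(np.e * n2))
        x = np.zeros((n1 + n2, 3))
        x[:n1, 1] = 0.25
        x[n1:, 1] = 0.75
        x[:, 2] = 0.5
        grid = ch.compute_pmf(
            x, bin_width=0.5, box=np.array([1.0, 1.0, 1.0]), min_samples=100
        )
        vals = grid.values[~grid.mask]
        delta = vals.max() - vals.min()
        assert delta == pytest.approx(np.log(n1 / n2), abs=1e-12)
        assert delta == pytest.approx(1.0, abs=1e-4)

    def test_gauge_min_zero_and_masking(self):
        rng = np.random.default_rng(1)
        x = 0.3 * rng.standard_normal((50_000, 3)) + 2.0
        grid = ch.compute_pmf(x, bin_width=0.1, box=np.array([4.0, 4.0, 4.0]))
        assert np.nanmin(grid.values) == 0.0
        assert grid.mask.any()
        assert np.all(np.isnan(grid.values[grid.mask]))

    def test_gaussian_curvature_recovery(self):
        rng = np.random.default_rng(2)
        sigma = 0.25
        x = sigma * rng.standard_normal((2_000_000, 3)) + 2.0
        grid = ch.compute_pmf(x, bin_width=0.05, box=np.array([4.0, 4.0, 4.0]))
        yc = 0.5 * (grid.edges_x[:-1] + grid.edges_x[1:])
        i0 = np.nanargmin(np.abs(yc - 2.0))
        sel = np.abs(yc - 2.0) < 2 * sigma
        profile = grid.values[sel, i0]
        coef = np.polyfit(yc[sel] - 2.0, profile, 2)
        curvature = 2 * coef[0]
        assert abs(curvature - 1.0 / sigma**2) / (1.0 / sigma**2) < 0.05

    def test_single_bin_warning(self):
        rng = np.random.default_rng(3)
        x = 0.01 * rng.standard_normal((20_000, 3)) + 0.5
        with pytest.warns(UserWarning, match="bin width too large"):
            ch.compute_pmf(x, bin_width=1.0, box=np.array([2.0, 2.0, 2.0]))

    def test_min_samples(self):
        with pytest.raises(ValueError, match="samples"):
            ch.compute_pmf(np.zeros((100, 3)), bin_width=0.1)

    def test_gauge_invariance_of_differences(self):
        """Rescaling total counts shifts PMF uniformly; differences fixed."""
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, size=(40_000, 3))
        g1 = ch.compute_pmf(x, bin_width=0.25, box=np.ones(3))
        g2 = ch.compute_pmf(
            np.repeat(x, 3, axis=0), bin_width=0.25, box=np.ones(3)
        )
        d1 = g1.values - g1.values[0, 0]
        d2 = g2.values - g2.values[0, 0]
        np.testing.assert_allclose(d1, d2, atol=1e-12)


@pytest.fixture(scope="module")
def fluctuating_potential():
    return sd.MultiWellPotential(
        centers=np.array([[1.5, 1.5, 2.0], [2.5, 2.5, 2.0]]),
        depths=np.array([5.0, 5.0]),
        widths=np.array([0.35, 0.35]),
        box=np.array([4.0, 4.0, 4.0]),
        fluctuation_amplitude=2.0,
        fluctuation_timescale=1000.0,
        phases=np.array([np.pi / 2, -np.pi / 2]),
    )


class TestFrozenMatrixProbe:
    def test_static_same_seed_exactly_zero(self, fluctuating_potential):
        static = fluctuating_potential.frozen(0.0)
        _, metrics, _ = ch.frozen_matrix_probe(
            static,
            [0.0, 500.0, 1000.0],
            n_steps=100_000,
            bin_width=0.2,
            sample_stride=4,
            seed=7,
            per_slice_seeds=False,
        )
        np.testing.assert_array_equal(metrics, 0.0)

    def test_modulation_detected_above_static_baseline(self, fluctuating_potential):
        kw = dict(n_steps=400_000, bin_width=0.2, sample_stride=4, seed=7)
        _, fluct, _ = ch.frozen_matrix_probe(
            fluctuating_potential, [0.0, 500.0, 1000.0], **kw
        )
        # static control with the unmodulated depths (not frozen(0), which
        # bakes the +/-2 kBT modulation into the landscape)
        static = sd.MultiWellPotential(
            centers=fluctuating_potential.centers,
            depths=fluctuating_potential.depths,
            widths=fluctuating_potential.widths,
            box=fluctuating_potential.box,
        )
        _, base, _ = ch.frozen_matrix_probe(static, [0.0, 500.0, 1000.0], **kw)
        assert fluct.mean() > 1.5 * base.mean()

    def test_rerandomized_saturates(self, fluctuating_potential):
        class Rerandomized:
            """Duck-typed potential: a fresh well layout per freeze time."""

            box = np.array([4.0, 4.0, 4.0])

            def frozen(self, t):
                rng = np.random.default_rng(int(t) + 123)
                centers = rng.uniform(1.0, 3.0, size=(2, 3))
                return sd.MultiWellPotential(
                    centers=centers,
                    depths=np.array([5.0, 5.0]),
                    widths=np.array([0.35, 0.35]),
                    box=self.box,
                )

        kw = dict(n_steps=300_000, bin_width=0.25, sample_stride=4, seed=9)
        _, rerand, _ = ch.frozen_matrix_probe(
            Rerandomized(), [0.0, 1000.0, 2000.0], **kw
        )
        static = fluctuating_potential.frozen(0.0)
        _, base, _ = ch.frozen_matrix_probe(static, [0.0, 1000.0, 2000.0], **kw)
        assert rerand.mean() > 3.0 * base.mean()

    def test_requires_frozen_support(self):
        with pytest.raises(TypeError, match="frozen"):
            ch.frozen_matrix_probe(object(), [0.0])


class TestTST:
    def test_rate_equals_prefactor_zero_barrier(self):
        assert ch.tst_barrier(100.0, prefactor=100.0).delta_g == 0.0

    def test_paper_band_consistency(self):
        # 6.42 kBT with kBT/h at 300 K -> ~10 ns^-1, inside 1..50
        rate = ch.tst_rate(6.42, temperature=300.0)
        assert 1.0 < rate < 50.0
        assert np.isclose(rate, 10.2, rtol=0.02)

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ch.tst_barrier(10.0, prefactor=1.0)

    @given(
        rate=st.floats(1e-6, 1e3),
        prefactor=st.floats(1e3, 1e7),
    )
    @settings(max_examples=100, deadline=None)
    def test_bijection_machine_precision(self, rate, prefactor):
        est = ch.tst_barrier(rate, prefactor=prefactor)
        back = ch.tst_rate(est.delta_g, prefactor=prefactor)
        assert np.isclose(back, rate, rtol=1e-12)


def _model_from_sequence(seq, lag_ps=1.0, n_states=None):
    seq = np.asarray(seq)
    n = n_states or int(seq.max()) + 1
    transmat = np.full((n, n), 1.0 / n)
    return ch.MarkovModel(
        n_states=n,
        means=np.zeros((n, 3)),
        sds=np.ones(n),
        transmat=transmat,
        lag_ps=lag_ps,
        stationary=np.full(n, 1.0 / n),
        state_sequence=seq,
        timescales_ns=np.array([]),
    )


class TestHopStatistics:
    def test_alternating_filter_semantics(self):
        seq = np.array([0, 1] * 50)
        model = _model_from_sequence(seq)
        st1 = ch.hop_statistics(model, min_dwell=1.0)
        assert st1.n_hops == len(seq) - 1
        st3 = ch.hop_statistics(model, min_dwell=3.0)
        assert st3.n_hops == 0

    def test_three_state_cycle_no_returns(self):
        seq = np.array([0, 1, 2] * 40)
        model = _model_from_sequence(seq)
        stats = ch.hop_statistics(model, min_dwell=1.0)
        assert stats.return_trip_fraction == 0.0

    def test_two_state_rate_recovery(self):
        traj, _ = sd.gen_two_state_jump(
            2.0, 2.0, emission_sd=0.08, dt=1.0, n_steps=100_000, seed=6
        )
        model = ch.fit_hmm(traj, n_states=2, lag=5.0, n_bootstrap=0)
        stats = ch.hop_statistics(model, min_dwell=5.0)
        # total hop rate out of the stationary mix = 2 ns^-1
        assert abs(stats.hops_per_ns - 2.0) / 2.0 < 0.15

    def test_all_one_state(self):
        model = _model_from_sequence(np.zeros(100, dtype=int), n_states=2)
        stats = ch.hop_statistics(model)
        assert stats.n_hops == 0
        assert len(stats.dwell_times_ns[1]) == 0

    def test_min_dwell_below_frame_rejected(self):
        model = _model_from_sequence(np.array([0, 1, 0, 1]), lag_ps=10.0)
        with pytest.raises(ValueError, match="frame interval"):
            ch.hop_statistics(model, min_dwell=5.0)

    def test_dwell_count_identity(self):
        """Hops equal transitions of the dwell-filtered sequence."""
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 3, size=500)
        model = _model_from_sequence(seq)
        stats = ch.hop_statistics(model, min_dwell=2.0)
        total_runs = sum(len(d) for d in stats.dwell_times_ns.values())
        assert stats.n_hops == total_runs - 1


class TestAutocorrelation:
    def test_white_noise_fast(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2000, 3)) + 5.0
        traj = Trajectory(
            times=np.arange(2000.0),
            positions=x,
            unwrapped=x,
            box=np.array([100.0] * 3),
        )
        res = ch.position_autocorrelation(traj)
        assert res.decorrelation_time_ns <= traj.dt * 1e-3 * 1.01

    def test_ou_relaxation_time(self):
        theta = 50.0  # ps
        rng = np.random.default_rng(2)
        n = 200_000
        x = np.zeros((n, 3))
        for i in range(1, n):
            x[i] = x[i - 1] * (1 - 1.0 / theta) + np.sqrt(
                2 * 0.01
            ) * rng.standard_normal(3)
        traj = Trajectory(
            times=np.arange(float(n)),
            positions=x + 50,
            unwrapped=x + 50,
            box=np.array([100.0] * 3),
        )
        res = ch.position_autocorrelation(traj)
        assert not res.censored
        assert abs(res.decorrelation_time_ns - theta * 1e-3) / (theta * 1e-3) < 0.10

    def test_drift_censored(self):
        x = np.outer(np.linspace(0, 10, 500), np.ones(3))
        traj = Trajectory(
            times=np.arange(500.0),
            positions=x,
            unwrapped=x,
            box=np.array([100.0] * 3),
        )
        assert ch.position_autocorrelation(traj).censored

    def test_min_frames(self):
        with pytest.raises(ValueError, match="100 frames"):
            ch.position_autocorrelation(_static_traj(50))


class TestSliceAndModel:
    def test_stationary_two_state_consistent_slices(self):
        traj, _ = sd.gen_two_state_jump(
            2.0, 2.0, emission_sd=0.08, dt=1.0, n_steps=8000, seed=3
        )
        models = ch.slice_and_model(
            traj, slice_length_ns=2.0, lag=2.0, candidates=(1, 2, 3)
        )
        fitted = [m for _, m in models if m is not None]
        assert len(fitted) == 4
        assert all(m.n_states == 2 for m in fitted)

    def test_regime_switch_detected(self):
        traj, _ = sd.gen_two_state_jump(
            2.0, 2.0, emission_sd=0.06, dt=1.0, n_steps=4000, seed=8
        )
        rng = np.random.default_rng(9)
        merged = traj.positions.mean(axis=0) + 0.06 * rng.standard_normal((4000, 3))
        pos = np.vstack([traj.positions, merged])
        full = Trajectory(
            times=np.arange(8000.0),
            positions=pos,
            unwrapped=pos.copy(),
            box=traj.box,
        )
        models = ch.slice_and_model(
            full, slice_length_ns=4.0, lag=2.0, candidates=(1, 2, 3)
        )
        assert models[0][1].n_states == 2
        assert models[1][1].n_states == 1

    def test_single_slice_when_too_long(self, two_state_traj):
        traj, _ = two_state_traj
        models = ch.slice_and_model(
            traj.slice_frames(0, 5000), slice_length_ns=100.0, lag=5.0,
            candidates=(1, 2),
        )
        assert len(models) == 1

    def test_short_slice_skipped(self):
        traj, _ = sd.gen_two_state_jump(2.0, 2.0, dt=1.0, n_steps=2000, seed=0)
        with pytest.warns(UserWarning, match="too short"):
            models = ch.slice_and_model(
                traj, slice_length_ns=0.04, lag=10.0, candidates=(1, 2)
            )
        assert all(m is None for _, m in models)
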