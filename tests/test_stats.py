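"""Partitioning statistics: dm, dynamics, ordering, population curves, tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import massdivide as md
from massdivide.division import DivisionEvent
from massdivide.stats import AsymmetryRecord, heatmap_matrix


def _event(eid, dm0, rate, n=21, interval=3.0, pair_mass=600.0):
    t = np.arange(n) * interval
    dm = dm0 + rate * t
    m1 = pair_mass * (0.5 + dm / 4.0)
    return DivisionEvent(event_id=eid, parent_track=0, d1_track=1, d2_track=2,
                         t_furrow=0.0, m_parent=pair_mass,
                         m_d1=float(m1[0]), m_d2=float(pair_mass - m1[0]),
                         times=t, dm_signed=dm)


class TestDeltaM:
    def test_hand_computed_values(self):
        assert md.delta_m(200.0, 200.0) == 0.0
        assert md.delta_m(300.0, 100.0) == pytest.approx(1.0)
        assert md.delta_m(150.0, 0.0) == pytest.approx(2.0)

    def test_signed_form_keeps_direction(self):
        assert md.delta_m(100.0, 300.0, signed=True) == pytest.approx(-1.0)

    def test_zero_pair_mass_rejected(self):
        with pytest.raises(ValueError):
            md.delta_m(0.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(m1=st.floats(0.1, 1e3), m2=st.floats(0.1, 1e3),
           k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, m1, m2, k):
        assert md.delta_m(k * m1, k * m2) == pytest.approx(
            md.delta_m(m1, m2), rel=1e-9)


class TestAsymmetryDynamics:
    def test_constant_series_zero_rate(self):
        rec = md.asymmetry_dynamics(_event(0, dm0=0.3, rate=0.0))
        assert rec.rate == pytest.approx(0.0, abs=1e-12)
        assert rec.theta == pytest.approx(0.0, abs=1e-9)

    def test_pure_slope_theta_pi_over_2(self):
        rec = md.asymmetry_dynamics(_event(0, dm0=0.0, rate=0.02 / 60.0))
        assert rec.theta == pytest.approx(np.pi / 2)

    def test_too_few_frames_flagged(self):
        rec = md.asymmetry_dynamics(_event(0, 0.1, 0.0, n=2))
        assert not rec.valid

    def test_fit_restricted_to_horizon(self):
        # slope changes sign after 60 min; fit must see only the early part
        t = np.arange(41) * 3.0
        dm = np.where(t <= 60, 0.001 * t, 0.06 - 0.002 * (t - 60))
        ev = _event(0, 0.0, 0.0)
        ev.times, ev.dm_signed = t, dm
        rec = md.asymmetry_dynamics(ev, horizon=60.0)
        assert rec.rate == pytest.approx(0.001, rel=1e-6)

    def test_parameter_recovery_on_programmed_events(self):
        # frame-quantized recovery of programmed dm0 and r for 200 events
        rng = np.random.default_rng(0)
        for eid in range(200):
            dm0 = float(rng.uniform(0.0, 0.5))
            rate = float(rng.uniform(-0.002, 0.002))
            rec = md.asymmetry_dynamics(_event(eid, dm0, rate))
            assert rec.dm0 == pytest.approx(dm0, abs=1e-9)
            assert rec.rate == pytest.approx(rate, abs=1e-9)

    def test_redistribution_sign_recovered_from_movie(self, seg_cfg):
        from conftest import analyze_movie, division_movie
        frames, _ = division_movie(41, adherent=False, t_furrow=24.0,
                                   n_frames=32, shape=(64, 64),
                                   redistribution_rate=0.002)
        _, _, events = analyze_movie(frames, seg_cfg, adherent=False)
        assert len(events) == 1
        rec = md.asymmetry_dynamics(events[0])
        assert rec.rate > 0


class TestOrdering:
    def test_descending_theta_with_stable_ties(self):
        recs = [AsymmetryRecord(0, 0.1, 0.0, theta=np.pi / 2),
                AsymmetryRecord(1, 0.1, 0.0, theta=0.0),
                AsymmetryRecord(2, 0.1, 0.0, theta=-np.pi / 4),
                AsymmetryRecord(3, 0.1, 0.0, theta=0.0)]
        assert md.order_events(recs) == [0, 1, 3, 2]

    def test_order_independent_of_input_shuffle(self):
        rng = np.random.default_rng(3)
        recs = [AsymmetryRecord(i, 0.1, 0.0, theta=float(th))
                for i, th in enumerate(rng.normal(0, 1, 30))]
        order1 = md.order_events(recs)
        perm = rng.permutation(30)
        shuffled = [recs[i] for i in perm]
        order2 = [shuffled[j].event_id for j in md.order_events(shuffled)]
        assert [recs[j].event_id for j in order1] == order2

    def test_four_scenario_classes_form_contiguous_blocks(self):
        # symmetric-increasing, symmetric-stable, asymmetric-stable,
        # asymmetric-decreasing: theta separates them into blocks
        rng = np.random.default_rng(7)
        groups = {
            "sym_inc": dict(dm0=0.02, rate=0.004),
            "sym_stable": dict(dm0=0.05, rate=0.0002),
            "asym_stable": dict(dm0=0.5, rate=0.0),
            "asym_dec": dict(dm0=0.5, rate=-0.004),
        }
        recs, labels = [], []
        eid = 0
        for name, g in groups.items():
            for _ in range(10):
                rec = md.asymmetry_dynamics(_event(
                    eid, g["dm0"] * float(rng.uniform(0.9, 1.1)),
                    g["rate"] * float(rng.uniform(0.9, 1.1))))
                recs.append(rec)
                labels.append(name)
                eid += 1
        order = md.order_events(recs)
        seq = [labels[i] for i in order]
        # each class occupies one contiguous block of the sorted heatmap
        changes = sum(a != b for a, b in zip(seq, seq[1:]))
        assert changes == len(groups) - 1

    def test_heatmap_matrix_rows_follow_ordering(self):
        recs = [md.asymmetry_dynamics(_event(i, dm0, 0.0))
                for i, dm0 in enumerate([0.0, 0.4])]
        mat = heatmap_matrix(recs, bin_width=3.0)
        assert list(mat.index) == [md.order_events(recs)[0],
                                   md.order_events(recs)[1]]


class TestPopulationCurves:
    def test_symmetric_events_zero_mean_dm(self):
        events = [_event(i, 0.0, 0.0) for i in range(5)]
        curve = md.mean_abs_dm_curve(events)
        assert np.allclose(curve.mean_abs_dm, 0.0)

    def test_cv_identical_masses_zero(self):
        assert md.coefficient_of_variation([10.0, 10.0, 10.0]) == 0.0

    def test_cv_hand_computed(self):
        # {9, 11}: sd = 1.414, mean = 10 -> CV = 14.1%
        assert md.coefficient_of_variation([9.0, 11.0]) == pytest.approx(
            0.1414, abs=1e-3)

    def test_cv_curve_bins_and_range(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(-90, 90, 4000)
        m = rng.lognormal(np.log(400.0), 0.1393, 4000)
        curve = md.mass_cv_curve(t, m)
        assert len(curve) == 18
        assert np.all((curve.cv > 0.10) & (curve.cv < 0.18))

    def test_mean_dm_sem_decreases_with_noise(self):
        noisy = [_event(i, dm0, 0.0) for i, dm0 in
                 enumerate(np.random.default_rng(1).normal(0, 0.1, 50))]
        curve = md.mean_abs_dm_curve(noisy)
        assert (curve["sem"] > 0).all()


class TestWelch:
    def test_identical_samples(self):
        t, p = md.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0]
        t, p = md.welch_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_swap_negates_t_keeps_p(self):
        a = [1.0, 2.0, 3.5, 4.0]
        b = [2.0, 5.0, 6.0, 8.0, 9.0]
        t1, p1 = md.welch_t_test(a, b)
        t2, p2 = md.welch_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            md.welch_t_test([1.0], [1.0, 2.0])

    @settings(deadline=None, max_examples=30)
    @given(st.data())
    def test_agrees_with_scipy_on_random_samples(self, data):
        a = data.draw(st.lists(st.floats(-50, 50), min_size=3, max_size=20))
        b = data.draw(st.lists(st.floats(-50, 50), min_size=3, max_size=20))
        if np.var(a) == 0 and np.var(b) == 0:
            return
        t, p = md.welch_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestRegressionF:
    def test_constant_response(self):
        slope, _, p = md.regression_f_test([1.0, 2, 3, 4], [5.0, 5, 5, 5])
        assert slope == pytest.approx(0.0)
        assert p == 1.0

    def test_exact_line_p_zero(self):
        x = np.arange(10.0)
        slope, _, p = md.regression_f_test(x, 2.0 * x)
        assert slope == pytest.approx(2.0)
        assert p == 0.0

    def test_f_equals_square_of_slope_t(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 50)
        y = 1.5 * x + rng.normal(0, 2, 50)
        slope, f, p = md.regression_f_test(x, y)
        res = sps.linregress(x, y)
        assert slope == pytest.approx(res.slope, abs=1e-10)
        assert f == pytest.approx((res.slope / res.stderr) ** 2, rel=1e-8)
        assert p == pytest.approx(res.pvalue, abs=1e-8)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            md.regression_f_test([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
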