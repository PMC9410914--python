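"""Generator correctness: dwell statistics, rendering, cohorts, presets."""

import numpy as np
import pytest
from scipy import stats

from ribokin.datamodel import (
    AcquisitionParams,
    KineticScheme,
    PhotophysicsParams,
    events_tile,
)
from ribokin.simulate import (
    MoleculeClassSpec,
    generate_bleach_control,
    generate_cohort,
    preset,
    preset_names,
    render_trace,
    sample_occupancy_mixture,
    simulate_events,
    simulate_titration,
)


def fast_cycling_scheme(k_off: float, a_off_slow: float = 0.0,
                        k_off_fast: float | None = None) -> KineticScheme:
    """Near-instant binding so bound dwells dominate the event list."""
    return KineticScheme(
        k_on_fast=5e7, k_on_slow=5e7, a_on_slow=0.0,
        k_off_fast=k_off_fast if k_off_fast is not None else k_off,
        k_off_slow=k_off, a_off_slow=a_off_slow,
    )


class TestSimulateEvents:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_events_tile_duration_exactly(self, wt_scheme, seed):
        events = simulate_events(wt_scheme, 1000.0, seed)
        assert events_tile(events, 1000.0)
        total = sum(e - s for _, s, e in events)
        assert total == pytest.approx(1000.0, abs=1e-9)

    def test_vanishing_on_rate_gives_single_unbound_event(self):
        scheme = KineticScheme(1e-30, 1e-30, 0.5, 0.5, 0.002, 0.5)
        events = simulate_events(scheme, 500.0, 0)
        assert events == [("unbound", 0.0, 500.0)]

    def test_vanishing_off_rate_bound_to_end(self):
        scheme = KineticScheme(5e7, 5e7, 0.0, 1e-12, 1e-12, 0.5)
        events = simulate_events(scheme, 500.0, 0)
        assert events[-1][0] == "bound"
        assert events[-1][2] == pytest.approx(500.0)

    def test_bound_dwell_mean_matches_exponential(self):
        # pure k_off = 0.1/s; ~10,000 bound dwells; SE = 10/sqrt(n)
        durations = []
        seed = 0
        while len(durations) < 10_000:
            events = simulate_events(fast_cycling_scheme(0.1), 12_000.0, seed)
            durations += [e - s for st, s, e in events[:-1] if st == "bound"]
            seed += 1
        durations = np.array(durations[:10_000])
        se = 10.0 / np.sqrt(durations.size)
        assert abs(durations.mean() - 10.0) < 3 * se

    def test_dwell_survival_matches_mixture_ks(self):
        # two-component bound mixture vs analytic survival at the 1% level
        scheme = fast_cycling_scheme(0.05, a_off_slow=0.4, k_off_fast=1.0)
        durations = []
        seed = 100
        while len(durations) < 10_000:
            events = simulate_events(scheme, 50_000.0, seed)
            durations += [e - s for st, s, e in events[:-1] if st == "bound"]
            seed += 1
        t = np.array(durations[:10_000])

        def cdf(x):
            return 1 - 0.6 * np.exp(-1.0 * x) - 0.4 * np.exp(-0.05 * x)

        d, _ = stats.kstest(t, cdf)
        assert d < 1.628 / np.sqrt(t.size)  # 1% critical value


class TestRenderTrace:
    def test_noiseless_rendering_is_exact_two_level(self, clean_photophysics):
        acquisition = AcquisitionParams(frame_time=0.1, n_frames=50)
        events = [("unbound", 0.0, 2.0), ("bound", 2.0, 4.0), ("unbound", 4.0, 5.0)]
        trace, _ = render_trace(events, acquisition, clean_photophysics, 0)
        lo, hi = clean_photophysics.intensity_unbound, clean_photophysics.intensity_bound
        np.testing.assert_allclose(trace.acceptor[:20], lo)
        np.testing.assert_allclose(trace.acceptor[20:40], hi)
        np.testing.assert_allclose(trace.acceptor[40:], lo)

    def test_straddling_frame_carries_duty_cycle_intensity(self, clean_photophysics):
        acquisition = AcquisitionParams(frame_time=0.1, n_frames=20)
        events = [("unbound", 0.0, 1.05), ("bound", 1.05, 2.0)]
        trace, _ = render_trace(events, acquisition, clean_photophysics, 0)
        lo, hi = clean_photophysics.intensity_unbound, clean_photophysics.intensity_bound
        assert trace.acceptor[10] == pytest.approx(lo + 0.5 * (hi - lo))

    def test_dual_label_loss_time_closed_form(self):
        # mean of the max of two Exp(k_b) is 3/(2 k_b)
        k_b = 0.001
        phot = PhotophysicsParams(k_bleach_acceptor=k_b, k_bleach_donor=0.0,
                                  noise_sd=0.0)
        acquisition = AcquisitionParams(frame_time=0.1, n_frames=20)
        losses = []
        for i in range(5000):
            _, truth = render_trace(
                [("bound", 0.0, 2.0)], acquisition, phot, i)
            losses.append(truth.acceptor_bleach_times[0])
        losses = np.array(losses)
        expected = 3.0 / (2.0 * k_b)
        se = np.sqrt(5.0) / (2.0 * k_b) / np.sqrt(losses.size)
        assert abs(losses.mean() - expected) < 3 * se

    def test_noise_sd_tracks_request(self, wt_scheme):
        acquisition = AcquisitionParams(frame_time=0.1, n_frames=5000)
        for target in (20.0, 50.0):
            phot = PhotophysicsParams(k_bleach_acceptor=0.0, k_bleach_donor=0.0,
                                      noise_sd=target)
            trace, _ = render_trace(
                [("unbound", 0.0, 500.0)], acquisition, phot, 7)
            resid_sd = np.std(trace.acceptor - phot.intensity_unbound)
            assert abs(resid_sd - target) / target < 0.05

    def test_default_frame_time_is_100_ms(self):
        assert AcquisitionParams().frame_time == 0.1
        assert preset("wt_minus").acquisition.frame_time == 0.1


class TestGenerateCohort:
    def test_single_class_shares_scheme(self, wt_scheme, clean_photophysics):
        acquisition = AcquisitionParams(frame_time=0.1, n_frames=100)
        cohort = generate_cohort(
            [MoleculeClassSpec(1.0, wt_scheme, "only")], 5, acquisition,
            clean_photophysics, seed=0)
        assert len(cohort.traces) == 5
        assert all(gt.class_label == "only" for gt in cohort.ground_truths.values())

    def test_class_counts_follow_binomial(self, wt_scheme, clean_photophysics):
        # short movies keep 10,000-molecule sampling cheap
        acquisition = AcquisitionParams(frame_time=0.1, n_frames=2)
        weights = (0.81, 0.13, 0.06)
        classes = [MoleculeClassSpec(w, wt_scheme, f"c{i}")
                   for i, w in enumerate(weights)]
        cohort = generate_cohort(classes, 10_000, acquisition,
                                 clean_photophysics, seed=1)
        labels = [gt.class_label for gt in cohort.ground_truths.values()]
        for i, w in enumerate(weights):
            count = labels.count(f"c{i}")
            sd = np.sqrt(10_000 * w * (1 - w))
            assert abs(count - 10_000 * w) < 3 * sd

    def test_seed_determinism(self, wt_scheme, clean_photophysics):
        acquisition = AcquisitionParams(frame_time=0.1, n_frames=200)
        classes = [MoleculeClassSpec(1.0, wt_scheme)]
        a = generate_cohort(classes, 3, acquisition, clean_photophysics, seed=5)
        b = generate_cohort(classes, 3, acquisition, clean_photophysics, seed=5)
        c = generate_cohort(classes, 3, acquisition, clean_photophysics, seed=6)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)
        assert not np.array_equal(a.traces[0].acceptor, c.traces[0].acceptor)

    def test_empty_class_list_rejected(self, clean_photophysics):
        with pytest.raises(ValueError):
            generate_cohort([], 3, AcquisitionParams(), clean_photophysics)

    def test_bleach_control_is_locked_on(self):
        phot = PhotophysicsParams()
        control = generate_bleach_control(3, phot, seed=0)
        for gt in control.ground_truths.values():
            assert [e[0] for e in gt.events] == ["bound"]
        assert control.photophysics.k_bleach_donor == 0.0


class TestPresets:
    def test_wild_type_slow_rates_are_published_values(self):
        assert preset("wt_minus").scheme.k_on_slow == pytest.approx(0.33e6)
        assert preset("wt_minus").scheme.k_off_slow == pytest.approx(0.002)
        assert preset("wt_plus").scheme.k_off_slow == pytest.approx(0.006)
        assert preset("wt_plus").scheme.k_on_slow == pytest.approx(0.24e6)
        assert preset("ds1").scheme.k_off_slow == pytest.approx(0.01)

    def test_mutant_presets_use_150_ms_frames(self):
        assert preset("i1s8").acquisition.frame_time == pytest.approx(0.15)
        assert preset("i1s8").scheme.k_on_slow == pytest.approx(0.25e6)
        assert preset("i4s0").scheme.k_on_slow == pytest.approx(0.26e6)

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="wt_minus"):
            preset("nope")
        assert "wt_plus" in preset_names()


class TestAuxiliarySamplers:
    def test_titration_noise_free_matches_hill_closed_form(self):
        d = simulate_titration([0.0, 48e-9], 0.33e6, 0.24e6, 0.002, 0.006,
                               K_half=48e-9, noise_frac=0.0, seed=0)
        assert d["kon"][0] == pytest.approx(0.33e6)
        assert d["koff"][0] == pytest.approx(0.002)
        # at c = K each series sits at its midpoint
        assert d["kon"][1] == pytest.approx((0.33e6 + 0.24e6) / 2)
        assert d["koff"][1] == pytest.approx(0.004)

    def test_occupancy_mixture_clips_and_weights(self):
        f, comp = sample_occupancy_mixture(
            [0.81, 0.13, 0.06], [0.05, 0.15, 0.30], [0.02] * 3, 5000, seed=0)
        assert f.min() >= 0.0 and f.max() <= 1.0
        assert abs((comp == 0).mean() - 0.81) < 3 * np.sqrt(0.81 * 0.19 / 5000)
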