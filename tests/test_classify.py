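"""Event and molecule classification, rastergrams, conditional dwells, jumps."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ribokin.classify import (
    OccupancyMixture,
    build_rastergram,
    classify_events,
    classify_molecules,
    conditional_unbound_dwells,
    event_threshold,
    fit_occupancy_gaussians,
    fractional_bound_time,
    pair_jump_segments,
)
from ribokin.datamodel import (
    ClassThresholds,
    Dwell,
    DwellSet,
    ExpMixtureFit,
    Idealization,
    OccupancyProfile,
)
from ribokin.simulate import sample_occupancy_mixture


def _fit(k_f, k_s, a_f):
    return ExpMixtureFit(2, [k_f, k_s], [a_f, 1 - a_f], 0.0, 0.0)


def _numeric_threshold(k_f, k_s, a_f):
    a_s = 1 - a_f

    def diff(t):
        return a_f * k_f * np.exp(-k_f * t) - a_s * k_s * np.exp(-k_s * t)

    return brentq(diff, 1e-9, 10.0 / k_s, xtol=1e-12)


class TestEventThreshold:
    @pytest.mark.parametrize(
        "k_f,k_s,a_f",
        [(0.5, 0.002, 0.42), (1.0, 0.05, 0.6), (0.2, 0.01, 0.9), (5.0, 0.5, 0.3)],
    )
    def test_matches_numeric_density_equality_root(self, k_f, k_s, a_f):
        assert event_threshold(_fit(k_f, k_s, a_f)) == pytest.approx(
            _numeric_threshold(k_f, k_s, a_f), abs=1e-6
        )

    def test_published_dissociation_mixture_threshold(self):
        # k_off,fast 0.5 / k_off,slow 0.002 with amplitudes 0.42/0.58
        t_star = event_threshold(_fit(0.5, 0.002, 0.42))
        assert 10.0 < t_star < 11.0

    def test_vanishing_fast_amplitude_limit_gives_zero(self):
        assert event_threshold(_fit(0.5, 0.002, 1e-12)) == 0.0

    def test_equal_rates_rejected(self):
        fit = ExpMixtureFit(2, [0.5, 0.5], [0.4, 0.6], 0.0, 0.0)
        with pytest.raises(ValueError, match="separation"):
            event_threshold(fit)

    def test_rule_achieves_bayes_error(self):
        # threshold classification error on labelled draws equals the
        # analytic Bayes error of the mixture within 1%
        k_f, k_s, a_f = 0.5, 0.02, 0.6
        t_star = event_threshold(_fit(k_f, k_s, a_f))
        rng = np.random.default_rng(0)
        n = 100_000
        is_fast = rng.random(n) < a_f
        t = np.where(is_fast, rng.exponential(1 / k_f, n),
                     rng.exponential(1 / k_s, n))
        predicted_slow = t > t_star
        err = np.mean(predicted_slow == is_fast)
        bayes = a_f * np.exp(-k_f * t_star) + (1 - a_f) * (1 - np.exp(-k_s * t_star))
        assert abs(err - bayes) < 0.01


class TestClassifyEvents:
    def _dwells(self, specs):
        return DwellSet(
            [
                Dwell("bound", d, False, c, f"m{i}")
                for i, (d, c) in enumerate(specs)
            ],
            0.1,
        )

    def test_short_and_long_labels(self):
        labels, counts = classify_events(
            self._dwells([(1.0, False), (20.0, False)]), 10.0
        )
        assert labels == ["short", "long"]
        assert counts == {"short": 1, "long": 1, "indeterminate": 0}

    def test_censored_below_threshold_is_indeterminate(self):
        labels, counts = classify_events(
            self._dwells([(5.0, True), (20.0, True)]), 10.0
        )
        assert labels == ["indeterminate", "long"]

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(1)
        specs = [(float(t), bool(c)) for t, c in
                 zip(rng.exponential(10, 200), rng.random(200) < 0.3)]
        _, counts = classify_events(self._dwells(specs), 8.0)
        assert sum(counts.values()) == 200

    def test_empty_set_zero_counts(self):
        _, counts = classify_events(DwellSet([], 0.1), 10.0)
        assert counts == {"short": 0, "long": 0, "indeterminate": 0}


class TestFractionalBoundTime:
    def test_extremes_and_arithmetic(self):
        assert fractional_bound_time(
            Idealization("m", np.ones(100, dtype=np.int8), 100)) == 1.0
        assert fractional_bound_time(
            Idealization("m", np.zeros(100, dtype=np.int8), 100)) == 0.0
        states = np.zeros(1000, dtype=np.int8)
        states[:250] = 1
        assert fractional_bound_time(Idealization("m", states, 1000)) == 0.25

    def test_zero_analyzable_frames_rejected(self):
        with pytest.raises(ValueError, match="analyzable"):
            fractional_bound_time(Idealization("m", np.ones(5, dtype=np.int8), 0))


class TestRastergram:
    def _ideal(self, mol, bound_frames, n=100):
        states = np.zeros(n, dtype=np.int8)
        for i0, i1 in bound_frames:
            states[i0:i1] = 1
        return Idealization(mol, states, n)

    def test_single_molecule_row_matches_dwells(self):
        raster = build_rastergram([self._ideal("m0", [(10, 20)])], 0.1)
        assert len(raster) == 1
        row = raster.iloc[0]
        assert row["start_s"] == pytest.approx(1.0)
        assert row["end_s"] == pytest.approx(2.0)

    def test_rows_sorted_by_descending_occupancy(self):
        ideals = [
            self._ideal("a", [(0, 10)]),
            self._ideal("b", [(0, 60)]),
            self._ideal("c", [(0, 30)]),
        ]
        raster = build_rastergram(ideals, 0.1)
        by_row = raster.groupby("row")["molecule"].first()
        assert list(by_row) == ["b", "c", "a"]

    def test_subsample_reproducible_under_seed(self):
        ideals = [self._ideal(f"m{i}", [(0, i + 1)]) for i in range(30)]
        a = build_rastergram(ideals, 0.1, max_rows=10, seed=3)
        b = build_rastergram(ideals, 0.1, max_rows=10, seed=3)
        assert a.equals(b)
        assert a["molecule"].nunique() == 10

    def test_labels_split_by_threshold(self):
        raster = build_rastergram(
            [self._ideal("m0", [(0, 5), (50, 90)])], 0.1, t_star=2.0)
        assert set(raster["label"]) == {"short", "long"}


class TestOccupancyMixture:
    def test_well_separated_crossovers_bracketed_by_means(self):
        f, _ = sample_occupancy_mixture(
            [0.3, 0.44, 0.26], [0.05, 0.15, 0.30], [0.02] * 3, 1000, seed=0)
        om = fit_occupancy_gaussians(f)
        t1, t2 = om.thresholds_.low_high_boundaries
        assert om.thresholds_.source == "gaussian_crossover"
        assert 0.05 < t1 < 0.15
        assert 0.15 < t2 < 0.30

    def test_crossovers_near_working_boundaries(self):
        # the working L/M/H boundaries 0.10 and 0.20 emerge from the fit
        f, _ = sample_occupancy_mixture(
            [0.3, 0.44, 0.26], [0.05, 0.15, 0.30], [0.02] * 3, 1000, seed=1)
        t1, t2 = fit_occupancy_gaussians(f).thresholds_.low_high_boundaries
        assert t1 == pytest.approx(0.10, abs=0.03)
        assert t2 == pytest.approx(0.20, abs=0.05)

    def test_single_tight_cluster_falls_back(self):
        rng = np.random.default_rng(2)
        f = rng.normal(0.15, 0.005, 200).clip(0, 1)
        with pytest.warns(UserWarning):
            om = OccupancyMixture().fit(f)
        assert om.thresholds_.source == "fixed"
        assert om.thresholds_.low_high_boundaries == (0.10, 0.20)

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError, match="50"):
            OccupancyMixture().fit(np.linspace(0, 1, 30))

    def test_crossover_and_fixed_thresholds_agree_on_most_molecules(self):
        f, _ = sample_occupancy_mixture(
            [0.3, 0.44, 0.26], [0.05, 0.15, 0.30], [0.02] * 3, 1000, seed=3)
        om = fit_occupancy_gaussians(f)
        from_crossover = om.predict(f)
        fixed = np.where(f < 0.10, "L", np.where(f > 0.20, "H", "M"))
        assert np.mean(from_crossover == fixed) >= 0.95


class TestClassifyMolecules:
    def test_boundary_assignments(self):
        profiles, _ = classify_molecules([0.05, 0.15, 0.30, 0.10, 0.20])
        assert [p.occupancy_class for p in profiles] == ["L", "M", "H", "M", "M"]

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        _, summary = classify_molecules(rng.random(500))
        total = sum(summary[c]["fraction"] for c in "LMH")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_three_class_cohort_recovered_within_binomial_error(self):
        f, _ = sample_occupancy_mixture(
            [0.81, 0.13, 0.06], [0.05, 0.15, 0.30], [0.02] * 3, 300, seed=5)
        _, summary = classify_molecules(f)
        sd = np.sqrt(0.81 * 0.19 / 300)
        assert abs(summary["L"]["fraction"] - 0.81) < 3 * sd


class TestConditionalUnboundDwells:
    def _interleaved(self, pairs):
        """pairs: list of (unbound_duration, following_label, bound_duration)."""
        dwells, labels = [], []
        for i, (u, label, b) in enumerate(pairs):
            dwells.append(Dwell("unbound", u, False, False, "m0"))
            dwells.append(Dwell("bound", b, False, False, "m0"))
            labels.append(label)
        return DwellSet(dwells, 0.1), labels

    def test_constructed_ratio_of_ten(self):
        pairs = [(5.0, "short", 1.0), (50.0, "long", 20.0)] * 20
        ds, labels = self._interleaved(pairs)
        out = conditional_unbound_dwells(ds, labels, n_boot=200, seed=0)
        assert out["ratio_of_means"] == pytest.approx(10.0)

    def test_null_generator_ci_includes_one(self):
        rng = np.random.default_rng(6)
        pairs = [
            (float(rng.exponential(10.0)),
             "long" if rng.random() < 0.5 else "short",
             float(rng.exponential(5.0)))
            for _ in range(400)
        ]
        ds, labels = self._interleaved(pairs)
        out = conditional_unbound_dwells(ds, labels, n_boot=500, seed=1)
        lo, hi = out["ratio_ci95"]
        assert lo < 1.0 < hi

    def test_assignable_dwells_partitioned(self):
        pairs = [(2.0, "short", 1.0), (3.0, "long", 20.0), (4.0, "short", 0.5)]
        ds, labels = self._interleaved(pairs)
        out = conditional_unbound_dwells(ds, labels)
        assert len(out["short"]) + len(out["long"]) == 3


class TestPairJumpSegments:
    def _profile(self, mol, cls, n_events=5):
        fraction = {"L": 0.05, "M": 0.15, "H": 0.30}[cls]
        return OccupancyProfile(mol, fraction, cls, n_events_short=n_events)

    def test_identical_segments_all_same(self):
        before = [self._profile(f"m{i}", "M") for i in range(10)]
        records, summary = pair_jump_segments(before, before)
        assert summary["same"] == 1.0
        assert all(r.response == "same" for r in records)

    def test_constructed_drop_fraction(self):
        before = [self._profile(f"m{i}", "H") for i in range(100)]
        after = [self._profile(f"m{i}", "L" if i < 48 else "H")
                 for i in range(100)]
        _, summary = pair_jump_segments(before, after)
        assert summary["decreased"] == pytest.approx(0.48)

    def test_zero_after_events_is_inaccessible_and_decreased(self):
        before = [self._profile("m0", "L")]
        after = [OccupancyProfile("m0", 0.0, "L", 0, 0)]
        records, summary = pair_jump_segments(before, after)
        assert records[0].class_after == "inaccessible"
        assert records[0].response == "decreased"
        assert summary["inaccessible_after"] == 1.0

    def test_unmatched_ids_excluded(self):
        before = [self._profile("m0", "M"), self._profile("m1", "M")]
        after = [self._profile("m0", "M")]
        records, summary = pair_jump_segments(before, after)
        assert len(records) == 1 and summary["n_molecules"] == 1
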