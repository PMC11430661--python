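"""Binned validation, segmented descriptive fit, trajectory reports."""

import numpy as np
import pytest

from flipnorms.cohort import ChildTrajectory
from flipnorms.comparison import (
    FlagRules,
    binned_sample_percentiles,
    compare_bins_to_curves,
    segmented_linear_fit,
    trajectory_report,
)
from flipnorms.growth import logistic_eval
from flipnorms.io import read_trajectory
from flipnorms.quantile import CohortRecord


def recs(pairs):
    return [CohortRecord(f"c{i}", a, s) for i, (a, s) in enumerate(pairs)]


class TestBinnedPercentiles:
    def test_constant_sample_every_percentile_equal(self):
        bins = binned_sample_percentiles(
            recs([(4.0, 10.0)] * 8), taus=[0.16, 0.5, 0.84])
        assert bins[0].percentiles == {0.16: 10.0, 0.5: 10.0, 0.84: 10.0}

    def test_odd_length_median(self):
        bins = binned_sample_percentiles(
            recs([(10.0 + 0.1 * i, float(s)) for i, s in enumerate(range(1, 10))]),
            taus=[0.5])
        assert bins[1].percentiles[0.5] == 5.0

    def test_partition_covers_each_record_once(self, rng):
        records = recs([(float(a), float(s)) for a, s in
                        zip(rng.uniform(0.01, 72, 500), rng.uniform(0, 64, 500))])
        bins = binned_sample_percentiles(records, taus=[0.5], min_count=1)
        assert len(bins) == 12
        assert sum(b.count for b in bins) == 500

    def test_undersized_bin_carries_no_values(self):
        bins = binned_sample_percentiles(recs([(4.0, 10.0)] * 3), taus=[0.5],
                                         min_count=5)
        assert bins[0].count == 3
        assert bins[0].percentiles == {}

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            binned_sample_percentiles([], taus=[0.5], bin_width=5.0)


class TestCompareBinsToCurves:
    def test_self_comparison_is_zero(self, reference_table):
        pairs = []
        for mid in np.arange(3.0, 72.0, 6.0):
            val = float(logistic_eval(reference_table.entries[0.5], mid))
            pairs += [(float(mid), min(val, 64.0))] * 6
        bins = binned_sample_percentiles(recs(pairs), taus=[0.5])
        report = compare_bins_to_curves(bins, reference_table)
        assert report["max_abs"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_bins_give_empty_report(self, reference_table):
        assert compare_bins_to_curves([], reference_table) == \
            {"per_tau": {}, "max_abs": 0.0}

    def test_antisymmetry_under_sample_fitted_swap(self, reference_table):
        pairs = [(float(a), 30.0) for a in np.linspace(20, 40, 30)]
        bins = binned_sample_percentiles(recs(pairs), taus=[0.5])
        report = compare_bins_to_curves(bins, reference_table)
        for tau, entry in report["per_tau"].items():
            for mid, diff in entry["diffs"]:
                fitted = float(logistic_eval(reference_table.entries[tau], mid))
                sample = diff + fitted
                assert (fitted - sample) == pytest.approx(-diff)

    def test_mega_cohort_binned_medians_track_curve(self, mega_cohort, reference_table):
        bins = binned_sample_percentiles(mega_cohort, taus=[0.5])
        report = compare_bins_to_curves(bins, reference_table)
        assert report["per_tau"][0.5]["max_abs"] < 1.0


class TestSegmentedFit:
    def test_collinear_segments_fit_exactly(self):
        pairs = [(a, min(2.0 * a, 64.0)) for a in
                 [5.0, 10, 20, 28, 35, 40, 50, 53, 58, 60, 65, 70]]
        fits = segmented_linear_fit(recs(pairs))
        assert len(fits) == 3
        assert fits[0].slope == pytest.approx(2.0)
        assert fits[0].r2 == pytest.approx(1.0)

    def test_early_slope_exceeds_late_slope(self, mega_cohort):
        fits = segmented_linear_fit(mega_cohort)
        assert fits[0].slope > fits[2].slope

    def test_empty_segment_named_in_error(self):
        pairs = [(a, 10.0) for a in [35.0, 40.0, 45.0, 50.0]]
        with pytest.raises(ValueError, match=r"\(0, 30\]"):
            segmented_linear_fit(recs(pairs))


class TestTrajectoryReport:
    def on_median(self, reference_table, ages):
        pts = [(a, float(np.clip(logistic_eval(reference_table.entries[0.5], a), 0, 64)))
               for a in ages]
        return ChildTrajectory(child_id="med", points=pts)

    def test_median_trajectory_unflagged(self, reference_table):
        traj = self.on_median(reference_table, [6, 12, 18, 24, 36, 48])
        rep = trajectory_report(traj, reference_table)
        assert all(p.band == "16th-84th" for p in rep.points)
        assert not rep.divergence and not rep.plateau and not rep.converging

    def test_single_point_gets_band_but_no_flags(self, reference_table):
        traj = ChildTrajectory(child_id="one", points=[(24.0, 43.0)])
        rep = trajectory_report(traj, reference_table)
        assert rep.points[0].band == "16th-84th"
        assert not (rep.divergence or rep.plateau or rep.converging)

    def test_packaged_child_b_pattern(self, reference_table):
        """The demonstration fixture shows the clinical pattern: within the
        envelope early, diverging and plateauing mid-trajectory, converging
        after intervention."""
        from importlib import resources
        with resources.as_file(
                resources.files("flipnorms.data").joinpath("child_b_synthetic.csv")) as p:
            traj = read_trajectory(p)
        rep = trajectory_report(traj, reference_table)
        assert rep.divergence
        assert rep.plateau
        assert rep.converging
        assert rep.plateau_intervals
        lo, hi = rep.plateau_intervals[0]
        assert 12 <= lo <= 20 and 24 <= hi <= 45

    def test_packaged_child_a_tracks_median_after_activation(self, reference_table):
        from importlib import resources
        with resources.as_file(
                resources.files("flipnorms.data").joinpath("child_a_synthetic.csv")) as p:
            traj = read_trajectory(p)
        rep = trajectory_report(traj, reference_table)
        late = [p for p in rep.points if p.age >= 12]
        assert all(p.band == "16th-84th" for p in late)

    def test_flags_invariant_to_annotations_and_id(self, reference_table):
        pts = [(6.0, 5.0), (12.0, 6.0), (24.0, 6.5), (36.0, 7.0)]
        t1 = ChildTrajectory(child_id="a", points=pts)
        t2 = ChildTrajectory(child_id="b", points=pts,
                             annotations=[(12.0, "event")])
        r1 = trajectory_report(t1, reference_table)
        r2 = trajectory_report(t2, reference_table)
        assert (r1.divergence, r1.plateau, r1.converging) == \
            (r2.divergence, r2.plateau, r2.converging)
        assert r1.divergence and r1.plateau

    def test_plateau_requires_span_and_median_growth(self, reference_table):
        # flat over only 4 months: below the default 6-month span, no flag
        pts = [(12.0, 20.0), (16.0, 20.5)]
        rep = trajectory_report(ChildTrajectory(child_id="s", points=pts),
                                reference_table)
        assert not rep.plateau
        rules = FlagRules(plateau_span=3.0)
        rep2 = trajectory_report(ChildTrajectory(child_id="s", points=pts),
                                 reference_table, rules=rules)
        assert rep2.plateau
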