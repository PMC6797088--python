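import numpy as np
import pytest

from strandscan import (
    SurveyPoint,
    SurveyPointSet,
    count_comparison,
    detection_report,
    nearest_match,
    report_row_from_counts,
    round_half_up,
    within_distance_summary,
)
from strandscan.detector import CandidatePixel
from strandscan.evaluate import NearMatch
from strandscan.raster import GeoTransform
from strandscan.scenegen import TruthObject, TruthSet


def points(coords, source="truth"):
    return SurveyPointSet([
        SurveyPoint(id=str(i), easting=x, northing=y, source=source)
        for i, (x, y) in enumerate(coords)
    ])


class TestNearestMatch:
    def test_coincident_points_distance_zero(self):
        m = nearest_match(points([(5.0, 5.0)]), points([(5.0, 5.0)]))
        assert m[0].distance_m == 0.0

    def test_three_four_five(self):
        m = nearest_match(points([(0.0, 0.0)]), points([(3.0, 4.0)]))
        assert m[0].distance_m == pytest.approx(5.0)

    def test_random_matches_exhaustive_all_pairs(self):
        rng = np.random.default_rng(11)
        a = points(rng.uniform(0, 1000, (50, 2)))
        b = points(rng.uniform(0, 1000, (30, 2)))
        got = nearest_match(a, b)
        bc = b.coords()
        for pa, m in zip(a.points, got):
            dists = np.hypot(bc[:, 0] - pa.easting, bc[:, 1] - pa.northing)
            assert m.distance_m == pytest.approx(dists.min())
            assert m.b_id == b.points[int(np.argmin(dists))].id

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            nearest_match(points([(0, 0)]), points([]))


class TestWithinDistanceSummary:
    def test_published_within_100m_share(self):
        # 19 of 24 detections within 100 m reports as 79%
        dists = [50.0] * 19 + [150.0] * 5
        matches = [NearMatch("a", "b", d) for d in dists]
        out = within_distance_summary(matches, [100.0, 200.0])
        assert out[0]["count"] == 19 and out[0]["percent"] == 79
        assert out[1]["percent"] == 100

    def test_all_zero_distances(self):
        matches = [NearMatch("a", "b", 0.0)] * 4
        out = within_distance_summary(matches, [1.0, 10.0])
        assert all(o["percent"] == 100 for o in out)

    def test_random_matches_counting_oracle(self):
        rng = np.random.default_rng(2)
        dists = rng.uniform(0, 500, 40)
        matches = [NearMatch(str(i), "x", d) for i, d in enumerate(dists)]
        radii = [50.0, 100.0, 250.0, 500.0]
        out = within_distance_summary(matches, radii)
        for r, o in zip(radii, out):
            k = sum(1 for d in dists if d <= r)
            assert o["count"] == k
            assert o["percent"] == int(round_half_up(100 * k / 40))
        counts = [o["count"] for o in out]
        assert counts == sorted(counts)

    def test_validation(self):
        with pytest.raises(ValueError):
            within_distance_summary([], [10.0])
        with pytest.raises(ValueError):
            within_distance_summary([NearMatch("a", "b", 1.0)], [10.0, 5.0])


def make_truth(whale_footprints, shape=(20, 20)):
    t = GeoTransform(0.0, 0.0, 2.0)
    objs = [
        TruthObject(id=i, label="whale", easting=0.0, northing=0.0,
                    footprint=fp, length_m=10.0, orientation_deg=0.0)
        for i, fp in enumerate(whale_footprints)
    ]
    return TruthSet(objs, t, shape)


def make_candidates(coords_liks):
    return [
        CandidatePixel(row=r, col=c, easting=2 * c + 1, northing=-2 * r - 1,
                       label="w", angle_rad=0.01, likelihood=lik)
        for r, c, lik in coords_liks
    ]


class TestDetectionReport:
    def test_worked_pixel_percentages(self):
        row = report_row_from_counts(0.0, total_pixels=39, whale_pixels=26,
                                     whales_identified=14, n_whales=21)
        assert row.pct_whale_pixels == 66.7
        assert row.pct_commission == 33.3
        assert row.commission_pixels == 13

    def test_worked_whale_percentages(self):
        row = report_row_from_counts(0.0, 0, 0, whales_identified=14, n_whales=21)
        assert row.pct_whales_identified == 66.7
        assert row.omission_whales == 7
        assert row.pct_omission == 33.3

    def test_zero_candidates_full_omission(self):
        truth = make_truth([[(5, 5), (5, 6)]])
        rep = detection_report([], truth, [0.0])
        row = rep.rows[0]
        assert row.total_pixels == 0 and row.commission_pixels == 0
        assert row.pct_omission == 100.0

    def test_association_and_once_per_whale(self):
        truth = make_truth([[(5, 5), (5, 6)], [(15, 15)]])
        # two separate pixel groups hit whale 0; one pixel is 1 px off the
        # footprint (jitter tolerance); one commission far away
        cands = make_candidates([(5, 5, 90), (5, 7, 80), (10, 0, 70), (4, 5, 60)])
        rep = detection_report(cands, truth, [0.0, 75.0])
        all_row = rep.row(0.0)
        assert all_row.total_pixels == 4
        assert all_row.whale_pixels == 3
        assert all_row.commission_pixels == 1
        assert all_row.whales_identified == 1  # whale 0 counted once
        assert all_row.omission_whales == 1
        hi = rep.row(75.0)
        assert hi.total_pixels == 2 and hi.whales_identified == 1

    def test_conservation_and_monotonicity(self):
        rng = np.random.default_rng(4)
        truth = make_truth([[(2, 2)], [(10, 10), (10, 11)]])
        cands = make_candidates([
            (int(r), int(c), float(lik))
            for r, c, lik in zip(rng.integers(0, 20, 30),
                                 rng.integers(0, 20, 30),
                                 rng.uniform(0, 100, 30))
        ])
        rep = detection_report(cands, truth, [0.0, 40.0, 65.0])
        prev = None
        for row in rep.rows:
            assert row.whale_pixels + row.commission_pixels == row.total_pixels
            assert row.whales_identified + row.omission_whales == row.n_whales
            if prev is not None:
                assert row.commission_pixels <= prev.commission_pixels
                assert row.omission_whales >= prev.omission_whales
                assert row.total_pixels <= prev.total_pixels
            prev = row

    def test_no_truth_whales_rejected(self):
        truth = make_truth([])
        with pytest.raises(ValueError):
            detection_report([], truth, [0.0])


class TestCountComparison:
    def test_published_excess(self):
        out = count_comparison(23, ground_count=14)
        assert out.excess == 9 and out.excess_pct == 64

    def test_equal_counts(self):
        out = count_comparison(20, ground_count=20)
        assert out.excess == 0 and out.excess_pct == 0

    def test_per_class_sum_discrepancy_surfaced(self):
        # 22 objects reported but the printed classes sum to 21
        out = count_comparison({1: 11, 2: 2, 3: 8}, ground_count=30,
                               satellite_count=22)
        assert out.excess == -8
        assert out.discrepancy is not None
        consistent = count_comparison({1: 14, 2: 3, 3: 6}, ground_count=14,
                                      satellite_count=23)
        assert consistent.discrepancy is None

    def test_zero_ground_flagged(self):
        out = count_comparison(5, ground_count=0)
        assert out.excess_pct is None


def test_round_half_up_reporting_convention():
    assert round_half_up(2.25, 1) == 2.3  # exact binary tie
    assert round_half_up(0.5) == 1
    assert round_half_up(-0.5) == -1
    assert round_half_up(66.66666, 1) == 66.7
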