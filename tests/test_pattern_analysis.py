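"""Spot segmentation and pattern metrics, exercised on idealized synthetic
disc fields with known geometry and checked against brute-force oracles."""

import math

import numpy as np
import pytest

from denticle_rd.grid_solver import GridSpec
from denticle_rd.initiators import (SpotConfig, catshark_config, gap_config,
                                    synthetic_spot_field)
from denticle_rd.kinetics import catshark_params
from denticle_rd.pattern_analysis import (DensityOrderingError,
                                          compare_initiator_emergent,
                                          density_suite, gap_infill_metrics,
                                          nearest_neighbor_stats,
                                          replicate_proportion, segment_spots)

G = GridSpec.for_params(catshark_params())


def _rasterized_area(center, radius):
    """Brute-force oracle for the domain-unit area of one rasterized disc."""
    f = synthetic_spot_field([center], radius, 1.0, G)
    return float((f > 0).sum()) * G.dx ** 2


class TestSegmentation:
    def test_constant_field_yields_no_spots_with_warning(self):
        with pytest.warns(UserWarning, match="constant field"):
            assert segment_spots(np.zeros((G.n, G.n)), G) == []

    def test_two_disjoint_discs_detected(self):
        f = synthetic_spot_field([(20.0, 20.0), (55.0, 55.0)], 4.0, 2.0, G)
        spots = segment_spots(f, G)
        assert len(spots) == 2
        found = sorted((s.x, s.y) for s in spots)
        for (fx, fy), (cx, cy) in zip(found, [(20.0, 20.0), (55.0, 55.0)]):
            assert math.hypot(fx - cx, fy - cy) < G.dx

    def test_detected_area_matches_rasterized_disc_oracle(self):
        f = synthetic_spot_field([(37.5, 37.5)], 6.0, 1.0, G)
        (spot,) = segment_spots(f, G)
        assert spot.area_units == pytest.approx(_rasterized_area((37.5, 37.5), 6.0))
        assert spot.area_cells == spot.area_units / G.dx ** 2

    def test_min_area_suppresses_speckle(self):
        f = np.zeros((G.n, G.n))
        f[10, 10] = 1.0                       # single-cell speckle
        f[40:46, 40:46] = 1.0                 # genuine 36-cell blob
        spots = segment_spots(f, G)
        assert len(spots) == 1
        assert spots[0].area_cells == 36

    def test_initiator_flagging_by_footprint(self):
        cfg = SpotConfig(n_spot=1, R_spot=4.0, centers=((20.0, 20.0),))
        f = synthetic_spot_field([(20.0, 20.0), (55.0, 55.0)], 4.0, 2.0, G)
        spots = segment_spots(f, G, cfg=cfg)
        flags = {(round(s.x), round(s.y)): s.is_initiator for s in spots}
        assert flags[(20, 20)] is True
        assert flags[(55, 55)] is False

    def test_threshold_monotone_total_area(self):
        """Raising the threshold fraction never increases total segmented
        area."""
        rng = np.random.default_rng(3)
        f = rng.uniform(0, 1, (G.n, G.n))
        f += synthetic_spot_field([(20, 20), (50, 50)], 8.0, 3.0, G)
        areas = []
        for tf in (0.2, 0.35, 0.5, 0.65, 0.8):
            spots = segment_spots(f, G, threshold_fraction=tf, min_area=1)
            areas.append(sum(s.area_cells for s in spots))
        assert areas == sorted(areas, reverse=True)

    def test_label_count_matches_brute_force_flood_fill(self):
        """8-connected component count agrees with an independent BFS flood
        fill on random small binary fields."""
        rng = np.random.default_rng(11)
        g = GridSpec(L=16, n=16, dt=0.01, T=1)
        for _ in range(20):
            f = (rng.uniform(size=(16, 16)) < 0.35).astype(float)
            f[0, 0] = 0.0
            f[8, 8] = 1.0   # guarantee both values are present
            seen = np.zeros_like(f, dtype=bool)
            n_components = 0
            for r in range(16):
                for c in range(16):
                    if f[r, c] == 1.0 and not seen[r, c]:
                        n_components += 1
                        stack = [(r, c)]
                        seen[r, c] = True
                        while stack:
                            rr, cc = stack.pop()
                            for dr in (-1, 0, 1):
                                for dc in (-1, 0, 1):
                                    r2, c2 = rr + dr, cc + dc
                                    if (0 <= r2 < 16 and 0 <= c2 < 16
                                            and f[r2, c2] == 1.0
                                            and not seen[r2, c2]):
                                        seen[r2, c2] = True
                                        stack.append((r2, c2))
            spots = segment_spots(f, g, min_area=1)
            assert len(spots) == n_components

    def test_segmentation_invariant_to_field_rescaling(self):
        f = synthetic_spot_field([(20, 20), (50, 50)], 5.0, 1.0, G)
        a = segment_spots(f, G)
        b = segment_spots(2.0 * f, G)
        assert [(s.label, s.area_cells) for s in a] == \
               [(s.label, s.area_cells) for s in b]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            segment_spots(np.ones((8, 8)), G, threshold_fraction=1.0)


class TestInitiatorEmergentComparison:
    def test_big_initiator_disc_vs_small_emergent_discs(self):
        """One radius-6 disc at an initiator center plus five radius-3 discs
        elsewhere: the mean-area ratio follows the r^2 scaling (~4), with the
        exact value fixed by the rasterized-disc oracle."""
        cfg = SpotConfig(n_spot=1, R_spot=6.0, centers=((37.5, 37.5),))
        small = [(10.0, 10.0), (10.0, 60.0), (60.0, 10.0), (60.0, 60.0),
                 (37.5, 10.0)]
        f = synthetic_spot_field([(37.5, 37.5)], 6.0, 1.0, G) \
            + synthetic_spot_field(small, 3.0, 1.0, G)
        spots = segment_spots(f, G, cfg=cfg)
        m = compare_initiator_emergent(spots, cfg, G)
        assert m.initiator_count == 1
        assert m.emergent_count == 5
        expected = _rasterized_area((37.5, 37.5), 6.0) / \
            np.mean([_rasterized_area(c, 3.0) for c in small])
        assert m.initiator_emergent_ratio == pytest.approx(expected)
        assert m.initiator_emergent_ratio == pytest.approx(4.0, rel=0.05)

    def test_ratio_flagged_undefined_without_initiators(self):
        cfg = SpotConfig(n_spot=1, R_spot=3.0, centers=((20.0, 20.0),),
                         removed_indices=[0])
        f = synthetic_spot_field([(50.0, 50.0), (60.0, 20.0)], 3.0, 1.0, G)
        m = compare_initiator_emergent(segment_spots(f, G, cfg=cfg), cfg, G)
        assert not m.ratio_defined
        assert math.isnan(m.initiator_emergent_ratio)
        assert m.emergent_count == 2
        assert not m.warnings          # no active centers, no mismatch

    def test_topology_mismatch_warned_in_report(self):
        cfg = SpotConfig(n_spot=1, R_spot=3.0, centers=((20.0, 20.0),))
        f = synthetic_spot_field([(60.0, 60.0)], 3.0, 1.0, G)
        m = compare_initiator_emergent(segment_spots(f, G, cfg=cfg), cfg, G)
        assert any("topology" in w for w in m.warnings)

    def test_density_is_count_over_domain_area(self):
        cfg = SpotConfig(n_spot=1, R_spot=3.0, centers=((20.0, 20.0),))
        f = synthetic_spot_field([(20.0, 20.0), (60.0, 60.0)], 3.0, 1.0, G)
        m = compare_initiator_emergent(segment_spots(f, G, cfg=cfg), cfg, G)
        assert m.density == m.count / 75.0 ** 2

    def test_empty_spot_list_rejected(self):
        with pytest.raises(ValueError):
            compare_initiator_emergent([], catshark_config(), G)


class TestGapInfill:
    def test_requires_a_gap_configuration(self):
        with pytest.raises(ValueError):
            gap_infill_metrics([], catshark_config())

    def test_synthetic_infill_detected(self):
        cfg = gap_config()
        surviving = list(cfg.active_centers)
        infill = [(28.0, 35.0), (32.0, 40.0)]     # near the removed (30, 37.5)
        f = synthetic_spot_field(surviving, 4.5, 1.0, G) \
            + synthetic_spot_field(infill, 2.0, 1.0, G)
        spots = segment_spots(f, G, cfg=cfg)
        rep = gap_infill_metrics(spots, cfg)
        assert rep.window_radius == 1.5 * 4.5
        assert rep.gap_spot_count == 2
        assert rep.infill_ok
        assert rep.gap_mean_area < rep.surviving_initiator_mean_area

    def test_empty_window_reports_zero(self):
        cfg = gap_config()
        f = synthetic_spot_field(list(cfg.active_centers), 4.5, 1.0, G)
        spots = segment_spots(f, G, cfg=cfg)
        rep = gap_infill_metrics(spots, cfg)
        assert rep.gap_spot_count == 0
        assert math.isnan(rep.gap_mean_area)
        assert not rep.infill_ok


class TestDensitySuite:
    @staticmethod
    def _metrics(count):
        cfg = SpotConfig(n_spot=1, R_spot=3.0, centers=((20.0, 20.0),))
        centers = [(10.0 + 7.0 * i, 10.0 + 6.0 * (i % 7)) for i in range(count)]
        f = synthetic_spot_field(centers, 2.0, 1.0, G)
        return compare_initiator_emergent(segment_spots(f, G, cfg=cfg), cfg, G)

    def test_strictly_decreasing_counts_pass(self):
        res = {"catshark": self._metrics(8), "thornback": self._metrics(5),
               "little_skate": self._metrics(3)}
        rep = density_suite(res)
        assert rep["ordering_ok"]
        assert rep["counts"] == {"catshark": 8, "thornback": 5,
                                 "little_skate": 3}

    def test_identical_presets_violate_ordering(self):
        m = self._metrics(5)
        with pytest.raises(DensityOrderingError, match="catshark"):
            density_suite({"catshark": m, "thornback": m, "little_skate": m})

    def test_missing_preset_rejected(self):
        with pytest.raises(KeyError):
            density_suite({"catshark": self._metrics(3)})


class TestReplicateProportion:
    @pytest.mark.parametrize("affected, total, expected",
                             [(20, 23, 87), (23, 23, 100), (6, 8, 75),
                              (7, 8, 88), (0, 5, 0)])
    def test_rounded_percentages(self, affected, total, expected):
        assert replicate_proportion(affected, total) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            replicate_proportion(1, 0)
        with pytest.raises(ValueError):
            replicate_proportion(5, 3)


def test_nearest_neighbor_cv_zero_on_a_perfect_lattice():
    class Pt:
        def __init__(self, x, y):
            self.x, self.y = x, y

    pts = [Pt(10.0 * i, 10.0 * j) for i in range(3) for j in range(3)]
    mean, cv = nearest_neighbor_stats(pts)
    assert mean == pytest.approx(10.0)
    assert cv == pytest.approx(0.0, abs=1e-12)
    assert all(math.isnan(x) for x in nearest_neighbor_stats(pts[:1]))
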