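"""Activation maps, conduction-velocity trajectory fits, concordance."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import linregress

from panomap import (
    ActivationMap,
    MappingError,
    Modality,
    anisotropy_ratio,
    build_activation_map,
    concordance,
    estimate_anisotropy,
    estimate_cv,
    interpolate_lat,
)
from panomap.mapping import _fit_lat_vs_distance


class _M:
    """Minimal metrics stub with LAT attributes."""

    def __init__(self, **kw):
        self.excluded = kw.pop("excluded", False)
        self.__dict__.update(kw)


def planar_map(layout, direction, speed_mm_ms, variant="olat_50"):
    """LAT field linear in position: wavefront plane moving along direction."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    pos = layout.positions()
    proj = pos @ d
    lats = (proj - proj.min()) / speed_mm_ms
    return ActivationMap(0, {s: float(l) for s, l in zip(layout.site_ids(), lats)}, variant)


class TestBuildMap:
    def test_total_activation_time(self, reference_layout):
        ids = reference_layout.site_ids()[:10]
        amap = build_activation_map({i: _M(olat_50=5.0) for i in ids},
                                    reference_layout, 0, "olat_50")
        assert amap.total_activation_time == 0.0

    def test_excluded_sites_dropped(self, reference_layout):
        ids = reference_layout.site_ids()[:10]
        metrics = {i: _M(olat_50=float(k)) for k, i in enumerate(ids)}
        metrics[ids[0]].excluded = True
        amap = build_activation_map(metrics, reference_layout, 0, "olat_50")
        assert ids[0] not in amap.lat_by_site
        assert ids[0] in amap.excluded_sites

    def test_no_valid_sites_rejected(self, reference_layout):
        with pytest.raises(MappingError):
            build_activation_map({reference_layout.site_ids()[0]: _M(olat_50=None)},
                                 reference_layout, 0, "olat_50")


class TestInterpolateLat:
    def test_exact_at_site(self, reference_layout):
        amap = planar_map(reference_layout, [0, 0, 1], 0.5)
        sid = reference_layout.site_ids()[5]
        got = interpolate_lat(amap, reference_layout, reference_layout.by_id[sid].position)
        assert got == pytest.approx(amap.lat_by_site[sid])

    def test_planar_field_small_error(self, reference_layout):
        amap = planar_map(reference_layout, [1, 0, 0], 0.6)
        rng = np.random.default_rng(0)
        pos = reference_layout.positions()
        lats = np.array([amap.lat_by_site[s] for s in reference_layout.site_ids()])
        rng_idx = rng.choice(len(pos), 30, replace=False)
        span = lats.max() - lats.min()
        for i in rng_idx:
            # query midway between a site and its neighbor
            q = reference_layout.ellipsoid.project(pos[i] + rng.normal(0, 0.2, 3))
            got = interpolate_lat(amap, reference_layout, q)
            d = np.asarray([1.0, 0, 0])
            expect = (q @ d - pos[:, 0].min()) / 0.6
            assert abs(got - expect) <= 0.02 * span

    def test_single_site_rejected(self, reference_layout):
        amap = ActivationMap(0, {reference_layout.site_ids()[0]: 1.0}, "olat_50")
        with pytest.raises(MappingError):
            interpolate_lat(amap, reference_layout, np.array([0.0, 0, 0]))

    def test_far_query_rejected(self, reference_layout):
        amap = planar_map(reference_layout, [0, 0, 1], 0.5)
        with pytest.raises(MappingError):
            interpolate_lat(amap, reference_layout, np.array([50.0, 50.0, 50.0]))


class TestEstimateCv:
    def test_exact_linear_lat_closed_form(self):
        d = np.linspace(0, 8, 20)
        lats = d / 0.5  # 0.5 mm/ms = 500 mm/s
        theta, r2 = _fit_lat_vs_distance(d, lats)
        assert theta == pytest.approx(500.0)
        assert r2 == pytest.approx(1.0)

    def test_unit_equivalence_mm_ms_vs_m_s(self):
        from panomap import ConductionEstimate

        est = ConductionEstimate(theta=600.0, r_squared=1.0, trajectory=np.zeros((3, 3)), n_points=3)
        # mm/s -> m/s is /1000; theta in mm/ms is numerically equal to m/s
        assert est.theta_m_per_s == pytest.approx(0.6)
        assert est.theta / 1000.0 == est.theta_m_per_s

    def test_retrograde_field_rejected(self):
        d = np.linspace(0, 8, 20)
        with pytest.raises(MappingError):
            _fit_lat_vs_distance(d, -d / 0.5)

    def test_noisy_trajectory_monte_carlo(self):
        # LAT noise SD 0.5 ms over a 10 mm trajectory at 600 mm/s
        rng = np.random.default_rng(1)
        d = np.linspace(0, 10, 30)
        thetas = []
        for _ in range(200):
            lats = d / 0.6 + rng.normal(0, 0.5, len(d))
            fit = linregress(d, lats)
            if fit.slope > 0:
                thetas.append(1000.0 / fit.slope)
        assert np.mean(thetas) == pytest.approx(600.0, rel=0.05)

    def test_cv_between_sites_on_planar_field(self, reference_layout, reference_mesh):
        amap = planar_map(reference_layout, [0, 0, 1], 0.5)
        ids = reference_layout.site_ids()
        pos = reference_layout.positions()
        lo = ids[int(np.argmin(pos[:, 2]))]
        hi = ids[int(np.argmax(pos[:, 2]))]
        est = estimate_cv(amap, reference_layout, reference_mesh, lo, hi)
        # a vertical planar wave measured along a meridian path
        assert est.r_squared > 0.95
        assert est.theta == pytest.approx(500.0, rel=0.15)

    def test_invariance_to_lat_offset(self, reference_layout, reference_mesh):
        amap = planar_map(reference_layout, [0, 0, 1], 0.5)
        ids = reference_layout.site_ids()
        pos = reference_layout.positions()
        lo = ids[int(np.argmin(pos[:, 2]))]
        hi = ids[int(np.argmax(pos[:, 2]))]
        a = estimate_cv(amap, reference_layout, reference_mesh, lo, hi)
        b = estimate_cv(amap.shifted(17.0), reference_layout, reference_mesh, lo, hi)
        assert b.theta == pytest.approx(a.theta, rel=1e-9)
        assert b.r_squared == pytest.approx(a.r_squared, rel=1e-9)


class TestAnisotropy:
    def test_ratio_helper(self):
        assert round(anisotropy_ratio(830.0, 390.0), 2) == 2.13
        with pytest.raises(MappingError):
            anisotropy_ratio(500.0, 0.0)

    def test_isotropic_field_ratio_near_one(self, reference_layout, reference_mesh, virtual_heart):
        from dataclasses import replace

        from panomap import simulate_lats

        cfg = replace(virtual_heart.config, theta_long=500.0, theta_trans=500.0)
        lats = simulate_lats(cfg)
        amap = ActivationMap(0, lats, "olat_50")
        res = estimate_anisotropy(amap, reference_layout, reference_mesh, cfg.origin_site)
        assert 1.0 - 0.05 <= res.anisotropy_ratio <= 1.1

    def test_ratio_two_recovered(self, reference_layout, reference_mesh, virtual_heart):
        from panomap import simulate_lats

        cfg = virtual_heart.config  # theta 600/300
        lats = simulate_lats(cfg)
        amap = ActivationMap(0, lats, "olat_50")
        res = estimate_anisotropy(amap, reference_layout, reference_mesh, cfg.origin_site)
        assert res.anisotropy_ratio == pytest.approx(2.0, rel=0.10)
        assert res.theta_max == pytest.approx(600.0, rel=0.10)


class TestConcordance:
    def test_identical_fields_zero_difference(self, reference_layout):
        omap = planar_map(reference_layout, [0, 0, 1], 0.5, "olat_50")
        emap = ActivationMap(0, dict(omap.lat_by_site), "elat_sg")
        rep = concordance(omap, emap, reference_layout)
        diffs = np.array(list(rep.differences.values()))
        petal_bias = np.abs(diffs)  # petal ring av. vs center on a planar field
        assert rep.sd < 0.6
        assert np.mean(petal_bias) < 0.5

    def test_uniform_shift_recovered_exactly(self, reference_layout):
        omap = planar_map(reference_layout, [0, 0, 1], 0.5, "olat_50")
        emap = ActivationMap(0, dict(omap.lat_by_site), "elat_sg")
        base = concordance(omap, emap, reference_layout)
        shifted = concordance(omap, emap.shifted(-1.7), reference_layout)
        assert shifted.mean == pytest.approx(base.mean + 1.7)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-9)

    def test_min_petals_enforced(self, reference_layout):
        omap = planar_map(reference_layout, [0, 0, 1], 0.5, "olat_50")
        emap = ActivationMap(0, {e: 0.0 for e in reference_layout.petal_map}, "elat_sg")
        # with only 3 optical sites left, no electrode keeps >= 4 valid petals
        optical_ids = reference_layout.site_ids(Modality.OPTICAL)
        few = {s: omap.lat_by_site[s] for s in optical_ids[:3]}
        sparse = ActivationMap(0, few, "olat_50")
        with pytest.raises(MappingError):
            concordance(sparse, emap, reference_layout, min_petals=4)

    def test_beat_mismatch_rejected(self, reference_layout):
        omap = planar_map(reference_layout, [0, 0, 1], 0.5, "olat_50")
        emap = ActivationMap(1, dict(omap.lat_by_site), "elat_sg")
        with pytest.raises(MappingError):
            concordance(omap, emap, reference_layout)
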