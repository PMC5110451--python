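import numpy as np
import pytest

from nanorisk import (
    DiscreteDistribution,
    DoseResponseConfig,
    build_material_network,
    classify_risk,
    concentration_distribution,
    derive_oel,
    exposure_posterior,
    hazard_quotient,
    heatmap_point,
    oel_distribution,
)
from nanorisk.errors import NanoriskError
from nanorisk.materials import MATERIAL_RISK_ORDER


class TestDeriveOEL:
    def test_noael_with_usual_factor_100(self):
        cfg = DoseResponseConfig(point_of_departure=1000.0)
        assert derive_oel(cfg) == pytest.approx(10.0)

    def test_unit_factor_is_identity(self):
        cfg = DoseResponseConfig(point_of_departure=123.4, uncertainty_factor=1.0)
        assert derive_oel(cfg) == pytest.approx(123.4)

    def test_loael_composes_extra_factor(self):
        cfg = DoseResponseConfig(
            point_of_departure=1000.0, pod_kind="LOAEL", uncertainty_factor=100.0
        )
        assert derive_oel(cfg) == pytest.approx(1.0)

    def test_cmr_switches_to_linear_mode_with_extra_divisor(self):
        threshold = DoseResponseConfig(point_of_departure=1000.0)
        linear = DoseResponseConfig(point_of_departure=1000.0, cmr=True)
        assert linear.effective_mode == "linear"
        assert derive_oel(linear) == pytest.approx(derive_oel(threshold) / 10.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(point_of_departure=-1.0),
            dict(point_of_departure=10.0, uncertainty_factor=0.5),
            dict(point_of_departure=10.0, pod_kind="GUESS"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DoseResponseConfig(**kwargs)


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "hq,band",
        [
            (5.0, "negligible"),
            (50.0, "caution"),
            (100.0, "caution"),  # the inflection is strictly above 100%
            (100.000001, "potential risk"),
            (250.0, "potential risk"),
            (1000.0, "potential risk"),
            (2500.0, "high risk"),
        ],
    )
    def test_bands(self, hq, band):
        assert classify_risk(hq) == band

    def test_inflection_exactly_at_100(self):
        eps = 1e-9
        assert classify_risk(100.0 - eps) == "caution"
        assert classify_risk(100.0 + eps) == "potential risk"


class TestHazardQuotient:
    def test_point_masses_scalar_ratio(self):
        f = hazard_quotient(DiscreteDistribution.point(5.0), DiscreteDistribution.point(10.0))
        assert f.mean_hq == pytest.approx(50.0)
        assert f.interval_90 == (pytest.approx(50.0), pytest.approx(50.0))
        assert f.band == "caution"

    def test_equal_point_masses_hit_100_exactly(self):
        f = hazard_quotient(DiscreteDistribution.point(7.0), DiscreteDistribution.point(7.0))
        assert f.mean_hq == pytest.approx(100.0)
        assert f.band == "caution"

    def test_distribution_sums_to_one(self):
        exp = DiscreteDistribution((1.0, 4.0, 20.0), (0.3, 0.5, 0.2))
        oel = DiscreteDistribution((2.0, 8.0, 40.0), (0.25, 0.5, 0.25))
        f = hazard_quotient(exp, oel)
        assert sum(f.hq_distribution) == pytest.approx(1.0, abs=1e-9)

    def test_matches_monte_carlo_oracle(self):
        """Mean and 90% quantiles of the discrete ratio agree with a
        10^6-draw sampling oracle within 0.5%."""
        exp = DiscreteDistribution((2.0, 7.0, 30.0), (0.35, 0.45, 0.2))
        oel = DiscreteDistribution((1.5, 9.0, 60.0), (0.3, 0.45, 0.25))
        f = hazard_quotient(exp, oel)

        rng = np.random.default_rng(123)
        n = 1_000_000
        c = rng.choice(exp.values, size=n, p=exp.probs)
        o = rng.choice(oel.values, size=n, p=oel.probs)
        hq = c / o * 100.0
        assert f.mean_hq == pytest.approx(hq.mean(), rel=5e-3)
        lo, hi = np.quantile(hq, [0.05, 0.95])
        assert f.interval_90[0] == pytest.approx(lo, rel=5e-3)
        assert f.interval_90[1] == pytest.approx(hi, rel=5e-3)

    def test_scale_equivariance(self):
        exp = DiscreteDistribution((1.0, 5.0, 12.0), (0.2, 0.5, 0.3))
        oel = DiscreteDistribution((4.0, 16.0), (0.6, 0.4))
        base = hazard_quotient(exp, oel).mean_hq
        for k in (0.1, 3.0, 42.0):
            scaled = DiscreteDistribution(
                tuple(k * v for v in exp.values), exp.probs
            )
            assert hazard_quotient(scaled, oel).mean_hq == pytest.approx(k * base, rel=1e-12)

    def test_oel_antitonicity(self):
        exp = DiscreteDistribution((1.0, 5.0, 12.0), (0.2, 0.5, 0.3))
        means = [
            hazard_quotient(exp, DiscreteDistribution.point(o)).mean_hq
            for o in (2.0, 5.0, 20.0, 100.0)
        ]
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_zero_oel_mass_rejected(self):
        exp = DiscreteDistribution.point(1.0)
        with pytest.raises(NanoriskError):
            hazard_quotient(exp, DiscreteDistribution((0.0, 5.0), (0.5, 0.5)))


class TestExposurePosterior:
    def test_fixed_bin_gives_point_mass(self, cnt_net):
        var = cnt_net.variable("NMs Concentration in Air")
        post = exposure_posterior(cnt_net, {var.name: var.states[2]})
        expected = np.zeros(var.cardinality)
        expected[2] = 1.0
        assert np.allclose(post, expected)

    def test_empty_evidence_valid_distribution(self, cnt_net):
        post = exposure_posterior(cnt_net)
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(post >= 0)

    def test_dispersibility_shift_does_not_lower_mean_concentration(self, cnt_net):
        lo = concentration_distribution(cnt_net, {"Dispersibility": "low"}).mean
        hi = concentration_distribution(cnt_net, {"Dispersibility": "high"}).mean
        assert hi >= lo


class TestHeatmap:
    def test_point_mass_coordinates(self):
        f = hazard_quotient(DiscreteDistribution.point(5.0), DiscreteDistribution.point(10.0))
        p = heatmap_point(f, "x")
        assert p.x_mean_oel == pytest.approx(10.0)
        assert p.y_mean_concentration == pytest.approx(5.0)
        assert p.band == f.band

    def test_materials_give_distinct_ordered_points(self):
        forecasts = {}
        for m in MATERIAL_RISK_ORDER:
            net = build_material_network(m)
            forecasts[m] = hazard_quotient(
                concentration_distribution(net), oel_distribution(net)
            )
        points = [heatmap_point(forecasts[m], m) for m in MATERIAL_RISK_ORDER]
        coords = {(p.x_mean_oel, p.y_mean_concentration) for p in points}
        assert len(coords) == len(points)
        hqs = [forecasts[m].mean_hq for m in MATERIAL_RISK_ORDER]
        assert hqs == sorted(hqs)
        band_rank = {"negligible": 0, "caution": 1, "potential risk": 2, "high risk": 3}
        ranks = [band_rank[p.band] for p in points]
        assert ranks == sorted(ranks)

    def test_point_inside_own_interval_rectangle(self):
        for m in MATERIAL_RISK_ORDER:
            net = build_material_network(m)
            f = hazard_quotient(concentration_distribution(net), oel_distribution(net))
            p = heatmap_point(f, m)
            assert p.x_interval_90[0] <= p.x_mean_oel <= p.x_interval_90[1]
            assert p.y_interval_90[0] <= p.y_mean_concentration <= p.y_interval_90[1]

    def test_render_heatmap_writes_png(self, tmp_path):
        from nanorisk.risk import render_heatmap

        f = hazard_quotient(DiscreteDistribution.point(5.0), DiscreteDistribution.point(10.0))
        out = tmp_path / "map.png"
        render_heatmap([heatmap_point(f, "demo")], str(out))
        assert out.stat().st_size > 0
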