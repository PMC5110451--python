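import numpy as np
import pytest
from scipy import stats

from nanorisk import (
    FixtureSpec,
    build_material_network,
    concentration_distribution,
    em_fit,
    generate_cases,
    hazard_quotient,
    oel_distribution,
    out_of_sample_check,
    predictive_set,
    sample_cases,
    truth_network,
)
from nanorisk.errors import DataError, NetworkError
from nanorisk.materials import MATERIAL_RISK_ORDER

from conftest import random_network


class TestTruthNetworks:
    def test_truths_validate_and_share_structure(self):
        nets = {m: truth_network(m) for m in MATERIAL_RISK_ORDER}
        ref = nets[MATERIAL_RISK_ORDER[0]]
        for net in nets.values():
            assert net.names == ref.names
            assert sorted(net.edges) == sorted(ref.edges)

    def test_unknown_material(self):
        with pytest.raises(KeyError):
            truth_network("graphene")

    def test_mean_hq_respects_configured_ordering(self):
        hqs = []
        for m in MATERIAL_RISK_ORDER:
            net = truth_network(m)
            f = hazard_quotient(
                concentration_distribution(net), oel_distribution(net)
            )
            hqs.append(f.mean_hq)
        assert hqs == sorted(hqs)


class TestGenerateCases:
    def test_deterministic_byte_identity(self):
        fix = FixtureSpec("CNT", seed=7)
        a = generate_cases(fix).to_csv(index=False)
        b = generate_cases(FixtureSpec("CNT", seed=7)).to_csv(index=False)
        assert a == b

    def test_zero_missing_rate_has_no_gaps(self):
        table = generate_cases(FixtureSpec("Ag", missing_rate=0.0, seed=1))
        assert not table.isna().any().any()

    def test_cnt_fixture_matches_collection_shape(self):
        table = generate_cases(FixtureSpec("CNT", seed=7))
        assert table.shape == (46, 14)
        frac = table.isna().to_numpy().mean()
        assert 0.2 < frac < 0.4  # around the default 0.3 MCAR rate

    def test_default_row_counts_per_material(self):
        for material, rows in (("CNT", 46), ("Ag", 39), ("TiO2", 55)):
            assert len(generate_cases(FixtureSpec(material, seed=0))) == rows

    def test_column_weights_skew_missingness(self):
        fix = FixtureSpec(
            "CNT", n_rows=400, seed=5, column_weights={"Coating": 3.0}
        )
        table = generate_cases(fix)
        assert table["Coating"].isna().mean() > table["pH"].isna().mean()

    def test_sampling_consistency_chi2(self):
        """Empirical joint of 50,000 complete samples is consistent with
        the generating network (χ² goodness-of-fit, α = 0.01)."""
        net = random_network(17, max_nodes=4)  # small: full joint is testable
        n = 50_000
        cases = sample_cases(net, n, np.random.default_rng(99))

        from nanorisk.inference import Factor, cpt_factor

        joint = Factor((), np.array(1.0))
        for name in net.names:
            joint = joint * cpt_factor(net, name)
        probs = joint.align(tuple(net.names)).ravel()

        cards = [net.variable(v).cardinality for v in net.names]
        idx = np.zeros(len(cases), dtype=int)
        for v, c in zip(net.names, cards):
            states = {s: i for i, s in enumerate(net.variable(v).states)}
            idx = idx * c + cases[v].map(states).to_numpy()
        observed = np.bincount(idx, minlength=probs.size)

        keep = probs * n >= 5  # classic χ² validity rule
        chi2 = float(((observed[keep] - n * probs[keep]) ** 2 / (n * probs[keep])).sum())
        dof = int(keep.sum()) - 1
        assert stats.chi2.sf(chi2, dof) > 0.01

    def test_invalid_fixture_specs(self):
        with pytest.raises(DataError):
            FixtureSpec("CNT", n_rows=0)
        with pytest.raises(DataError):
            FixtureSpec("CNT", missing_rate=1.0)


class TestPredictiveSets:
    def test_smallest_mass_set(self):
        assert predictive_set(np.array([0.5, 0.3, 0.15, 0.05]), 0.9) == [0, 1, 2]
        assert predictive_set(np.array([0.95, 0.05]), 0.9) == [0]
        assert predictive_set(np.array([0.25, 0.25, 0.25, 0.25]), 0.9) == [0, 1, 2, 3]

    def test_point_mass_needs_single_state(self):
        assert predictive_set(np.array([0.0, 1.0, 0.0]), 0.9) == [1]


class TestOutOfSample:
    def test_truth_model_is_calibrated(self):
        truth = truth_network("CNT")
        report = out_of_sample_check(truth, truth, n_test=300, seed=3)
        assert report.coverage >= 0.90  # discrete sets are conservative

    def test_uniform_model_covers_with_vacuous_sets(self):
        truth = truth_network("CNT")
        uniform = truth.copy()
        for n in uniform.cpts:
            uniform.cpts[n].table[:] = 1.0 / uniform.cpts[n].table.shape[1]
        sharp = out_of_sample_check(truth, truth, n_test=100, seed=5)
        vague = out_of_sample_check(truth, uniform, n_test=100, seed=5)
        assert vague.coverage >= 0.90
        assert vague.mean_set_size > sharp.mean_set_size  # wide, weak intervals

    def test_zero_test_cases_rejected(self):
        truth = truth_network("CNT")
        with pytest.raises(DataError):
            out_of_sample_check(truth, truth, n_test=0, seed=0)

    def test_structure_mismatch_rejected(self):
        truth = truth_network("CNT")
        other = random_network(2)
        with pytest.raises(NetworkError):
            out_of_sample_check(truth, other, n_test=10, seed=0)


class TestPipelineClosure:
    def test_fit_then_forecast_runs_end_to_end(self):
        """EM on the synthetic CNT collection, then a full risk forecast —
        no external input anywhere."""
        cases = generate_cases(FixtureSpec("CNT", seed=7))
        fit = em_fit(build_material_network("CNT"), cases, max_iter=25, seed=0)
        f = hazard_quotient(
            concentration_distribution(fit.network), oel_distribution(fit.network)
        )
        assert np.isfinite(f.mean_hq) and f.mean_hq > 0
        assert f.interval_90[0] <= f.interval_90[1]
        assert f.band in ("negligible", "caution", "potential risk", "high risk")
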