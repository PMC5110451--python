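import numpy as np
import pandas as pd
import pytest

from nanorisk import em_fit, update_with_cases, validate_network
from nanorisk.errors import DataError
from nanorisk.inference import eliminate
from nanorisk.learning import ExperienceTable, encode_cases
from nanorisk.synthetic import FixtureSpec, generate_cases, sample_cases

from conftest import random_network, recovery_truth


def frequency_mle(net, cases):
    """Independent count-and-divide oracle for complete data."""
    tables = {}
    for name in net.names:
        cpt = net.cpts[name]
        var = net.variable(name)
        counts = np.zeros_like(cpt.table)
        for _, row in cases.iterrows():
            cfg = net.parent_config_index(
                name, {p: net.variable(p).states.index(row[p]) for p in cpt.parents}
            )
            counts[cfg, var.states.index(row[name])] += 1
        tables[name] = counts
    return tables


class TestEMCompleteData:
    def test_zero_prior_equals_relative_frequency_mle(self):
        net = random_network(3)
        rng = np.random.default_rng(5)
        cases = sample_cases(net, 300, rng)
        counts = frequency_mle(net, cases)

        start = net.copy()
        for n in start.names:
            start.cpts[n].table[:] = 1.0 / start.cpts[n].table.shape[1]
        fit = em_fit(start, cases, prior_strength=0.0, tol=1e-9, max_iter=10, seed=0)
        for name in net.names:
            c = counts[name]
            visited = c.sum(axis=1) > 0
            expected = c[visited] / c[visited].sum(axis=1, keepdims=True)
            assert np.allclose(fit.network.cpts[name].table[visited], expected, atol=1e-12)

    def test_complete_data_converges_immediately(self):
        net = random_network(9)
        cases = sample_cases(net, 100, np.random.default_rng(1))
        fit = em_fit(net, cases, prior_strength=0.0, tol=1e-9, max_iter=20, seed=0)
        # the M-step from complete counts is already the fixed point
        assert fit.n_iter <= 3


class TestEMMissingData:
    def test_trace_nondecreasing_on_noisy_fixture(self):
        cases = generate_cases(FixtureSpec("CNT", seed=7))
        from nanorisk import build_material_network

        fit = em_fit(build_material_network("CNT"), cases, tol=1e-6, max_iter=40, seed=0)
        diffs = np.diff(fit.loglik_trace)
        assert diffs.size > 0
        assert np.all(diffs >= -1e-8)

    def test_trace_nondecreasing_zero_prior(self):
        net = random_network(12)
        cases = generate_cases(
            FixtureSpec("custom", n_rows=150, missing_rate=0.3, seed=2, truth=net)
        )
        fit = em_fit(net, cases, prior_strength=0.0, tol=1e-8, max_iter=30, seed=0)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_parameter_recovery_at_5000_rows(self):
        """Fitting 5,000 rows with 30% MCAR missingness recovers every
        well-populated CPT row of the generating network to TV < 0.05."""
        truth = recovery_truth()
        cases = generate_cases(
            FixtureSpec("custom", n_rows=5000, missing_rate=0.3, seed=11, truth=truth)
        )
        start = truth.copy()
        for n in start.names:
            start.cpts[n].table[:] = 1.0 / start.cpts[n].table.shape[1]
        fit = em_fit(start, cases, prior_strength=0.5, tol=1e-7, max_iter=60, seed=1)
        assert fit.converged
        for name in truth.names:
            cpt = truth.cpts[name]
            if cpt.parents:
                f = eliminate(truth, {}, set(cpt.parents))
                p_cfg = f.align(tuple(cpt.parents)).ravel()
            else:
                p_cfg = np.array([1.0])
            for r in range(cpt.n_configs):
                if 5000 * p_cfg[r] < 20:
                    continue
                tv = 0.5 * np.abs(cpt.table[r] - fit.network.cpts[name].table[r]).sum()
                assert tv < 0.05, f"{name} config {r}: TV {tv:.3f}"

    def test_all_missing_column_warned_and_ignored(self):
        net = random_network(3)
        cases = sample_cases(net, 20, np.random.default_rng(0))
        cases[net.names[0]] = np.nan
        with pytest.warns(UserWarning, match="entirely missing"):
            fit = em_fit(net, cases, max_iter=5)
        assert fit.n_iter >= 1

    def test_empty_case_table_rejected(self):
        net = random_network(3)
        with pytest.raises(DataError):
            em_fit(net, pd.DataFrame(columns=net.names))

    def test_unknown_column_rejected(self):
        net = random_network(3)
        cases = sample_cases(net, 5, np.random.default_rng(0))
        cases["Zeta"] = "1"
        with pytest.raises(DataError):
            encode_cases(net, cases)


class TestExperienceUpdating:
    def _uniform_net(self, seed=4):
        net = random_network(seed)
        for n in net.names:
            net.cpts[n].table[:] = 1.0 / net.cpts[n].table.shape[1]
        return validate_network(net)

    def test_zero_new_cases_is_identity(self):
        net = self._uniform_net()
        exp = ExperienceTable.zeros(net)
        new_net, new_exp = update_with_cases(net, exp, pd.DataFrame(columns=net.names))
        for name in net.names:
            assert np.array_equal(new_net.cpts[name].table, net.cpts[name].table)
            assert np.array_equal(new_exp.counts[name], exp.counts[name])

    def test_total_experience_equals_case_count(self):
        """Complete cases into a zero-experience network: the experience
        summed over a variable's parent configurations equals the number
        of observed cases."""
        net = self._uniform_net()
        cases = sample_cases(net, 37, np.random.default_rng(8))
        _, exp = update_with_cases(net, None, cases)
        for name in net.names:
            assert exp.total(name) == pytest.approx(37, abs=1e-9)

    def test_sequential_batches_equal_concatenation(self):
        net = self._uniform_net()
        cases = sample_cases(net, 60, np.random.default_rng(9))
        b1, b2 = cases.iloc[:25], cases.iloc[25:].reset_index(drop=True)

        n_seq, e_seq = update_with_cases(net, None, b1)
        n_seq, e_seq = update_with_cases(n_seq, e_seq, b2)
        n_cat, e_cat = update_with_cases(net, None, cases)
        for name in net.names:
            assert np.allclose(
                n_seq.cpts[name].table, n_cat.cpts[name].table, atol=1e-9
            )
            assert np.allclose(e_seq.counts[name], e_cat.counts[name], atol=1e-9)

    def test_influence_shrinks_with_experience(self):
        """For a fixed new batch, the L1 change of a CPT row is
        non-increasing in that row's prior experience count."""
        net = self._uniform_net()
        cases = sample_cases(net, 30, np.random.default_rng(10))
        name = net.names[-1]
        changes = []
        for e0 in (0.0, 5.0, 50.0, 500.0):
            exp = ExperienceTable.zeros(net)
            exp.counts[name][:] = e0
            new_net, _ = update_with_cases(net, exp, cases)
            changes.append(
                np.abs(new_net.cpts[name].table - net.cpts[name].table).sum()
            )
        assert all(b <= a + 1e-12 for a, b in zip(changes, changes[1:]))

    def test_negative_experience_rejected(self):
        net = self._uniform_net()
        with pytest.raises(ValueError):
            ExperienceTable({net.names[0]: np.array([-1.0])})

    def test_partial_cases_spread_fractional_experience(self):
        net = self._uniform_net(6)
        cases = generate_cases(
            FixtureSpec("custom", n_rows=40, missing_rate=0.5, seed=3, truth=net)
        )
        _, exp = update_with_cases(net, None, cases)
        for name in net.names:
            # every case contributes its full posterior mass somewhere
            assert exp.total(name) == pytest.approx(40, abs=1e-6)
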