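"""Per-probe models, variance moderation, BH-FDR and DMP calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methpanel.dmp as dmp
from methpanel.io import BetaMatrix, ValidationError


def _labels(n_nn, n_an):
    return pd.Series(
        ["NN"] * n_nn + ["AN"] * n_an,
        index=[f"s{i}" for i in range(n_nn + n_an)],
    )


def _matrix(values):
    values = np.atleast_2d(values)
    return BetaMatrix(
        pd.DataFrame(values, index=[f"p{i}" for i in range(len(values))],
                     columns=[f"s{j}" for j in range(values.shape[1])])
    )


def bh_bruteforce(p):
    """Explicit min-over-tail step-up: q_i = min_{j: p_j >= p_i} p_j*m/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestQcFilter:
    def test_missing_value_removed_as_failed_position(self):
        vals = np.full((3, 14), 0.5) + np.random.default_rng(0).normal(0, 0.01, (3, 14))
        df = pd.DataFrame(vals, index=["p0", "p1", "p2"], columns=[f"s{j}" for j in range(14)])
        df.iloc[1, 3] = np.nan
        beta = BetaMatrix(df)
        filtered, log = dmp.qc_filter_probes(beta, _labels(7, 7))
        assert "p1" not in filtered.probe_ids
        assert log.set_index("probe_id").loc["p1", "reason"] == "failed position"

    def test_heavy_tailed_residuals_removed(self):
        """t(1) residuals at n=28 are flagged in >= 80% of replicates."""
        removed = 0
        for s in range(50):
            r = np.random.default_rng(s)
            vals = 0.5 + 0.02 * r.standard_t(1, size=(1, 28))
            vals = np.clip(vals, 0.001, 0.999)
            beta = _matrix(vals)
            _, log = dmp.qc_filter_probes(beta, _labels(14, 14))
            removed += len(log) > 0
        assert removed >= 40

    def test_gaussian_type_one_rate(self):
        r = np.random.default_rng(1)
        vals = np.clip(0.5 + 0.02 * r.normal(size=(2000, 28)), 0.001, 0.999)
        beta = _matrix(vals)
        filtered, log = dmp.qc_filter_probes(beta, _labels(14, 14), shapiro_alpha=0.01)
        rate = len(log) / 2000
        assert rate < 0.025

    def test_too_few_samples_per_class(self):
        beta = _matrix(np.full((1, 4), 0.5))
        with pytest.raises(ValidationError):
            dmp.qc_filter_probes(beta, _labels(2, 2))


class TestFitProbeModels:
    def test_constant_groups_give_exact_delta(self):
        vals = np.array([[0.5] * 14 + [0.7] * 14])
        fits = dmp.fit_probe_models(_matrix(vals), _labels(14, 14))
        assert fits["delta_beta"].iloc[0] == pytest.approx(0.2)
        assert fits["s2"].iloc[0] == pytest.approx(0.0, abs=1e-25)

    def test_delta_equals_group_mean_difference(self, rng):
        vals = rng.uniform(0.2, 0.8, size=(50, 28))
        labels = _labels(13, 15)
        fits = dmp.fit_probe_models(_matrix(vals), labels)
        an = vals[:, 13:].mean(axis=1)
        nn = vals[:, :13].mean(axis=1)
        assert np.allclose(fits["delta_beta"].to_numpy(), an - nn, atol=1e-12)

    def test_sample_permutation_invariance(self, rng):
        vals = rng.uniform(0.2, 0.8, size=(20, 28))
        labels = _labels(14, 14)
        beta = _matrix(vals)
        fits1 = dmp.fit_probe_models(beta, labels)
        perm = rng.permutation(28)
        beta2 = BetaMatrix(beta.values.iloc[:, perm])
        fits2 = dmp.fit_probe_models(beta2, labels)
        assert np.allclose(fits1["t"].to_numpy(), fits2["t"].to_numpy())

    def test_rank_deficient_design_rejected(self, rng):
        vals = rng.uniform(size=(5, 28))
        cov = pd.DataFrame({"dup": (_labels(14, 14) == "AN").astype(float).to_numpy()})
        with pytest.raises(ValidationError, match="rank"):
            dmp.fit_probe_models(_matrix(vals), _labels(14, 14), covariates=cov)


class TestEbayes:
    def _fits(self, rng, n_probes=300):
        vals = np.clip(rng.normal(0.5, 0.05, size=(n_probes, 28)), 0.01, 0.99)
        return dmp.fit_probe_models(_matrix(vals), _labels(14, 14))

    def test_d0_zero_limit_gives_ordinary_t(self, rng):
        fits = self._fits(rng)
        prior = dmp.EBayesPrior(d0=1e-9, s0_sq=1.0)
        _, out = dmp.ebayes_moderate(fits, prior)
        assert np.allclose(out["t_mod"], fits["t"], rtol=1e-3)

    def test_d0_infinite_limit_pins_posterior_variance(self, rng):
        fits = self._fits(rng)
        prior = dmp.EBayesPrior(d0=np.inf, s0_sq=0.002)
        _, out = dmp.ebayes_moderate(fits, prior)
        assert np.allclose(out["s2_post"], 0.002)

    def test_prior_recovery(self):
        """Moment estimator recovers (d0=4, s0^2=0.01) from 1,000 probes."""
        from methpanel.experiments import ebayes_prior_recovery

        rec = ebayes_prior_recovery(d0_true=4.0, s0_sq_true=0.01, seed=3)
        assert 2.0 <= rec["d0"] <= 8.0
        assert abs(rec["s0_sq"] - 0.01) <= 0.003

    def test_all_zero_variance_rejected(self):
        vals = np.array([[0.5] * 14 + [0.7] * 14, [0.2] * 14 + [0.4] * 14])
        fits = dmp.fit_probe_models(_matrix(vals), _labels(14, 14))
        with pytest.raises(ValidationError, match="degenerate"):
            dmp.ebayes_moderate(fits)

    def test_null_moderated_p_uniform(self):
        """Under the global null, moderated p-values pass a KS test."""
        r = np.random.default_rng(8)
        vals = np.clip(r.normal(0.5, 0.04, size=(3000, 28)), 0.01, 0.99)
        fits = dmp.fit_probe_models(_matrix(vals), _labels(14, 14))
        _, out = dmp.ebayes_moderate(fits)
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        q = dmp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert dmp.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(dmp.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            dmp.bh_adjust([0.5, 1.2])

    def test_matches_bruteforce_on_random_vectors(self):
        r = np.random.default_rng(5)
        for _ in range(1000):
            p = r.uniform(size=r.integers(1, 40))
            assert np.allclose(dmp.bh_adjust(p), bh_bruteforce(p), atol=1e-12)


class TestCallDmps:
    def test_printed_count_fraction(self):
        """376 calls of which 326 hyper -> 86.7% hypermethylated."""
        n, n_hyper = 376, 326
        table = pd.DataFrame(
            {
                "delta_beta": [0.2] * n_hyper + [-0.2] * (n - n_hyper),
                "q": 0.05,
                "direction": ["hyper"] * n_hyper + ["hypo"] * (n - n_hyper),
            },
            index=[f"cg{i}" for i in range(n)],
        )
        calls = dmp.call_dmps(table, fdr=0.10)
        assert calls.n_total == 376 and calls.n_hyper == 326
        assert calls.pct_hyper == pytest.approx(86.7, abs=0.05)

    def test_no_calls_empty(self):
        table = pd.DataFrame({"delta_beta": [0.1], "q": [0.9], "direction": ["hyper"]},
                             index=["cg0"])
        assert dmp.call_dmps(table, 0.10).n_total == 0

    def test_probe_order_invariance(self, dmp_results):
        table = dmp_results.table
        shuffled = table.sample(frac=1, random_state=2)
        a = dmp.call_dmps(table, 0.10).table.index
        b = dmp.call_dmps(shuffled, 0.10).table.index
        assert set(a) == set(b)


class TestModelObject:
    def test_fit_summary_and_calls(self, dmp_results, small_plan):
        calls = dmp_results.call_dmps(0.10)
        planted = set(small_plan.planted_ids)
        called = set(calls.table.index)
        # planted effects dominate the calls; FDP stays moderate at small scale
        assert len(called & planted) >= 0.8 * len(planted)
        summary = dmp_results.summary()
        assert "prior df (d0)" in summary.index
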