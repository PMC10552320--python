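"""Generator contracts: determinism, planted effects, noise calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methpanel as mp
import methpanel.design as design_mod
import methpanel.synth as synth_mod
from methpanel.io import ValidationError
from methpanel.synth import CohortConfig, NoiseModel


class TestGenerateCohort:
    def test_default_composition(self):
        cohort = mp.generate_cohort(seed=1)
        assert len(cohort) == 433
        val = cohort.subset(cohort.df["cohort"] == "validation")
        counts = val.labels.value_counts()
        assert counts["NN"] == 39 and counts["AN"] == 66

    def test_empty_config(self):
        cohort = mp.generate_cohort(CohortConfig(composition=()), seed=0)
        assert len(cohort) == 0

    def test_same_seed_identical(self):
        a = mp.generate_cohort(seed=5).df
        b = mp.generate_cohort(seed=5).df
        pd.testing.assert_frame_equal(a, b)

    def test_ages_in_screening_window(self):
        df = mp.generate_cohort(seed=2).df
        assert df["age"].between(50, 75).all()

    def test_sex_balanced_within_groups(self):
        cohort = mp.generate_cohort(seed=3)
        disc = cohort.subset(cohort.df["cohort"] == "discovery")
        groups = disc.df.apply(design_mod.pathological_group, axis=1)
        for g, sub in disc.df.groupby(groups):
            sexes = sub["sex"].value_counts()
            assert abs(sexes.get("male", 0) - sexes.get("female", 0)) <= 1


class TestGenerateMethylome:
    def test_planted_effect_recovered(self):
        comp = (
            {"finding": "NCF", "count": 200},
            {"finding": "CRC", "stage": "II", "count": 200},
        )
        cohort = mp.generate_cohort(CohortConfig(composition=comp), seed=7)
        probes = [f"p{i}" for i in range(50)]
        plan = mp.make_marker_plan(probes, n_planted=1, effect_range=(0.2, 0.2),
                                   frac_hyper=1.0, seed=7)
        meth = mp.generate_methylome(cohort, plan, seed=7)
        labels = cohort.labels.to_numpy()
        target = plan.planted_ids[0]
        row = meth.values.loc[target]
        diff = row[labels == "AN"].mean() - row[labels == "NN"].mean()
        assert abs(diff - 0.2) < 0.03

    def test_null_calibration_t_test(self):
        """With no planted effects, per-probe t-tests reject at ~alpha."""
        comp = ({"finding": "NCF", "count": 60}, {"finding": "CRC", "stage": "I", "count": 60})
        cohort = mp.generate_cohort(CohortConfig(composition=comp), seed=9)
        probes = [f"p{i}" for i in range(2000)]
        plan = synth_mod.MarkerPlan(
            planted_ids=(), delta_beta=pd.Series(dtype=float),
            baseline_mean=pd.Series(0.5, index=probes),
        )
        meth = mp.generate_methylome(cohort, plan, seed=9)
        labels = cohort.labels.to_numpy()
        arr = meth.values.to_numpy()
        _, p = stats.ttest_ind(arr[:, labels == "AN"], arr[:, labels == "NN"], axis=1)
        rate = float(np.mean(p < 0.05))
        # MC tolerance: 3 * sqrt(0.05*0.95/2000) ~ 0.015
        assert abs(rate - 0.05) < 0.02

    def test_hyper_fraction_default(self):
        plan = mp.make_marker_plan([f"p{i}" for i in range(5000)], n_planted=300, seed=4)
        frac = float((plan.delta_beta > 0).mean())
        assert abs(frac - 0.867) < 0.01

    def test_effect_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError, match="probe"):
            synth_mod.MarkerPlan(
                planted_ids=("p0",),
                delta_beta=pd.Series({"p0": 0.5}),
                baseline_mean=pd.Series({"p0": 0.7}),
            )

    def test_determinism(self, discovery, small_plan):
        a = mp.generate_methylome(discovery, small_plan, seed=3).values
        b = mp.generate_methylome(discovery, small_plan, seed=3).values
        assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestSimulateArrayPools:
    def _pool(self, members):
        return design_mod.PoolSpec("POOL01", tuple(members), "NCF", "NN")

    def _matrix(self, values_by_member):
        df = pd.DataFrame(values_by_member, index=["probeA"])
        return mp.BetaMatrix(df)

    def test_zero_noise_constant_members(self):
        members = [f"m{i}" for i in range(10)]
        beta = self._matrix({m: [0.4] for m in members})
        pools = mp.simulate_array_pools(beta, [self._pool(members)],
                                        NoiseModel(array_logit_sd=0.0), seed=1)
        assert pools.values.loc["probeA", "POOL01"] == pytest.approx(0.4)

    def test_zero_noise_half_and_half(self):
        members = [f"m{i}" for i in range(10)]
        vals = {m: [0.0 if i < 5 else 1.0] for i, m in enumerate(members)}
        beta = self._matrix(vals)
        pools = mp.simulate_array_pools(beta, [self._pool(members)],
                                        NoiseModel(array_logit_sd=0.0), seed=1)
        assert pools.values.loc["probeA", "POOL01"] == pytest.approx(0.5)

    def test_missing_member_named(self, pool_data, discovery_pools):
        meth, _, _ = pool_data
        bad = design_mod.PoolSpec("POOL99", tuple(f"ghost{i}" for i in range(10)), "NCF", "NN")
        with pytest.raises(ValidationError, match="POOL99.*ghost0"):
            mp.simulate_array_pools(meth, [bad], seed=0)

    def test_default_noise_high_correlation(self, rng):
        """Pool values track member means across 1,000 probes (r > 0.95)."""
        members = [f"m{i}" for i in range(10)]
        vals = rng.uniform(0.05, 0.95, size=(1000, 10))
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(1000)], columns=members)
        beta = mp.BetaMatrix(df)
        pools = mp.simulate_array_pools(beta, [self._pool(members)], seed=3)
        r = np.corrcoef(vals.mean(axis=1), pools.values["POOL01"].to_numpy())[0, 1]
        assert r > 0.95


class TestSimulatePyrosequencing:
    def test_zero_noise_exact(self, pool_data):
        meth, _, _ = pool_data
        probes = meth.probe_ids[:3]
        pyro = mp.simulate_pyrosequencing(meth, probes, NoiseModel(pyro_percent_sd=0.0), seed=1)
        wide = pyro.wide()
        for p in probes:
            expected = 100.0 * meth.values.loc[p].reindex(wide.index)
            assert np.allclose(wide[p].to_numpy(), expected.to_numpy())

    def test_unknown_marker_rejected(self, pool_data):
        meth, _, _ = pool_data
        with pytest.raises(ValidationError, match="unknown"):
            mp.simulate_pyrosequencing(meth, ["not_a_probe"], seed=1)

    def test_noise_monotonically_degrades_concordance(self, pool_data, discovery_pools, discovery):
        """Doubling pyro noise lowers pool-vs-individual r (5 seeds)."""
        meth, pool_beta, _ = pool_data
        probes = list(meth.probe_ids[:26])
        group_of_pool = pd.Series({p.pool_id: p.group for p in discovery_pools})
        subj_group = discovery.df.apply(design_mod.pathological_group, axis=1)
        subj_group.index = discovery.df["subject_id"]

        def concordance(sd, seed):
            pyro = mp.simulate_pyrosequencing(meth, probes, NoiseModel(pyro_percent_sd=sd), seed=seed)
            wide = pyro.wide() / 100.0
            xs, ys = [], []
            for p in probes:
                pool_g = pool_beta.values.loc[p].groupby(group_of_pool).mean()
                ind_g = wide[p].groupby(subj_group.reindex(wide.index)).mean()
                common = pool_g.index.intersection(ind_g.index)
                xs.extend(pool_g[common]); ys.extend(ind_g[common])
            return np.corrcoef(xs, ys)[0, 1]

        worse = sum(concordance(16.0, s) < concordance(8.0, s) for s in range(5))
        assert worse >= 4


class TestRrbsTable:
    def test_exact_concordant_count(self, small_plan, dmp_results):
        from methpanel.prioritize import rrbs_concordance_filter

        table = mp.generate_rrbs_table(small_plan, n_concordant=8, min_diff=0.30, seed=2)
        # concordance against the plan's own truth (sign of planted effect)
        truth = pd.DataFrame({"delta_beta": small_plan.delta_beta})
        assert len(rrbs_concordance_filter(truth, table, 0.30)) == 8

    def test_zero_concordant(self, small_plan):
        from methpanel.prioritize import rrbs_concordance_filter

        table = mp.generate_rrbs_table(small_plan, n_concordant=0, min_diff=0.30, seed=2)
        truth = pd.DataFrame({"delta_beta": small_plan.delta_beta})
        assert rrbs_concordance_filter(truth, table, 0.30) == []

    def test_sign_flip_breaks_concordance(self, small_plan):
        from methpanel.prioritize import rrbs_concordance_filter

        table = mp.generate_rrbs_table(small_plan, n_concordant=8, min_diff=0.30, seed=2)
        table["rrbs_diff"] = -table["rrbs_diff"]
        truth = pd.DataFrame({"delta_beta": small_plan.delta_beta})
        assert rrbs_concordance_filter(truth, table, 0.30) == []

    def test_min_diff_validated(self, small_plan):
        with pytest.raises(ValidationError):
            mp.generate_rrbs_table(small_plan, min_diff=1.5, seed=0)


class TestOfftargetAndPaired:
    def _plan(self):
        probes = [f"p{i}" for i in range(4)]
        return mp.make_marker_plan(probes, n_planted=4, effect_range=(0.3, 0.35),
                                   frac_hyper=0.5, seed=1), {f"CG{i+1}": p for i, p in enumerate(probes)}

    def test_zero_offset_serum_equals_plasma(self):
        plan, markers = self._plan()
        off = mp.generate_offtarget_and_paired(
            plan, markers, NoiseModel(plasma_offset_sd=0.0), seed=3
        )
        s = off.serum_pyro.wide().to_numpy()
        p = off.plasma_pyro.wide().to_numpy()
        assert np.array_equal(s, p)
        from methpanel.valstats import group_tests
        with pytest.warns(UserWarning):
            assert group_tests(s[:, 0], p[:, 0], paired=True) == 1.0

    def test_contamination_zero(self):
        plan, markers = self._plan()
        off = mp.generate_offtarget_and_paired(plan, markers, contamination=0.0, seed=3)
        assert off.contaminated_ids == ()

    def test_contamination_count(self):
        plan, markers = self._plan()
        off = mp.generate_offtarget_and_paired(plan, markers, contamination=3 / 16, seed=3)
        assert len(off.contaminated_ids) == 3
        assert len(off.tumor_types) == 16

    def test_contamination_bounds(self):
        plan, markers = self._plan()
        with pytest.raises(ValidationError):
            mp.generate_offtarget_and_paired(plan, markers, contamination=1.2, seed=0)
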