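"""Canned end-to-end simulation experiments on the synthetic generator.

These functions wire the generator and the analysis stages into the
study-shaped computations the package is calibrated against: the
28-pool discovery design, the empirical false-discovery proportion of
the DMP caller, the pooled-array vs individual-pyrosequencing
concordance, penalized-lasso support recovery at evaluation-cohort
size, and the off-target tumor evaluation of a frozen 2- or 4-marker
panel.  They are used by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import design as design_mod
from . import synth as synth_mod
from .dmp import DifferentialMethylation
from .io import CohortTable
from .panels import PenalizedPanelSelector, build_design
from .valstats import PanelLogit, diagnostic_report, evaluate_offtarget, loocv_scores

__all__ = [
    "discovery_pool_design",
    "empirical_fdr",
    "pool_concordance_r",
    "lasso_recovery_rate",
    "offtarget_misclassification",
    "ebayes_prior_recovery",
]


def discovery_pool_design(seed: int = 0):
    """Pools built from a discovery cohort with the study composition.

    Returns (pools, cohort); the default composition yields 28 pools,
    13 NN and 15 AN, each 5 men + 5 women from one pathological group.
    """
    cohort = synth_mod.generate_cohort(seed=seed)
    disc = cohort.subset(cohort.df["cohort"] == "discovery")
    pools = design_mod.build_pools(disc, seed=seed)
    return pools, disc


def _two_arm_cohort(n_per_arm: int = 140, seed: int = 0) -> CohortTable:
    """Minimal NN/AN cohort sized for 14 + 14 pools of 10."""
    comp = (
        {"finding": "NCF", "count": n_per_arm},
        {"finding": "AA", "location": "distal", "count": n_per_arm // 2},
        {"finding": "CRC", "stage": "II", "count": n_per_arm - n_per_arm // 2},
    )
    return synth_mod.generate_cohort(synth_mod.CohortConfig(composition=comp), seed=seed)


def empirical_fdr(
    n_probes: int = 20000,
    n_planted: int = 200,
    effect: float = 0.2,
    n_seeds: int = 20,
    fdr: float = 0.10,
    seed: int = 0,
) -> dict:
    """Empirical false-discovery proportion of the DMP-calling stage.

    For each replicate: individuals with ``n_planted`` planted effects
    of |delta beta| = ``effect`` are pooled into 14 NN and 14 AN pools,
    the full QC -> per-probe fit -> moderation -> BH pipeline is run,
    and the fraction of called probes that were not planted is
    recorded.  Returns the mean FDP (percent) with its Monte-Carlo
    standard error and the mean number of calls.
    """
    rng = np.random.default_rng(seed)
    fdps, n_calls = [], []
    for r in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        cohort = _two_arm_cohort(seed=s)
        probes = [f"cg{i:08d}" for i in range(n_probes)]
        plan = synth_mod.make_marker_plan(
            probes, n_planted=n_planted, effect_range=(effect, effect), seed=s + 1
        )
        meth = synth_mod.generate_methylome(cohort, plan, seed=s + 2)
        pools = design_mod.build_pools(cohort, seed=s + 3)
        pool_beta = synth_mod.simulate_array_pools(meth, pools, seed=s + 4)
        classes = pd.Series({p.pool_id: p.cls for p in pools})
        res = DifferentialMethylation(pool_beta, classes).fit()
        calls = res.call_dmps(fdr=fdr)
        called = set(calls.table.index)
        planted = set(plan.planted_ids)
        fdps.append(len(called - planted) / len(called) if called else 0.0)
        n_calls.append(len(called))
    fdps = np.asarray(fdps)
    return {
        "fdp_pct": 100.0 * float(fdps.mean()),
        "mc_se_pct": 100.0 * float(fdps.std(ddof=1) / np.sqrt(len(fdps))),
        "mean_calls": float(np.mean(n_calls)),
        "n_seeds": n_seeds,
    }


def pool_concordance_r(n_markers: int = 26, seed: int = 0) -> dict:
    """Pearson r between pool-level array betas and group-mean pyro percents.

    Discovery individuals are pooled and array-measured at the marker
    probes; evaluation individuals are pyrosequenced at the same
    markers with default noise.  r is computed across (marker,
    pathological group) pairs, pairing the group's mean pool beta with
    the group's mean individual percent / 100.
    """
    cohort = synth_mod.generate_cohort(seed=seed)
    probes = [f"cg{i:06d}" for i in range(n_markers)]
    plan = synth_mod.make_marker_plan(
        probes, n_planted=n_markers, effect_range=(0.10, 0.30), seed=seed + 1
    )
    disc = cohort.subset(cohort.df["cohort"] == "discovery")
    ev = cohort.subset(cohort.df["cohort"] == "evaluation")
    meth_disc = synth_mod.generate_methylome(disc, plan, seed=seed + 2)
    pools = design_mod.build_pools(disc, seed=seed + 3)
    pool_beta = synth_mod.simulate_array_pools(meth_disc, pools, seed=seed + 4)
    meth_ev = synth_mod.generate_methylome(ev, plan, seed=seed + 5)
    markers = {f"CG{i + 1}": p for i, p in enumerate(probes)}
    pyro = synth_mod.simulate_pyrosequencing(meth_ev, markers, seed=seed + 6)

    group_of_pool = {p.pool_id: p.group for p in pools}
    ev_groups = ev.df.apply(design_mod.pathological_group, axis=1)
    ev_groups.index = ev.df["subject_id"]
    wide = pyro.wide() / 100.0
    xs, ys = [], []
    for mi, (marker, probe) in enumerate(markers.items()):
        pool_by_group = pool_beta.values.loc[probe].groupby(
            pd.Series(group_of_pool)
        ).mean()
        ind_by_group = wide[marker].groupby(ev_groups.reindex(wide.index)).mean()
        common = pool_by_group.index.intersection(ind_by_group.index)
        xs.extend(pool_by_group[common])
        ys.extend(ind_by_group[common])
    r = float(np.corrcoef(xs, ys)[0, 1])
    return {"pearson_r": r, "n_pairs": len(xs)}


def _planted_two_design(seed: int, n_markers: int = 26, effect_range=(0.26, 0.34)):
    """Evaluation-cohort design where exactly two markers carry signal.

    Effects average ~0.30 beta — the magnitude the external
    concordance filter treats as a large methylation difference —
    chosen so each informative marker is predictive but not
    individually sufficient, the regime in which support recovery is
    possible at n ~ 48.
    """
    cohort = synth_mod.generate_cohort(seed=seed)
    ev = cohort.subset(cohort.df["cohort"] == "evaluation")
    probes = [f"cg{i:06d}" for i in range(n_markers)]
    plan = synth_mod.make_marker_plan(
        probes, n_planted=2, effect_range=effect_range, frac_hyper=0.5, seed=seed
    )
    meth = synth_mod.generate_methylome(ev, plan, seed=seed + 100)
    markers = {f"CG{i + 1}": p for i, p in enumerate(probes)}
    pyro = synth_mod.simulate_pyrosequencing(meth, markers, seed=seed + 200)
    design = build_design(pyro, ev, transform="log10")
    truth = {f"CG{i + 1}" for i, p in enumerate(probes) if p in plan.planted_ids}
    return design, truth


def lasso_recovery_rate(n_seeds: int = 20, seed0: int = 0) -> dict:
    """Fraction of replicates where the CV-tuned lasso recovers exactly
    the two planted markers (age/sex excluded from the comparison)."""
    exact = contained = 0
    for s in range(seed0, seed0 + n_seeds):
        design, truth = _planted_two_design(s)
        fit = PenalizedPanelSelector(design, penalty="lasso", seed=s).fit()
        sel = {f for f in fit.selected if f not in ("age", "sex")}
        exact += sel == truth
        contained += truth <= sel
    return {
        "exact_rate": exact / n_seeds,
        "containment_rate": contained / n_seeds,
        "n_seeds": n_seeds,
    }


def offtarget_misclassification(
    n_panel_markers: int,
    contamination: float,
    seed: int = 0,
) -> dict:
    """Misclassification rate of a frozen panel on non-colorectal tumors.

    A panel of ``n_panel_markers`` well-separated markers is fitted on
    a synthetic validation cohort, frozen at its LOOCV Youden cutoff,
    and applied to 16 tumor sera generated with the given contaminated
    fraction sitting in the AN region.
    """
    cohort = synth_mod.generate_cohort(seed=seed)
    va = cohort.subset(cohort.df["cohort"] == "validation")
    probes = [f"cg{i:06d}" for i in range(n_panel_markers)]
    plan = synth_mod.make_marker_plan(
        probes, n_planted=n_panel_markers, effect_range=(0.28, 0.35), frac_hyper=0.5,
        seed=seed + 1,
    )
    meth = synth_mod.generate_methylome(va, plan, seed=seed + 2)
    markers = {f"CG{i + 1}": p for i, p in enumerate(probes)}
    pyro = synth_mod.simulate_pyrosequencing(meth, markers, seed=seed + 3)
    design = build_design(pyro, va, transform="log10", include_age_sex=False)
    X, y = design.X, design.y
    scores = loocv_scores(X, y)
    rep = diagnostic_report(scores, y.to_numpy())
    fitted = PanelLogit(X, y).fit()
    off = synth_mod.generate_offtarget_and_paired(
        plan, markers, contamination=contamination, seed=seed + 4
    )
    feats = design.transform_new(off.tumor_pyro.wide(), list(X.columns))
    result = evaluate_offtarget(fitted, feats, cutoff=rep["youden_cutoff"],
                                tumor_types=off.tumor_types)
    result["auc"] = rep["auc"]
    return result


def ebayes_prior_recovery(
    d0_true: float = 4.0,
    s0_sq_true: float = 0.01,
    n_probes: int = 1000,
    n_samples: int = 28,
    seed: int = 0,
) -> dict:
    """Recover the moderation prior from data generated under it.

    True per-probe variances follow a scaled inverse chi-square
    (d0, s0^2); Gaussian samples give observed s^2 with n - 2 residual
    df (two-group design), from which the moment estimator is run.
    """
    from .dmp import estimate_prior

    rng = np.random.default_rng(seed)
    sigma2 = d0_true * s0_sq_true / rng.chisquare(d0_true, size=n_probes)
    d = n_samples - 2
    s2 = sigma2 * rng.chisquare(d, size=n_probes) / d
    prior = estimate_prior(s2, float(d))
    return {"d0": prior.d0, "s0_sq": prior.s0_sq, "d0_true": d0_true, "s0_sq_true": s0_sq_true}
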