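"""End-to-end orchestration of the three-phase biomarker pipeline.

Discovery (synthetic cohort -> pools -> differential methylation ->
enrichment -> SES/CV prioritization), evaluation (pyrosequencing of
candidates on the 48-sample cohort -> penalized panel selection) and
validation (logistic panel fits on the 105-sample cohort -> LOOCV ROC,
Youden cutoff, confusion metrics, subgroup rates, off-target tumors,
serum/plasma comparison).  Each stage draws its own substream seed
from the master seed, so reruns of a stage are independent of the
others and the whole run is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from . import dmp as dmp_mod
from . import enrich as enrich_mod
from . import panels as panels_mod
from . import prioritize as prio_mod
from . import synth as synth_mod
from . import valstats as val_mod
from .io import ProbeAnnotation, RunConfig, ValidationError

__all__ = ["run_pipeline", "DEFAULT_SYNTH"]

# Study-condition defaults for the generator, scaled to a desk-size
# probe universe (the probe count is a knob, not a constant).
DEFAULT_SYNTH = {
    "n_probes": 20000,
    "n_planted": 200,
    "effect_range": (0.10, 0.30),
    "frac_hyper": 0.867,
    "precision": 50.0,
    "n_rrbs_concordant": 8,
    "rrbs_min_diff": 0.30,
    "n_tumors": 16,
    "contamination": 3 / 16,
    "n_pairs": 8,
}

STAGES = ("discovery", "evaluation", "validation")


def run_pipeline(config: RunConfig, out_dir=None, stages=STAGES) -> dict:
    """Run the configured stages in order and return the consolidated report.

    Stages must be a prefix of (discovery, evaluation, validation);
    disabling a later stage yields a partial report.  When ``out_dir``
    is given, intermediate artifacts (cohort sheet, pool assignments,
    DMP table, candidate list, panels, report JSON) are persisted
    there in the standard text formats.
    """
    stages = tuple(stages)
    if stages != STAGES[: len(stages)]:
        raise ValidationError(f"stages must be a prefix of {STAGES}, got {stages}")
    syn = {**DEFAULT_SYNTH, **(config.synth or {})}
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(stages)}

    # ------------------------------------------------------------------ setup
    cohort = synth_mod.generate_cohort(seed=config.stage_seed("cohort"))
    probe_ids = [f"cg{i:08d}" for i in range(int(syn["n_probes"]))]
    plan = synth_mod.make_marker_plan(
        probe_ids,
        n_planted=int(syn["n_planted"]),
        effect_range=tuple(syn["effect_range"]),
        frac_hyper=float(syn["frac_hyper"]),
        precision=float(syn["precision"]),
        seed=config.stage_seed("plan"),
    )
    noise = synth_mod.NoiseModel()
    if out:
        cohort.to_csv(out / "cohort.csv")

    # -------------------------------------------------------------- discovery
    disc = cohort.subset(cohort.df["cohort"] == "discovery")
    methylome = synth_mod.generate_methylome(disc, plan, seed=config.stage_seed("methylome"))
    pools = design_mod.build_pools(disc, seed=config.stage_seed("pools"))
    pools = design_mod.assign_to_slides(pools, slide_capacity=8, seed=config.stage_seed("slides"))
    f_stat, f_df, f_p = design_mod.check_pool_age_balance(pools, disc)
    pool_beta = synth_mod.simulate_array_pools(methylome, pools, noise, seed=config.stage_seed("array"))
    pool_classes = pd.Series({p.pool_id: p.cls for p in pools})

    model = dmp_mod.DifferentialMethylation(pool_beta, pool_classes)
    dmp_res = model.fit(qc=True, shapiro_alpha=config.shapiro_alpha)
    calls = dmp_res.call_dmps(fdr=config.fdr)

    annotation = ProbeAnnotation(
        synth_mod.generate_annotation(probe_ids, seed=config.stage_seed("annotation"))
    )
    enrichment = enrich_mod.enrichment_table(
        calls.table, annotation, background_probes=list(dmp_res.table.index)
    )

    dmp_probes = list(calls.table.index)
    X_pools = pool_beta.values.loc[dmp_probes].T
    sigs = prio_mod.ses_select(X_pools, pool_classes.reindex(X_pools.index),
                               alpha=config.ses_alpha, max_k=config.ses_max_k)
    # rank every probe the signatures cover, topped up with singleton
    # signatures for the strongest uncovered DMPs so the candidate list
    # always has enough ranked probes to draw from
    covered = {p for sig in sigs.signatures for p in sig}
    by_effect = calls.table["delta_beta"].abs().sort_values(ascending=False).index
    extra = [(p,) for p in by_effect if p not in covered][: max(0, 40 - len(covered))]
    all_sigs = list(sigs.signatures) + extra
    ranked = prio_mod.cv_rank_candidates(
        all_sigs, X_pools, pool_classes.reindex(X_pools.index),
        delta_beta=calls.table["delta_beta"], q=calls.table["q"],
        folds=config.cv_folds, repeats=config.cv_repeats,
        rf_trees=config.rf_trees, seed=config.stage_seed("cvrank"),
    )
    fine = pd.Series(
        {p.pool_id: ("AA" if p.group in ("P-AA", "D-AA") else ("NN" if p.cls == "NN" else "CRC"))
         for p in pools}
    ).reindex(X_pools.index)
    aa_zero = prio_mod.aa_zero_error_probes(
        X_pools, fine, [p for p in ranked["probe_id"] if p not in set(ranked.head(15)["probe_id"])],
        folds=min(config.cv_folds, 5), repeats=2, seed=config.stage_seed("aazero"),
    )
    rrbs = synth_mod.generate_rrbs_table(
        plan, n_concordant=int(syn["n_rrbs_concordant"]),
        min_diff=float(syn["rrbs_min_diff"]), seed=config.stage_seed("rrbs"),
    )
    rrbs_set = prio_mod.rrbs_concordance_filter(dmp_res.table, rrbs, min_diff=float(syn["rrbs_min_diff"]))
    candidates = prio_mod.select_candidates(ranked, n_top=15, aa_zero_error=aa_zero, rrbs_set=rrbs_set)

    report["discovery"] = {
        "n_subjects": len(disc),
        "n_pools": len(pools),
        "pools_nn": sum(p.cls == "NN" for p in pools),
        "pools_an": sum(p.cls == "AN" for p in pools),
        "pool_age_anova": {"F": f_stat, "df": list(f_df), "p": f_p},
        "probes_tested": len(dmp_res.table),
        "dmp": calls.summary(),
        "n_signatures": len(sigs),
        "signature_size": sigs.size,
        "n_candidates": len(candidates),
        "candidate_sources": candidates["source"].value_counts().to_dict(),
        "enriched_categories": int(enrichment["enriched"].sum()),
    }
    if out:
        design_mod.pools_to_frame(pools).to_csv(out / "pools.csv", index=False)
        dmp_res.table.to_csv(out / "dmp.tsv", sep="\t")
        candidates.to_csv(out / "candidates.csv", index=False)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if "evaluation" not in stages:
        return _finish(report, out)

    # ------------------------------------------------------------- evaluation
    markers = {f"CG{i + 1}": pid for i, pid in enumerate(candidates["probe_id"])}
    ev = cohort.subset(cohort.df["cohort"] == "evaluation")
    ev_meth = synth_mod.generate_methylome(ev, plan, seed=config.stage_seed("eval_meth"))
    ev_pyro = synth_mod.simulate_pyrosequencing(ev_meth, markers, noise, seed=config.stage_seed("eval_pyro"))
    design = panels_mod.build_design(ev_pyro, ev, transform=config.transform)
    lasso = panels_mod.PenalizedPanelSelector(
        design, penalty="lasso", n_lambda=config.n_lambda, seed=config.stage_seed("lasso")
    ).fit()
    enet = panels_mod.PenalizedPanelSelector(
        design, penalty="elastic_net", l1_ratio=config.enet_l1_ratio,
        n_lambda=config.n_lambda, seed=config.stage_seed("enet"),
    ).fit()
    panel_defs = panels_mod.derive_panels(lasso, enet, enet)
    report["evaluation"] = {
        "n_subjects": len(ev),
        "lasso_selected": lasso.selected,
        "enet_selected": enet.selected,
        "panels": {k: v for k, v in panel_defs.items() if k != "containment"},
        "containment": panel_defs["containment"],
    }
    if out:
        ev_pyro.to_csv(out / "evaluation_pyro.csv")
        (out / "panels.json").write_text(json.dumps(report["evaluation"], indent=2, default=str))
    if "validation" not in stages:
        return _finish(report, out)

    # ------------------------------------------------------------- validation
    va = cohort.subset(cohort.df["cohort"] == "validation")
    va_meth = synth_mod.generate_methylome(va, plan, seed=config.stage_seed("val_meth"))
    va_pyro = synth_mod.simulate_pyrosequencing(va_meth, markers, noise, seed=config.stage_seed("val_pyro"))
    va_design = panels_mod.build_design(va_pyro, va, transform=config.transform)
    val_block: dict = {"n_subjects": len(va), "panels": {}}
    panel_feature_sets = {
        "sparse_lasso": panel_defs["sparse_lasso"]["markers"],
        "sparse_enet": panel_defs["sparse_enet"]["markers"],
        "large_enet": panel_defs["large_enet"]["markers"]
        + (["sex"] if panel_defs["large_enet"]["with_sex"] else []),
    }
    offtarget = synth_mod.generate_offtarget_and_paired(
        plan, markers, noise,
        n_tumors=int(syn["n_tumors"]), contamination=float(syn["contamination"]),
        n_pairs=int(syn["n_pairs"]), seed=config.stage_seed("offtarget"),
    )
    for name, feats in panel_feature_sets.items():
        feats = [f for f in feats if f in va_design.X.columns]
        if not feats:
            val_block["panels"][name] = {"skipped": "no features selected"}
            continue
        X = va_design.X[feats]
        y = va_design.y.to_numpy()
        scores = val_mod.loocv_scores(X, y)
        rep = val_mod.diagnostic_report(scores, y, cohort_df=va.df)
        fitted = val_mod.PanelLogit(X, y).fit()
        marker_feats = [f for f in feats if f != "sex"]
        if marker_feats:
            tum_raw = offtarget.tumor_pyro.wide()[marker_feats]
            tum_X = va_design.transform_new(tum_raw, marker_feats)
            if "sex" in feats:
                tum_X["sex"] = 0.0
            rep["offtarget"] = val_mod.evaluate_offtarget(
                fitted, tum_X, cutoff=rep["youden_cutoff"], tumor_types=offtarget.tumor_types
            )
        val_block["panels"][name] = rep
    serum = offtarget.serum_pyro.wide()
    plasma = offtarget.plasma_pyro.wide()
    val_block["serum_vs_plasma_p"] = {
        m: val_mod.group_tests(serum[m].to_numpy(), plasma[m].to_numpy(), paired=True)
        for m in list(serum.columns)[:4]
    }
    report["validation"] = val_block
    if out:
        va_pyro.to_csv(out / "validation_pyro.csv")
    return _finish(report, out)


def _finish(report: dict, out: Path | None) -> dict:
    if out:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        (out / "report.json").write_text(json.dumps(report, indent=2, default=_default) + "\n")
    return report
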