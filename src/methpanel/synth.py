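"""Synthetic cohorts, methylomes, pools and pyrosequencing readouts.

The generator emulates the data a serum cfDNA methylation screening
study produces: a multicenter cohort of colonoscopy-classified
subjects (ages 50-75), individual-level beta-value methylomes with a
configurable set of planted differentially methylated positions
(hyper- or hypomethylated in advanced neoplasia), 10-member
sex-balanced cfDNA pools measured with array-like noise, targeted
pyrosequencing percent-methylation readouts concordant with the array,
an external bisulfite-sequencing differential table, non-colorectal
tumor sera, and matched serum/plasma pairs.

Individual betas are drawn from beta distributions parameterized by
(mean, precision); planted effects are added on the mean (beta) scale.
Array noise acts on the logit scale so values stay inside (0, 1)
without distorting boundary-adjacent effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import PoolSpec
from .io import BetaMatrix, CohortTable, PyroTable, ValidationError

__all__ = [
    "CohortConfig",
    "MarkerPlan",
    "NoiseModel",
    "OfftargetData",
    "TABLE1_COMPOSITION",
    "generate_cohort",
    "make_marker_plan",
    "generate_methylome",
    "simulate_array_pools",
    "simulate_pyrosequencing",
    "generate_rrbs_table",
    "generate_offtarget_and_paired",
    "generate_annotation",
]

# Default cohort composition: one row per (cohort, finding, location, stage)
# cell with its subject count, mirroring the study's three sub-cohorts
# (discovery n=280, evaluation n=48, validation n=105).
TABLE1_COMPOSITION: tuple[dict, ...] = (
    # --- discovery (280 = 130 NN + 150 AN) ---
    {"cohort": "discovery", "finding": "NCF", "count": 30},
    {"cohort": "discovery", "finding": "BEN_hemorrhoids", "count": 25},
    {"cohort": "discovery", "finding": "BEN_diverticula", "count": 25},
    {"cohort": "discovery", "finding": "NAA", "count": 50},
    {"cohort": "discovery", "finding": "AA", "location": "distal", "count": 50},
    {"cohort": "discovery", "finding": "AA", "location": "proximal", "count": 50},
    {"cohort": "discovery", "finding": "CRC", "stage": "I", "count": 16},
    {"cohort": "discovery", "finding": "CRC", "stage": "II", "count": 14},
    {"cohort": "discovery", "finding": "CRC", "stage": "III", "count": 14},
    {"cohort": "discovery", "finding": "CRC", "stage": "IV", "count": 6},
    # --- evaluation (48 = 21 NN + 27 AN) ---
    {"cohort": "evaluation", "finding": "NCF", "count": 7},
    {"cohort": "evaluation", "finding": "BEN_hemorrhoids", "count": 3},
    {"cohort": "evaluation", "finding": "BEN_diverticula", "count": 4},
    {"cohort": "evaluation", "finding": "NAA", "count": 7},
    {"cohort": "evaluation", "finding": "AA", "location": "distal", "count": 8},
    {"cohort": "evaluation", "finding": "AA", "location": "proximal", "count": 8},
    {"cohort": "evaluation", "finding": "CRC", "stage": "I", "count": 3},
    {"cohort": "evaluation", "finding": "CRC", "stage": "II", "count": 3},
    {"cohort": "evaluation", "finding": "CRC", "stage": "III", "count": 4},
    {"cohort": "evaluation", "finding": "CRC", "stage": "IV", "count": 1},
    # --- validation (105 = 39 NN + 66 AN: 23 D-AA, 19 P-AA, 24 CRC) ---
    {"cohort": "validation", "finding": "NCF", "count": 15},
    {"cohort": "validation", "finding": "BEN_hemorrhoids", "count": 8},
    {"cohort": "validation", "finding": "BEN_diverticula", "count": 5},
    {"cohort": "validation", "finding": "NAA", "count": 11},
    {"cohort": "validation", "finding": "AA", "location": "distal", "count": 23},
    {"cohort": "validation", "finding": "AA", "location": "proximal", "count": 19},
    {"cohort": "validation", "finding": "CRC", "stage": "I", "count": 8},
    {"cohort": "validation", "finding": "CRC", "stage": "II", "count": 8},
    {"cohort": "validation", "finding": "CRC", "stage": "III", "count": 2},
    {"cohort": "validation", "finding": "CRC", "stage": "IV", "count": 6},
)

_HOSPITALS = ("Ourense", "Barcelona", "Donostia", "Alicante")


@dataclass
class CohortConfig:
    """Composition and demographics for the synthetic cohort."""

    composition: tuple[dict, ...] = TABLE1_COMPOSITION
    hospitals: tuple[str, ...] = _HOSPITALS
    age_range: tuple[int, int] = (50, 75)


@dataclass
class NoiseModel:
    """Measurement noise scales for the three assay layers.

    array_logit_sd: sd of logit-scale perturbation of pool betas.
    pyro_percent_sd: sd (percentage points) of pyrosequencing readouts.
    plasma_offset_sd: sd of the zero-centered serum-to-plasma offset.
    """

    array_logit_sd: float = 0.10
    pyro_percent_sd: float = 8.0
    plasma_offset_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("array_logit_sd", "pyro_percent_sd", "plasma_offset_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class MarkerPlan:
    """Planted truth for the methylome generator.

    ``delta_beta`` is the true AN-minus-NN group mean difference on the
    beta scale at each planted probe; ``baseline_mean`` holds the NN
    group mean for every probe; ``precision`` is the beta-distribution
    precision (a+b) controlling between-subject dispersion.
    """

    planted_ids: tuple[str, ...]
    delta_beta: pd.Series  # indexed by planted id, signed
    baseline_mean: pd.Series  # indexed by all probe ids
    precision: float = 50.0
    frac_hyper: float = 0.867

    def __post_init__(self) -> None:
        missing = set(self.planted_ids) - set(self.baseline_mean.index)
        if missing:
            raise ValidationError(f"planted probes absent from baseline: {sorted(missing)[:5]}")
        d = self.delta_beta.reindex(list(self.planted_ids))
        if d.isna().any() or (d.abs() <= 0).any() or (d.abs() >= 1).any():
            raise ValidationError("planted |delta beta| must lie in (0, 1)")
        shifted = self.baseline_mean.reindex(list(self.planted_ids)) + d
        bad = shifted[(shifted <= 0) | (shifted >= 1)]
        if len(bad):
            raise ValidationError(
                f"effect pushes group mean outside (0,1) at probe {bad.index[0]!r}"
            )

    @property
    def directions(self) -> pd.Series:
        return self.delta_beta.map(lambda d: "hyper" if d > 0 else "hypo")


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortTable:
    """Draw a reproducible synthetic cohort with the configured composition.

    Category counts are exact; ages are uniform over the screening
    range; sexes are balanced within each (cohort, pathological group)
    stratum so pool construction is feasible by design.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for cell in config.composition:
        finding = cell["finding"]
        for _ in range(int(cell["count"])):
            rows.append(
                {
                    "cohort": cell.get("cohort", "unassigned"),
                    "finding": finding,
                    "location": cell.get(
                        "location", "none" if finding not in ("AA", "CRC") else "distal"
                    ),
                    "stage": cell.get("stage", "none" if finding != "CRC" else "I"),
                }
            )
    if not rows:
        df = pd.DataFrame(
            columns=[
                "subject_id", "sex", "age", "hospital", "finding",
                "aa_histology", "aa_dysplasia", "stage", "location", "cohort",
            ]
        )
        return CohortTable(df)
    df = pd.DataFrame(rows)
    lo, hi = config.age_range
    df["age"] = rng.integers(lo, hi + 1, size=len(df))
    df["hospital"] = rng.choice(list(config.hospitals), size=len(df))
    df["aa_histology"] = "none"
    df["aa_dysplasia"] = "none"
    aa = df["finding"] == "AA"
    df.loc[aa, "aa_histology"] = rng.choice(["TA", "TVA", "VA"], size=int(aa.sum()), p=[0.55, 0.35, 0.10])
    df.loc[aa, "aa_dysplasia"] = rng.choice(["LGD", "HGD"], size=int(aa.sum()), p=[0.9, 0.1])

    # sex-balance within (cohort, pooling-group) strata
    from .design import pathological_group

    df["sex"] = "male"
    group = df.apply(pathological_group, axis=1)
    for _, idx in df.groupby([df["cohort"], group], sort=True).groups.items():
        idx = np.asarray(list(idx))
        perm = rng.permutation(len(idx))
        half = len(idx) // 2
        df.loc[idx[perm[:half]], "sex"] = "female"
        df.loc[idx[perm[half:]], "sex"] = "male"
    df.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(df))])
    cols = [
        "subject_id", "sex", "age", "hospital", "finding",
        "aa_histology", "aa_dysplasia", "stage", "location", "cohort",
    ]
    return CohortTable(df[cols].copy())


def make_marker_plan(
    probe_ids: list[str],
    n_planted: int = 200,
    effect_range: tuple[float, float] = (0.10, 0.30),
    frac_hyper: float = 0.867,
    precision: float = 50.0,
    seed: int = 0,
) -> MarkerPlan:
    """Choose planted DMPs, their signed effects and per-probe baselines.

    Baselines mimic the bimodal beta-value landscape of methylation
    arrays; planted probes get baselines that leave room for the effect
    so group means never leave (0, 1).
    """
    if n_planted > len(probe_ids):
        raise ValidationError("more planted DMPs than probes")
    rng = np.random.default_rng(seed)
    probe_ids = list(probe_ids)
    # bimodal background: mostly near-0 or near-1, some intermediate
    comp = rng.choice(3, size=len(probe_ids), p=[0.42, 0.38, 0.20])
    base = np.where(
        comp == 0,
        rng.beta(2.0, 10.0, size=len(probe_ids)),
        np.where(comp == 1, rng.beta(10.0, 2.0, size=len(probe_ids)), rng.uniform(0.2, 0.8, size=len(probe_ids))),
    )
    base = np.clip(base, 0.05, 0.95)
    baseline = pd.Series(base, index=probe_ids)

    planted = list(rng.choice(probe_ids, size=n_planted, replace=False))
    n_hyper = int(round(frac_hyper * n_planted))
    signs = np.array([1.0] * n_hyper + [-1.0] * (n_planted - n_hyper))
    mags = rng.uniform(effect_range[0], effect_range[1], size=n_planted)
    delta = pd.Series(signs * mags, index=planted)
    # re-draw planted baselines so the shifted mean stays inside (0.02, 0.98)
    for pid in planted:
        d = delta[pid]
        if d > 0:
            baseline[pid] = rng.uniform(0.05, 0.98 - d)
        else:
            baseline[pid] = rng.uniform(0.02 - d, 0.95)
    return MarkerPlan(
        planted_ids=tuple(planted),
        delta_beta=delta,
        baseline_mean=baseline,
        precision=precision,
        frac_hyper=frac_hyper,
    )


def generate_methylome(
    cohort: CohortTable,
    plan: MarkerPlan,
    seed: int = 0,
) -> BetaMatrix:
    """Individual-level beta matrix for every subject in the cohort.

    Each subject's beta at probe j is Beta(m*phi, (1-m)*phi) with m the
    group mean: the baseline for NN subjects, baseline + delta at
    planted probes for AN subjects.  Non-planted probes have zero
    expected group difference by construction.
    """
    rng = np.random.default_rng(seed)
    probes = list(plan.baseline_mean.index)
    labels = cohort.labels.to_numpy()
    subject_ids = cohort.df["subject_id"].tolist()
    m_nn = plan.baseline_mean.to_numpy(dtype=float)
    m_an = m_nn.copy()
    pos = pd.Index(probes).get_indexer(list(plan.planted_ids))
    m_an[pos] = m_an[pos] + plan.delta_beta.to_numpy(dtype=float)
    for name, m in (("NN", m_nn), ("AN", m_an)):
        if ((m <= 0) | (m >= 1)).any():
            j = int(np.argmax((m <= 0) | (m >= 1)))
            raise ValidationError(f"{name} group mean outside (0,1) at probe {probes[j]!r}")
    phi = plan.precision
    values = np.empty((len(probes), len(subject_ids)))
    for cls, m in (("NN", m_nn), ("AN", m_an)):
        cols = np.where(labels == cls)[0]
        if len(cols) == 0:
            continue
        a = (m * phi)[:, None]
        b = ((1.0 - m) * phi)[:, None]
        values[:, cols] = rng.beta(a, b, size=(len(probes), len(cols)))
    values = np.clip(values, 1e-6, 1 - 1e-6)
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=subject_ids), level="individual")


def simulate_array_pools(
    individual: BetaMatrix,
    pools: list[PoolSpec],
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> BetaMatrix:
    """Pool-level beta matrix: member means plus logit-scale array noise.

    The pool value is the unweighted mean of the 10 member betas
    (equal cfDNA mass per member); with zero noise it is exact.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    cols = {}
    sample_index = pd.Index(individual.sample_ids)
    for p in pools:
        missing = [m for m in p.members if m not in sample_index]
        if missing:
            raise ValidationError(f"pool {p.pool_id}: member(s) not in beta matrix: {missing}")
        mean = individual.values[list(p.members)].mean(axis=1).to_numpy()
        if noise.array_logit_sd > 0:
            z = logit(np.clip(mean, 1e-6, 1 - 1e-6))
            z = z + rng.normal(0.0, noise.array_logit_sd, size=len(mean))
            mean = expit(z)
        cols[p.pool_id] = np.clip(mean, 1e-6, 1 - 1e-6)
    df = pd.DataFrame(cols, index=individual.probe_ids)
    return BetaMatrix(df, level="pool")


def simulate_pyrosequencing(
    individual: BetaMatrix,
    markers: dict[str, str] | list[str],
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> PyroTable:
    """Percent-methylation readouts for selected markers.

    ``markers`` maps marker names (e.g. ``CG3``) to probe ids, or is a
    list of probe ids used as their own marker names.  percent =
    100 * beta + truncated Gaussian noise, clipped to [0, 100]; exact
    when the noise scale is zero.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    if not isinstance(markers, dict):
        markers = {m: m for m in markers}
    unknown = [p for p in markers.values() if p not in individual.values.index]
    if unknown:
        raise ValidationError(f"unknown marker probe id(s): {unknown}")
    rows = []
    for marker, probe in markers.items():
        beta = individual.values.loc[probe].to_numpy(dtype=float)
        pct = 100.0 * beta
        if noise.pyro_percent_sd > 0:
            pct = pct + rng.normal(0.0, noise.pyro_percent_sd, size=len(pct))
        pct = np.clip(pct, 0.0, 100.0)
        for sid, v in zip(individual.sample_ids, pct):
            rows.append({"sample_id": sid, "marker_id": marker, "percent_methylation": v})
    return PyroTable(pd.DataFrame(rows))


def generate_rrbs_table(
    plan: MarkerPlan,
    n_concordant: int = 8,
    min_diff: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """External bisulfite-sequencing serum/tissue differential table.

    Exactly ``n_concordant`` planted CpGs receive a difference
    exceeding ``min_diff`` with the same sign as the planted array
    effect; the remaining planted CpGs get sub-threshold differences
    (random sign) so they fail the magnitude filter regardless of
    direction.
    """
    if not (0 < min_diff < 1):
        raise ValidationError(f"min_diff must lie in (0,1), got {min_diff}")
    if n_concordant > len(plan.planted_ids):
        raise ValidationError("n_concordant exceeds planted DMP count")
    rng = np.random.default_rng(seed)
    planted = list(plan.planted_ids)
    chosen = list(rng.choice(planted, size=n_concordant, replace=False)) if n_concordant else []
    rows = []
    for pid in planted:
        sign = np.sign(plan.delta_beta[pid])
        if pid in chosen:
            mag = min(min_diff + rng.uniform(0.02, 0.25), 0.95)
            diff = sign * mag
        else:
            flip = 1.0 if rng.random() < 0.5 else -1.0
            diff = flip * sign * rng.uniform(0.0, min_diff * 0.8)  # below threshold
        rows.append({"cpg_id": pid, "rrbs_diff": diff})
    return pd.DataFrame(rows)


@dataclass
class OfftargetData:
    """Non-colorectal tumor sera and matched serum/plasma pairs."""

    tumor_pyro: PyroTable
    tumor_types: pd.Series  # sample_id -> tumor type
    serum_pyro: PyroTable
    plasma_pyro: PyroTable
    contaminated_ids: tuple[str, ...]


_TUMOR_TYPES = ("lung", "breast", "kidney", "prostate", "ovarian")


def generate_offtarget_and_paired(
    plan: MarkerPlan,
    markers: dict[str, str],
    noise: NoiseModel | None = None,
    n_tumors: int = 16,
    contamination: float = 3 / 16,
    n_pairs: int = 8,
    seed: int = 0,
) -> OfftargetData:
    """Off-target tumor sera plus matched serum/plasma measurements.

    Tumor sera are drawn from the NN-like marker distribution except
    for a configurable contaminated fraction drawn from the AN-like
    region (these are the cases a colorectal panel would flag).  Plasma
    values equal serum values plus zero-centered offset noise.
    """
    noise = noise or NoiseModel()
    if not (0 <= contamination <= 1):
        raise ValidationError(f"contamination must lie in [0,1], got {contamination}")
    rng = np.random.default_rng(seed)
    n_contam = int(round(contamination * n_tumors))
    probes = list(markers.values())
    nn_pct = 100.0 * plan.baseline_mean.reindex(probes).to_numpy()
    delta = plan.delta_beta.reindex(probes).fillna(0.0).to_numpy()
    an_pct = np.clip(nn_pct + 100.0 * delta, 0.0, 100.0)

    def _draw(center: np.ndarray) -> np.ndarray:
        v = center + rng.normal(0.0, max(noise.pyro_percent_sd, 1e-9) / 2.0, size=len(center))
        return np.clip(v, 0.0, 100.0)

    tumor_rows, types = [], {}
    contam_ids = []
    for i in range(n_tumors):
        sid = f"T{i + 1:03d}"
        types[sid] = _TUMOR_TYPES[i % len(_TUMOR_TYPES)]
        contaminated = i < n_contam
        if contaminated:
            contam_ids.append(sid)
        vals = _draw(an_pct if contaminated else nn_pct)
        for m, v in zip(markers, vals):
            tumor_rows.append({"sample_id": sid, "marker_id": m, "percent_methylation": v})

    serum_rows, plasma_rows = [], []
    for i in range(n_pairs):
        sid = f"PAIR{i + 1:02d}"
        serum = _draw(nn_pct)
        if noise.plasma_offset_sd > 0:
            plasma = np.clip(serum + rng.normal(0.0, noise.plasma_offset_sd, size=len(serum)), 0, 100)
        else:
            plasma = serum.copy()
        for m, s, p in zip(markers, serum, plasma):
            serum_rows.append({"sample_id": sid, "marker_id": m, "percent_methylation": s})
            plasma_rows.append({"sample_id": sid, "marker_id": m, "percent_methylation": p})

    return OfftargetData(
        tumor_pyro=PyroTable(pd.DataFrame(tumor_rows)),
        tumor_types=pd.Series(types, name="tumor_type"),
        serum_pyro=PyroTable(pd.DataFrame(serum_rows)),
        plasma_pyro=PyroTable(pd.DataFrame(plasma_rows)),
        contaminated_ids=tuple(contam_ids),
    )


def generate_annotation(
    probe_ids: list[str],
    seed: int = 0,
    island_enriched: list[str] | None = None,
    island_frac_enriched: float = 0.5,
) -> pd.DataFrame:
    """Synthetic probe annotation with array-like category frequencies.

    Optionally plants an elevated CpG-island fraction in a probe subset
    (for enrichment-analysis exercises).  Returns a ProbeAnnotation-
    compatible DataFrame.
    """
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    islands = rng.choice(
        ["Island", "Shore", "Shelf", "OpenSea"], size=n, p=[0.20, 0.17, 0.10, 0.53]
    )
    genic = rng.choice(
        ["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic"],
        size=n,
        p=[0.12, 0.08, 0.10, 0.05, 0.40, 0.04, 0.21],
    )
    df = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, size=n)],
            "pos": rng.integers(1, 2_000_000, size=n),
            "gene_symbol": [f"GENE{g}" for g in rng.integers(1, max(n // 4, 2), size=n)],
            "island_relation": islands,
            "genic_feature": genic,
        }
    )
    if island_enriched:
        mask = df["probe_id"].isin(island_enriched)
        hits = rng.random(int(mask.sum())) < island_frac_enriched
        sub = df.loc[mask, "island_relation"].to_numpy()
        sub[hits] = "Island"
        df.loc[mask, "island_relation"] = sub
    return df
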