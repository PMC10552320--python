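"""Cohort splitting, cfDNA pool construction and slide allocation.

The discovery phase measures 10-member cfDNA pools (5 men + 5 women
from the same pathological group, age- and hospital-matched) rather
than individuals.  Pathological groups refine the NN/AN dichotomy:
NCF, BEN, NAA on the NN side; P-AA, D-AA, CRC stage I-II and CRC stage
III-IV on the AN side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable, ValidationError, derive_label

__all__ = [
    "PoolSpec",
    "pathological_group",
    "group_class",
    "stratified_split",
    "build_pools",
    "assign_to_slides",
    "check_pool_age_balance",
    "pools_to_frame",
]

POOL_SIZE = 10
_PER_SEX = POOL_SIZE // 2

NN_GROUPS = ("NCF", "BEN", "NAA")
AN_GROUPS = ("P-AA", "D-AA", "CRC_I-II", "CRC_III-IV")
GROUPS = NN_GROUPS + AN_GROUPS


@dataclass
class PoolSpec:
    """A 10-member cfDNA pool: 5 male + 5 female, one pathological group."""

    pool_id: str
    members: tuple[str, ...]
    group: str
    cls: str  # NN or AN
    slide: str | None = None

    def __post_init__(self) -> None:
        if len(self.members) != POOL_SIZE:
            raise ValidationError(
                f"pool {self.pool_id} has {len(self.members)} members, expected {POOL_SIZE}"
            )
        if len(set(self.members)) != POOL_SIZE:
            raise ValidationError(f"pool {self.pool_id} has duplicated members")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown pathological group {self.group!r}")
        if self.cls != group_class(self.group):
            raise ValidationError(f"pool {self.pool_id}: class {self.cls} does not match group")


def pathological_group(row: pd.Series) -> str:
    """Pooling group of a subject from finding, location and stage."""
    finding = row["finding"]
    if finding == "NCF":
        return "NCF"
    if finding in ("BEN_hemorrhoids", "BEN_diverticula"):
        return "BEN"
    if finding == "NAA":
        return "NAA"
    if finding == "AA":
        return "P-AA" if row["location"] == "proximal" else "D-AA"
    if finding == "CRC":
        return "CRC_I-II" if row["stage"] in ("I", "II") else "CRC_III-IV"
    raise ValidationError(f"unknown finding {finding!r}")


def group_class(group: str) -> str:
    return "NN" if group in NN_GROUPS else "AN"


def stratified_split(
    cohort: CohortTable,
    target_sizes: dict[str, int],
    strata: list[str] = ("finding", "sex"),
    seed: int = 0,
) -> CohortTable:
    """Assign unassigned subjects to cohorts by stratified random sampling.

    Allocation per stratum is proportional with largest-remainder
    rounding, so each target cohort hits its exact total while sex and
    finding proportions stay within one subject of the parent cohort's.
    Targets are drawn in the given order from the remaining pool.
    """
    df = cohort.df.copy()
    eligible = df.index[df["cohort"] == "unassigned"]
    total_target = sum(target_sizes.values())
    if total_target > len(eligible):
        raise ValidationError(
            f"targets sum to {total_target} but only {len(eligible)} unassigned subjects"
        )
    strata = list(strata)
    rng = np.random.default_rng(seed)
    remaining: dict[tuple, list] = {}
    for key, sub in df.loc[eligible].groupby(strata, sort=True):
        idx = list(sub.index)
        rng.shuffle(idx)
        remaining[key] = idx

    for cohort_name, target in target_sizes.items():
        n_rem = sum(len(v) for v in remaining.values())
        if target > n_rem:
            raise ValidationError(f"target {cohort_name}={target} exceeds remaining {n_rem}")
        keys = sorted(remaining, key=str)
        quotas = np.array([target * len(remaining[k]) / n_rem for k in keys])
        base = np.floor(quotas).astype(int)
        short = target - int(base.sum())
        # largest remainders get the leftover units
        order = np.argsort(-(quotas - base), kind="stable")
        alloc = base.copy()
        alloc[order[:short]] += 1
        for k, a in zip(keys, alloc):
            if a > len(remaining[k]):
                raise ValidationError(
                    f"stratum {k} too small: needs {a}, has {len(remaining[k])}"
                )
            take, remaining[k] = remaining[k][:a], remaining[k][a:]
            df.loc[take, "cohort"] = cohort_name
    return CohortTable(df)


def build_pools(
    cohort: CohortTable,
    groups: list[str] | None = None,
    seed: int = 0,
    pool_prefix: str = "POOL",
) -> list[PoolSpec]:
    """Partition eligible subjects into 10-member sex-balanced pools.

    Within each pathological group, males and females are sorted by
    age and dealt round-robin across the group's pools, so every pool
    receives a comparable spread of ages (mutually age-matched pools:
    a between-pool ANOVA on age stays null when members come from one
    age distribution).  Every eligible subject is used exactly once.
    """
    df = cohort.df.copy()
    df["_group"] = df.apply(pathological_group, axis=1)
    if groups is None:
        groups = [g for g in GROUPS if (df["_group"] == g).any()]
    pools: list[PoolSpec] = []
    counter = 1
    for group in groups:
        sub = df[df["_group"] == group]
        n = len(sub)
        if n % POOL_SIZE != 0:
            raise ValidationError(
                f"group {group}: {n} subjects is not a multiple of {POOL_SIZE}"
            )
        n_pools = n // POOL_SIZE
        males = sub[sub["sex"] == "male"].sort_values(["hospital", "age", "subject_id"])
        females = sub[sub["sex"] == "female"].sort_values(["hospital", "age", "subject_id"])
        need = n_pools * _PER_SEX
        if len(males) != need or len(females) != need:
            deficit = need - min(len(males), len(females))
            raise ValidationError(
                f"group {group}: needs {need} of each sex for {n_pools} pools "
                f"(5M+5F); short by {deficit}"
            )
        males = males.sort_values(["age", "subject_id"])
        females = females.sort_values(["age", "subject_id"])
        m_deal = [males.iloc[i::n_pools] for i in range(n_pools)]
        f_deal = [females.iloc[i::n_pools] for i in range(n_pools)]
        for mi in range(n_pools):
            members = tuple(sorted(m_deal[mi]["subject_id"]) + sorted(f_deal[mi]["subject_id"]))
            pools.append(
                PoolSpec(
                    pool_id=f"{pool_prefix}{counter:02d}",
                    members=members,
                    group=group,
                    cls=group_class(group),
                )
            )
            counter += 1
    return pools


def assign_to_slides(
    pools: list[PoolSpec],
    slide_capacity: int = 8,
    seed: int = 0,
    n_slides: int | None = None,
) -> list[PoolSpec]:
    """Randomized slide allocation with no group repeated on a slide.

    Groups are placed from most to least frequent, each pool going to
    the admissible slide with the most free positions (random
    tie-break), which is feasible whenever no group has more pools than
    there are slides.
    """
    counts = pd.Series([p.group for p in pools]).value_counts()
    if n_slides is None:
        # enough slides for the volume AND for the most frequent group
        n_slides = max(int(np.ceil(len(pools) / slide_capacity)), int(counts.max()))
    if (counts > n_slides).any():
        g = counts.idxmax()
        raise ValidationError(
            f"infeasible slide layout: group {g} has {counts.max()} pools but only "
            f"{n_slides} slide(s)"
        )
    if len(pools) > n_slides * slide_capacity:
        raise ValidationError("total pools exceed total slide capacity")
    rng = np.random.default_rng(seed)
    free = np.full(n_slides, slide_capacity)
    groups_on = [set() for _ in range(n_slides)]
    out: list[PoolSpec] = []
    order = sorted(range(len(pools)), key=lambda i: (-counts[pools[i].group], pools[i].pool_id))
    assignment: dict[int, int] = {}
    for i in order:
        p = pools[i]
        admissible = [s for s in range(n_slides) if free[s] > 0 and p.group not in groups_on[s]]
        if not admissible:
            raise ValidationError(f"no admissible slide for pool {p.pool_id}")
        cap = max(free[s] for s in admissible)
        best = [s for s in admissible if free[s] == cap]
        s = best[rng.integers(len(best))]
        free[s] -= 1
        groups_on[s].add(p.group)
        assignment[i] = s
    for i, p in enumerate(pools):
        out.append(PoolSpec(p.pool_id, p.members, p.group, p.cls, slide=f"SLIDE{assignment[i] + 1}"))
    return out


def check_pool_age_balance(pools: list[PoolSpec], cohort: CohortTable):
    """One-way ANOVA of member age across pools: (F, df, p)."""
    if len(pools) < 2:
        raise ValidationError("age-balance ANOVA needs at least 2 pools")
    ages = cohort.df.set_index("subject_id")["age"]
    groups = []
    for p in pools:
        a = ages.reindex(list(p.members))
        if a.isna().any():
            missing = list(a.index[a.isna()])
            raise ValidationError(f"pool {p.pool_id}: members not in cohort: {missing}")
        if len(a) < 2:
            raise ValidationError(f"pool {p.pool_id} has fewer than 2 members")
        groups.append(a.to_numpy(dtype=float))
    f, p = stats.f_oneway(*groups)
    k, n = len(groups), sum(len(g) for g in groups)
    return float(f), (k - 1, n - k), float(p)


def pools_to_frame(pools: list[PoolSpec]) -> pd.DataFrame:
    """Long-format serialization (pool_id, subject_id, group, class, slide)."""
    rows = [
        {"pool_id": p.pool_id, "subject_id": m, "group": p.group, "class": p.cls, "slide": p.slide}
        for p in pools
        for m in p.members
    ]
    return pd.DataFrame(rows)
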