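"""Annotation of DMPs and one-sided Fisher enrichment vs the array background.

Enrichment is tested per category (CpG-island relation and genic
feature), separately for all / hypermethylated / hypomethylated DMP
subsets, against the set of probes that survived QC.  The one-sided
Fisher test is the hypergeometric upper tail P[X >= k]; no
cross-category correction is applied (each category is flagged at
p < 0.05 on its own).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProbeAnnotation, ValidationError

__all__ = ["EnrichmentResult", "annotate_dmps", "fisher_enrichment", "enrichment_table"]

_AXES = {"island_relation": "island", "genic_feature": "genic"}


@dataclass
class EnrichmentResult:
    category: str
    subset: str  # all / hyper / hypo
    k: int  # DMPs in category
    n: int  # DMPs in subset
    K: int  # background in category
    N: int  # background total
    fold: float
    p: float

    @property
    def enriched(self) -> bool:
        return self.p < 0.05


def annotate_dmps(
    dmp_table: pd.DataFrame,
    annotation: ProbeAnnotation,
) -> pd.DataFrame:
    """Category counts and fractions per classification axis and subset.

    ``dmp_table`` must carry a ``direction`` column and be indexed by
    probe id.  Probes absent from the annotation are tallied under
    ``unannotated`` rather than dropped.  Within each axis and subset,
    fractions sum to 1.
    """
    if len(dmp_table) == 0:
        return pd.DataFrame(columns=["axis", "subset", "category", "count", "fraction"])
    ann = annotation.lookup(dmp_table.index)
    rows = []
    subsets = {
        "all": np.ones(len(dmp_table), dtype=bool),
        "hyper": (dmp_table["direction"] == "hyper").to_numpy(),
        "hypo": (dmp_table["direction"] == "hypo").to_numpy(),
    }
    for axis in _AXES:
        cats = ann[axis].fillna("unannotated").to_numpy()
        for subset, mask in subsets.items():
            total = int(mask.sum())
            if total == 0:
                continue
            counts = pd.Series(cats[mask]).value_counts()
            for cat, cnt in counts.items():
                rows.append(
                    {
                        "axis": axis,
                        "subset": subset,
                        "category": cat,
                        "count": int(cnt),
                        "fraction": cnt / total,
                    }
                )
    return pd.DataFrame(rows)


def fisher_enrichment(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Fold enrichment and one-sided (greater) Fisher exact p.

    Drawing n probes from a background of N containing K category
    members, the p-value is the hypergeometric upper tail P[X >= k].
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValidationError(f"inconsistent margins: k={k}, n={n}, K={K}, N={N}")
    if n == 0 or K == 0:
        return (np.nan if n == 0 else 0.0), 1.0
    fold = (k / n) / (K / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return fold, min(p, 1.0)


def enrichment_table(
    dmp_table: pd.DataFrame,
    annotation: ProbeAnnotation,
    background_probes: list[str],
) -> pd.DataFrame:
    """Per-category enrichment for all/hyper/hypo DMP subsets.

    The background defaults to the QC-surviving probe universe (pass
    the unfiltered manifest ids to test against the full array
    instead).
    """
    bg_ann = annotation.lookup(background_probes)
    N = len(background_probes)
    results: list[EnrichmentResult] = []
    subsets = {
        "all": dmp_table,
        "hyper": dmp_table[dmp_table["direction"] == "hyper"],
        "hypo": dmp_table[dmp_table["direction"] == "hypo"],
    }
    for axis in _AXES:
        bg_cats = bg_ann[axis].fillna("unannotated")
        for subset, sub in subsets.items():
            n = len(sub)
            if n == 0:
                continue
            sub_cats = annotation.lookup(sub.index)[axis].fillna("unannotated")
            for cat in sorted(bg_cats.unique()):
                K = int((bg_cats == cat).sum())
                k = int((sub_cats == cat).sum())
                fold, p = fisher_enrichment(k, n, K, N)
                results.append(
                    EnrichmentResult(category=f"{axis}:{cat}", subset=subset, k=k, n=n, K=K, N=N, fold=fold, p=p)
                )
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "subset": r.subset,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "fold": r.fold,
                "p": r.p,
                "enriched": r.enriched,
            }
            for r in results
        ]
    )
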