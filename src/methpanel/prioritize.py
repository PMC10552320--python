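"""Candidate biomarker prioritization from called DMPs.

Three stages narrow the DMP list to a candidate panel:

1. A statistically-equivalent-signatures (SES) search: forward
   conditional-inclusion by likelihood-ratio chi-square tests between
   nested logistic models, with a backward pruning pass.  At each
   inclusion, competing features whose substitution changes the
   deviance non-significantly are recorded as equivalents; the
   signature set is the cartesian product of the equivalence classes
   (multiple minimal, equally predictive feature sets).
2. Cross-validated ranking: every signature is scored by stratified
   k-fold misclassification under three learner families (logistic
   regression, random forest, linear SVM); each probe inherits the
   minimum error over signatures containing it and probes are ranked
   lexicographically by (error asc, |delta beta| desc, q asc).
3. Selection: the top-ranked probes, plus probes with zero
   cross-validated error on the harder NN-vs-AA subproblem, plus
   probes concordant with an external bisulfite-sequencing table
   (|difference| above a threshold, same direction as the array).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .io import ValidationError

__all__ = [
    "SignatureSet",
    "ses_select",
    "cv_rank_candidates",
    "aa_zero_error_probes",
    "rrbs_concordance_filter",
    "select_candidates",
]


@dataclass
class SignatureSet:
    """Equally-sized, statistically equivalent feature sets."""

    signatures: list[tuple[str, ...]]
    selected: tuple[str, ...]
    equivalence_classes: list[tuple[str, ...]]
    alpha: float
    notes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def size(self) -> int:
        return len(self.selected)


def _as_binary(y) -> np.ndarray:
    """Coerce NN/AN string labels (or numeric 0/1) to a float vector."""
    s = pd.Series(np.asarray(y))
    if not np.issubdtype(s.dtype, np.number):
        s = s.map({"NN": 0.0, "AN": 1.0})
        if s.isna().any():
            raise ValidationError("labels must be NN/AN or numeric 0/1")
    return s.to_numpy(dtype=float)


def _logistic_deviance(X: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Residual deviance of a logistic fit; flags penalized fallbacks.

    An (effectively) unpenalized fit is tried first; if separation
    drives coefficients to extremes, a ridge-penalized fit is used
    instead so the search never aborts.
    """
    if X.shape[1] == 0:
        p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        return -2.0 * (y.sum() * np.log(p) + (len(y) - y.sum()) * np.log(1 - p)), False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, max_iter=500, tol=1e-8)
        try:
            model.fit(X, y)
            fallback = bool(np.abs(model.coef_).max() > 30)
        except Exception:
            fallback = True
        if fallback:
            model = LogisticRegression(C=10.0, max_iter=1000)
            model.fit(X, y)
        prob = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    dev = -2.0 * float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    return dev, fallback


def ses_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    alpha: float = 0.05,
    max_k: int = 3,
    max_signatures: int = 256,
) -> SignatureSet:
    """Forward-backward conditional selection with equivalence recording.

    A candidate's score is its maximal likelihood-ratio p-value over
    all conditioning subsets of the selected set up to size ``max_k``
    (the max-min association heuristic of constraint-based selection):
    a feature must look associated marginally AND given the selected
    features.  Inclusion additionally requires clearing a per-step
    Bonferroni guard (alpha over the number of candidates tested),
    which keeps pure-noise features out.  Equivalence between the
    winner and a competitor is declared when both are individually
    significant at ``alpha`` and their same-size models differ in
    deviance by less than the chi-square(1) critical value at
    ``alpha``.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must lie in (0,1), got {alpha}")
    y = _as_binary(y)
    features = list(X.columns)
    arr = X.to_numpy(dtype=float)
    notes: list[str] = []
    selected: list[int] = []
    classes: list[list[int]] = []
    crit = stats.chi2.ppf(1 - alpha, df=1)

    _dev_cache: dict[tuple, float] = {}

    def dev_of(cols: list[int]) -> float:
        key = tuple(sorted(cols))
        if key not in _dev_cache:
            d, fb = _logistic_deviance(arr[:, list(key)], y)
            if fb:
                notes.append(f"penalized fallback fit for columns {[features[c] for c in key]}")
            _dev_cache[key] = d
        return _dev_cache[key]

    def max_cond_p(j: int) -> tuple[float, float]:
        """(max p over conditioning subsets, deviance given full S)."""
        worst = 0.0
        dev_full = np.nan
        subsets = [selected] if not selected else [[], selected]
        if len(selected) > 1:
            subsets += [[s] for s in selected]
        for S in subsets:
            cols = [c for c in S if c != j]
            lrt = max(dev_of(cols) - dev_of(cols + [j]), 0.0)
            p = stats.chi2.sf(lrt, df=1)
            worst = max(worst, p)
            if len(cols) == len(selected):
                dev_full = dev_of(cols + [j])
        return worst, dev_full

    while len(selected) < max(1, max_k):
        base_dev = dev_of(selected)
        candidates = [j for j in range(len(features)) if j not in selected]
        if not candidates:
            break
        devs = {}
        pvals = {}
        for j in candidates:
            pvals[j], devs[j] = max_cond_p(j)
        best = min(candidates, key=lambda j: (pvals[j], devs[j], j))
        if pvals[best] >= alpha / len(candidates):  # Bonferroni guard on inclusion
            break
        equiv = [
            j
            for j in candidates
            if pvals[j] < alpha and abs(devs[j] - devs[best]) < crit
        ]
        if best not in equiv:
            equiv.insert(0, best)
        selected.append(best)
        classes.append(sorted(set(equiv)))
        # backward pruning: drop earlier features that lost significance
        changed = True
        while changed and len(selected) > 1:
            changed = False
            full_dev = dev_of(selected)
            for s in list(selected[:-1]):
                reduced = [c for c in selected if c != s]
                lrt = max(dev_of(reduced) - full_dev, 0.0)
                if stats.chi2.sf(lrt, df=1) >= alpha:
                    pos = selected.index(s)
                    selected.pop(pos)
                    classes.pop(pos)
                    changed = True
                    break

    if not selected:
        return SignatureSet(signatures=[], selected=(), equivalence_classes=[], alpha=alpha, notes=notes)

    name_classes = [tuple(features[j] for j in cls) for cls in classes]
    signatures = []
    for combo in itertools.product(*name_classes):
        if len(set(combo)) == len(combo):
            signatures.append(tuple(sorted(combo)))
        if len(signatures) >= max_signatures:
            notes.append(f"signature enumeration capped at {max_signatures}")
            break
    signatures = sorted(set(signatures))
    return SignatureSet(
        signatures=signatures,
        selected=tuple(features[j] for j in selected),
        equivalence_classes=name_classes,
        alpha=alpha,
        notes=notes,
    )


def _learners(rf_trees: int, seed: int) -> dict:
    return {
        "logistic": LogisticRegression(max_iter=1000),
        "random_forest": RandomForestClassifier(n_estimators=rf_trees, random_state=seed),
        "svm": SVC(kernel="linear", C=1.0),
    }


def _cv_error(X: np.ndarray, y: np.ndarray, learner, folds: int, repeats: int, seed: int) -> float:
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    errs = []
    for train, test in cv.split(X, y):
        if len(np.unique(y[train])) < 2:
            raise ValidationError("a CV fold lost a class; re-stratify with fewer folds")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            learner.fit(X[train], y[train])
            pred = learner.predict(X[test])
        errs.append(float(np.mean(pred != y[test])))
    return float(np.mean(errs))


def cv_rank_candidates(
    signatures: SignatureSet | list[tuple[str, ...]],
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    delta_beta: pd.Series,
    q: pd.Series,
    folds: int = 5,
    repeats: int = 10,
    rf_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank probes by minimum cross-validated signature error.

    Every signature is scored under the three learner families; a
    probe's error is the minimum over all (signature, learner)
    combinations that include it.  Ties are broken by larger |delta
    beta|, then smaller q.
    """
    sigs = signatures.signatures if isinstance(signatures, SignatureSet) else list(signatures)
    if not sigs:
        raise ValidationError("no signatures to rank")
    yv = _as_binary(y)
    probe_err: dict[str, float] = {}
    sig_errors = []
    for si, sig in enumerate(sigs):
        Xs = X[list(sig)].to_numpy(dtype=float)
        errs = {}
        for name, learner in _learners(rf_trees, seed).items():
            errs[name] = _cv_error(Xs, yv, learner, folds, repeats, seed + si)
        best = min(errs.values())
        sig_errors.append({"signature": sig, **errs, "min_error": best})
        for probe in sig:
            probe_err[probe] = min(probe_err.get(probe, np.inf), best)
    rows = []
    for probe, err in probe_err.items():
        rows.append(
            {
                "probe_id": probe,
                "min_cv_error": err,
                "abs_delta_beta": abs(float(delta_beta.get(probe, np.nan))),
                "q": float(q.get(probe, np.nan)),
            }
        )
    ranked = pd.DataFrame(rows).sort_values(
        ["min_cv_error", "abs_delta_beta", "q", "probe_id"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked.attrs["signature_errors"] = pd.DataFrame(sig_errors)
    return ranked.reset_index(drop=True)


def aa_zero_error_probes(
    X: pd.DataFrame,
    fine_labels: pd.Series,
    candidates: list[str],
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    max_probes: int = 3,
) -> list[str]:
    """Probes with 0% cross-validated error on the NN-vs-AA subproblem.

    Single-probe logistic models are cross-validated on the NN and AA
    samples only; probes achieving exactly zero misclassification are
    returned (at most ``max_probes``, in candidate order).
    """
    mask = fine_labels.isin(["NN", "AA"]).to_numpy()
    yv = (fine_labels[mask] == "AA").astype(float).to_numpy()
    if yv.sum() < folds or (len(yv) - yv.sum()) < folds:
        folds = max(2, int(min(yv.sum(), len(yv) - yv.sum())))
    out = []
    for probe in candidates:
        Xs = X.loc[mask, [probe]].to_numpy(dtype=float)
        err = _cv_error(Xs, yv, LogisticRegression(max_iter=1000), folds, repeats, seed)
        if err == 0.0:
            out.append(probe)
        if len(out) >= max_probes:
            break
    return out


def rrbs_concordance_filter(
    fits: pd.DataFrame,
    rrbs_table: pd.DataFrame,
    min_diff: float = 0.30,
) -> list[str]:
    """CpGs whose external bisulfite-sequencing difference exceeds
    ``min_diff`` in magnitude with the same sign as the array effect."""
    merged = rrbs_table.merge(
        fits[["delta_beta"]], left_on="cpg_id", right_index=True, how="inner"
    )
    keep = (merged["rrbs_diff"].abs() > min_diff) & (
        np.sign(merged["rrbs_diff"]) == np.sign(merged["delta_beta"])
    )
    return sorted(merged.loc[keep, "cpg_id"].tolist())


def select_candidates(
    ranked: pd.DataFrame,
    n_top: int = 15,
    aa_zero_error: list[str] | None = None,
    rrbs_set: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the candidate panel with per-marker provenance.

    Union of the top-``n_top`` ranked probes, up to three zero-AA-error
    probes not already chosen, and the externally concordant set
    (deduplicated, first provenance wins).  The default layout is
    15 + 3 + 8 = 26 candidates.
    """
    if len(ranked) < n_top:
        raise ValidationError(f"only {len(ranked)} ranked probes, need {n_top}")
    rows: list[dict] = []
    seen: set[str] = set()

    def add(probe: str, source: str, rank=None, err=None, adb=None):
        if probe in seen:
            return
        seen.add(probe)
        rows.append(
            {
                "probe_id": probe,
                "source": source,
                "rank": rank,
                "min_cv_error": err,
                "abs_delta_beta": adb,
            }
        )

    for _, r in ranked.head(n_top).iterrows():
        add(r["probe_id"], "ses_top15", r["rank"], r["min_cv_error"], r["abs_delta_beta"])
    for probe in (aa_zero_error or [])[:3]:
        add(probe, "aa_zero_error")
    for probe in rrbs_set or []:
        add(probe, "rrbs_concordant")
    return pd.DataFrame(rows)
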