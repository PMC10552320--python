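"""Validation-phase modelling and diagnostic statistics.

A fixed marker panel is fitted by maximum-likelihood logistic
regression (with a bias-reduced Firth fit as the fallback under
separation), scored by leave-one-out cross-validation, and summarized
by the empirical ROC: AUC (trapezoid = Mann-Whitney with half-ties),
a DeLong 95% CI, the Youden-index cutoff (ties broken toward higher
specificity), and confusion metrics with exact Clopper-Pearson 95%
CIs.  Subgroup detection rates, distal-vs-proximal Fisher comparison,
Wilcoxon group tests, probe-set averaging and off-target tumor
evaluation round out the reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io import BetaMatrix, ValidationError

__all__ = [
    "PanelLogit",
    "PanelLogitResults",
    "ROCResult",
    "ConfusionMetrics",
    "loocv_scores",
    "roc_auc",
    "youden_cutoff",
    "confusion_metrics",
    "clopper_pearson",
    "subgroup_detection",
    "group_tests",
    "average_probe_set",
    "evaluate_offtarget",
    "diagnostic_report",
]


def _binary(y) -> np.ndarray:
    """NN/AN strings or numeric 0/1 to a float {0, 1} vector."""
    s = pd.Series(np.asarray(y))
    if not np.issubdtype(s.dtype, np.number):
        s = s.map({"NN": 0.0, "AN": 1.0})
        if s.isna().any():
            raise ValidationError("labels must be NN/AN or numeric 0/1")
    return s.to_numpy(dtype=float)


# --- logistic panel fits ----------------------------------------------------


def _add_const(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _irls_logit(X: np.ndarray, y: np.ndarray, firth: bool, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for logistic regression; Firth's hat-diagonal score
    adjustment when ``firth`` is set.  Returns (beta, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        XtWX = (X * W[:, None]).T @ X
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        score = X.T @ (y - mu)
        if firth:
            sqw = np.sqrt(W)
            H = (sqw[:, None] * X) @ XtWX_inv @ (X * sqw[:, None]).T
            h = np.diag(H)
            score = X.T @ (y - mu + h * (0.5 - mu))
        step = XtWX_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            return beta, XtWX_inv, True
    return beta, XtWX_inv, False


class PanelLogit:
    """Logistic regression of AN status on a fixed marker panel.

    ``X`` is a samples-x-features DataFrame (already transformed /
    standardized as desired); ``y`` is binary (1 = AN).  ``fit``
    performs plain maximum likelihood and switches to a bias-reduced
    Firth fit — flagged on the results — when separation drives the
    MLE to infinity.
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series | np.ndarray) -> None:
        self.X = X
        self.y = _binary(y)
        if len(self.X) != len(self.y):
            raise ValidationError("X and y lengths differ")
        counts = pd.Series(self.y).value_counts()
        if len(counts) < 2:
            raise ValidationError("both classes must be present")
        if min(counts) < X.shape[1] + 1:
            raise ValidationError("need n per class >= panel size + 1")
        Xc = _add_const(X.to_numpy(dtype=float))
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValidationError(
                f"collinear features: {X.columns[i]!r} and {X.columns[j]!r}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, panel: list[str], label_col: str = "label"):
        return cls(df[panel], df[label_col])

    def fit(self) -> "PanelLogitResults":
        Xc = _add_const(self.X.to_numpy(dtype=float))
        beta, cov, converged = _irls_logit(Xc, self.y, firth=False)
        separated = (not converged) or (np.abs(beta).max() > 20)
        if separated:
            beta, cov, _ = _irls_logit(Xc, self.y, firth=True)
        names = ["const"] + list(self.X.columns)
        return PanelLogitResults(
            model=self,
            params=pd.Series(beta, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            method="firth" if separated else "mle",
        )


@dataclass
class PanelLogitResults:
    """Fitted panel coefficients with standard errors and prediction."""

    model: PanelLogit
    params: pd.Series
    cov: pd.DataFrame
    method: str  # mle / firth

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.model.X.columns)].to_numpy(dtype=float)
        eta = _add_const(np.asarray(X, dtype=float)) @ self.params.to_numpy()
        return expit(eta)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "method": self.method}
        )


def loocv_scores(X: pd.DataFrame, y, fit_cls=PanelLogit) -> np.ndarray:
    """Leave-one-out out-of-fold probability for every sample."""
    yv = _binary(y)
    n = len(yv)
    if n < 10:
        raise ValidationError("LOOCV needs at least 10 samples")
    for cls_count in pd.Series(yv).value_counts().items():
        if cls_count[1] < 2:
            raise ValidationError("each class needs >= 2 samples for LOOCV")
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        res = fit_cls(X.iloc[mask], yv[mask]).fit()
        scores[i] = res.predict(X.iloc[[i]])[0]
    return scores


# --- ROC / Youden / confusion ----------------------------------------------


@dataclass
class ROCResult:
    points: pd.DataFrame  # threshold, sensitivity, specificity (sorted by threshold)
    auc: float
    auc_ci: tuple[float, float]
    youden_threshold: float = field(default=np.nan)
    youden_j: float = field(default=np.nan)
    sensitivity: float = field(default=np.nan)
    specificity: float = field(default=np.nan)


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float, alpha: float = 0.05) -> tuple[float, float]:
    """DeLong variance of the empirical AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC over all observed thresholds with AUC and DeLong CI.

    A sample is called positive when its score is >= the threshold.
    The AUC equals the Mann-Whitney statistic with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _binary(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present for a ROC curve")
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    rows = []
    for t in thresholds:
        pred = scores >= t
        rows.append(
            {
                "threshold": t,
                "sensitivity": float(np.mean(pred[labels == 1])),
                "specificity": float(np.mean(~pred[labels == 0])),
            }
        )
    points = pd.DataFrame(rows).sort_values("threshold").reset_index(drop=True)
    greater = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    auc = float((greater + 0.5 * ties) / (len(pos) * len(neg)))
    roc = ROCResult(points=points, auc=auc, auc_ci=_delong_ci(scores, labels, auc))
    t, sens, spec = youden_cutoff(roc)
    roc.youden_threshold, roc.sensitivity, roc.specificity = t, sens, spec
    roc.youden_j = sens + spec - 1.0
    return roc


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Threshold maximizing J = sens + spec - 1; ties favor specificity."""
    pts = roc.points
    j = pts["sensitivity"] + pts["specificity"] - 1.0
    best = j.max()
    tied = pts[np.isclose(j, best)]
    row = tied.sort_values(["specificity", "threshold"], ascending=[False, False]).iloc[0]
    return float(row["threshold"]), float(row["sensitivity"]), float(row["specificity"])


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval for k/n."""
    if n == 0:
        return (np.nan, np.nan)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    ppv: float | None
    sensitivity_ci: tuple | None
    specificity_ci: tuple | None
    npv_ci: tuple | None
    ppv_ci: tuple | None

    def as_dict(self, percent: bool = True) -> dict:
        s = 100.0 if percent else 1.0
        def f(x):
            return None if x is None else round(s * x, 10)
        def ci(x):
            return None if x is None else (f(x[0]), f(x[1]))
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": f(self.sensitivity), "specificity": f(self.specificity),
            "npv": f(self.npv), "ppv": f(self.ppv),
            "sensitivity_ci": ci(self.sensitivity_ci), "specificity_ci": ci(self.specificity_ci),
            "npv_ci": ci(self.npv_ci), "ppv_ci": ci(self.ppv_ci),
        }


def confusion_metrics(pred_labels, true_labels) -> ConfusionMetrics:
    """Confusion counts with exact Clopper-Pearson 95% CIs.

    Positive = AN.  A metric whose denominator is empty is reported as
    None (undefined), never propagated as NaN.
    """
    pred = _binary(pred_labels)
    true = _binary(true_labels)
    if len(pred) != len(true):
        raise ValidationError("prediction and truth lengths differ")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))

    def rate(k, n):
        return (None, None) if n == 0 else (k / n, clopper_pearson(k, n))

    sens, sens_ci = rate(tp, tp + fn)
    spec, spec_ci = rate(tn, tn + fp)
    npv, npv_ci = rate(tn, tn + fn)
    ppv, ppv_ci = rate(tp, tp + fp)
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, npv=npv, ppv=ppv,
        sensitivity_ci=sens_ci, specificity_ci=spec_ci, npv_ci=npv_ci, ppv_ci=ppv_ci,
    )


# --- subgroup and group-difference tests ------------------------------------


def subgroup_detection(pred_labels, cohort_df: pd.DataFrame) -> dict:
    """Detection rates by AA location and CRC stage, with the Fisher
    distal-vs-proximal comparison among AA cases.

    ``pred_labels`` must align with ``cohort_df`` rows; detection means
    the model called the subject AN.  Empty subgroups report None.
    """
    pred = _binary(pred_labels)
    df = cohort_df.reset_index(drop=True)

    def rate(mask) -> dict | None:
        n = int(mask.sum())
        if n == 0:
            return None
        k = int(pred[mask.to_numpy()].sum())
        return {"detected": k, "n": n, "rate": 100.0 * k / n}

    aa = df["finding"] == "AA"
    crc = df["finding"] == "CRC"
    out = {
        "aa": {
            "all": rate(aa),
            "distal": rate(aa & (df["location"] == "distal")),
            "proximal": rate(aa & (df["location"] == "proximal")),
        },
        "crc": {"all": rate(crc)},
    }
    for stage in ("I", "II", "III", "IV"):
        out["crc"][f"stage_{stage}"] = rate(crc & (df["stage"] == stage))
    d = out["aa"]["distal"]
    p = out["aa"]["proximal"]
    if d and p:
        table = [[d["detected"], d["n"] - d["detected"]], [p["detected"], p["n"] - p["detected"]]]
        out["aa"]["fisher_distal_vs_proximal_p"] = float(stats.fisher_exact(table)[1])
    return out


def group_tests(values, groups=None, paired: bool = False) -> float:
    """Wilcoxon rank-sum (unpaired) or signed-rank (paired) p-value.

    Rank-sum is exact for group sizes <= 25 without ties, otherwise the
    tie-corrected normal approximation.  Signed-rank drops zero
    differences per the standard convention; an all-tied comparison
    returns p = 1 with a warning.
    """
    if paired:
        a, b = np.asarray(values, dtype=float), np.asarray(groups, dtype=float)
        if len(a) != len(b):
            raise ValidationError("paired vectors must have equal length")
        diff = a - b
        if np.all(diff == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 1.0
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValidationError(f"rank-sum test needs exactly 2 groups, got {len(uniq)}")
    a = values[groups == uniq[0]]
    b = values[groups == uniq[1]]
    if np.all(values == values[0]):
        warnings.warn("all values tied; p = 1")
        return 1.0
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def average_probe_set(beta: BetaMatrix, probe_ids: list[str]) -> pd.Series:
    """Per-sample mean beta over the available probes of a set.

    Missing probes are skipped with a warning (e.g. the three promoter
    probes averaged for a single-gene score); all-missing is an error.
    """
    present = [p for p in probe_ids if p in beta.values.index]
    missing = sorted(set(probe_ids) - set(present))
    if not present:
        raise ValidationError(f"none of the probes present: {missing}")
    if missing:
        warnings.warn(f"probes missing from matrix, skipped: {missing}")
    return beta.values.loc[present].mean(axis=0)


def evaluate_offtarget(
    results: PanelLogitResults,
    features: pd.DataFrame,
    cutoff: float,
    tumor_types: pd.Series | None = None,
) -> dict:
    """Apply a frozen panel model to off-target tumor sera.

    ``features`` must be on the model's training feature scale.
    Reports the overall misclassification (called AN) count and rate,
    and a per-tumor-type breakdown when types are provided.
    """
    missing = [c for c in results.model.X.columns if c not in features.columns]
    if missing:
        raise ValidationError(f"unmeasured marker(s) for off-target samples: {missing}")
    complete = features.dropna(subset=list(results.model.X.columns))
    excluded = sorted(set(features.index) - set(complete.index))
    prob = results.predict(complete)
    called = prob >= cutoff
    out = {
        "n": int(len(complete)),
        "misclassified": int(called.sum()),
        "rate": 100.0 * float(called.mean()) if len(complete) else None,
        "excluded_samples": excluded,
    }
    if tumor_types is not None:
        per_type: dict[str, dict] = {}
        for ttype in sorted(tumor_types.unique()):
            ids = tumor_types.index[tumor_types == ttype]
            mask = complete.index.isin(ids)
            if mask.sum() == 0:
                continue
            per_type[ttype] = {
                "n": int(mask.sum()),
                "misclassified": int(called[mask].sum()),
            }
        out["by_type"] = per_type
    return out


def diagnostic_report(
    scores: np.ndarray,
    true_labels,
    cohort_df: pd.DataFrame | None = None,
) -> dict:
    """Full LOOCV diagnostic block: ROC, Youden cutoff, confusion, subgroups."""
    roc = roc_auc(scores, true_labels)
    pred = (np.asarray(scores, dtype=float) >= roc.youden_threshold).astype(int)
    cm = confusion_metrics(pred, _binary(true_labels))
    report = {
        "auc": roc.auc,
        "auc_ci": list(roc.auc_ci),
        "youden_cutoff": roc.youden_threshold,
        "youden_j": roc.youden_j,
        "confusion": cm.as_dict(),
    }
    if cohort_df is not None:
        report["subgroups"] = subgroup_detection(pred, cohort_df)
    return report
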