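"""Epigenome-wide differential methylation between AN and NN pools.

Per-probe linear models on the beta scale with empirical-Bayes
variance moderation, Benjamini-Hochberg FDR control and DMP calling.

The model is `beta_j ~ class (+ covariates)` fitted probe-by-probe by
least squares (pools are independent, so OLS is the GLS special case
used here).  Residual variances are shrunk toward a common prior
estimated by moment matching on log s^2 — the hierarchical model in
which true variances follow a scaled inverse chi-square with prior
degrees of freedom d0 and location s0^2.  The moderated statistic

    t~_j = delta_j / (s~_j * sqrt(v))    with
    s~_j^2 = (d0 * s0^2 + d_j * s_j^2) / (d0 + d_j)

is referred to a t distribution on d_j + d0 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, ValidationError

__all__ = [
    "EBayesPrior",
    "DifferentialMethylation",
    "DMPResults",
    "qc_filter_probes",
    "fit_probe_models",
    "ebayes_moderate",
    "bh_adjust",
    "call_dmps",
]


@dataclass
class EBayesPrior:
    """Prior degrees of freedom and variance of the moderation step."""

    d0: float  # may be inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError(f"prior df must be > 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValidationError(f"prior variance must be > 0, got {self.s0_sq}")


def qc_filter_probes(
    beta: BetaMatrix,
    labels: pd.Series,
    shapiro_alpha: float = 0.01,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Drop failed positions and probes violating residual normality.

    A probe is removed if any sample value is missing ("failed
    position") or if the Shapiro-Wilk test on its within-group
    residuals rejects at ``shapiro_alpha``.  Returns the filtered
    matrix and a removal log with reasons.
    """
    labels = labels.reindex(beta.sample_ids)
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 3).any():
        raise ValidationError("need at least 3 samples per class for per-probe models")
    values = beta.values
    removed: list[dict] = []
    failed = values.isna().any(axis=1)
    for pid in values.index[failed]:
        removed.append({"probe_id": pid, "reason": "failed position"})
    keep = values.loc[~failed]
    arr = keep.to_numpy(dtype=float)
    groups = [np.where((labels == g).to_numpy())[0] for g in counts.index]
    resid = arr.copy()
    for cols in groups:
        resid[:, cols] = arr[:, cols] - arr[:, cols].mean(axis=1, keepdims=True)
    ok = np.ones(len(keep), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(keep)):
            r = resid[i]
            if np.allclose(r, r[0]):
                continue  # constant residuals: nothing to test
            if stats.shapiro(r).pvalue < shapiro_alpha:
                ok[i] = False
                removed.append({"probe_id": keep.index[i], "reason": "non-normal residuals"})
    log = pd.DataFrame(removed, columns=["probe_id", "reason"])
    return BetaMatrix(keep.loc[ok], level=beta.level), log


def _design_matrix(labels: pd.Series, covariates: pd.DataFrame | None) -> tuple[np.ndarray, int]:
    """Intercept + AN indicator (+ covariates); returns (X, class column)."""
    cls = (labels == "AN").astype(float).to_numpy()
    cols = [np.ones_like(cls), cls]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    return X, 1


def fit_probe_models(
    beta: BetaMatrix,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe least-squares fits of the class contrast.

    Returns a frame with the class effect (delta beta, AN minus NN),
    residual variance s2, residual df, and the ordinary t statistic.
    Vectorized across probes; invariant to sample order.
    """
    labels = labels.reindex(beta.sample_ids)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    X, class_col = _design_matrix(labels, covariates)
    Y = beta.values.to_numpy(dtype=float)  # probes x samples
    n, p = X.shape
    d = n - p
    if d <= 0:
        raise ValidationError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T  # probes x p
    resid = Y - B @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / d
    v = XtX_inv[class_col, class_col]
    delta = B[:, class_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(s2 * v)
    return pd.DataFrame(
        {
            "probe_id": beta.probe_ids,
            "delta_beta": delta,
            "s2": s2,
            "df": float(d),
            "v": v,
            "t": t,
        }
    ).set_index("probe_id")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> EBayesPrior:
    """Moment-matching fit of the scaled inverse chi-square prior.

    Works on z = log s^2: under the hierarchical model z has mean
    digamma(d/2) - log(d/2) + log sigma^2 shifted by the prior, and
    excess variance trigamma(d0/2) beyond the sampling term
    trigamma(d/2); inverting the trigamma gives d0.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 2:
        raise ValidationError("need >= 2 probes with positive residual variance")
    z = np.log(s2[pos])
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(
    fits: pd.DataFrame,
    prior: EBayesPrior | None = None,
) -> tuple[EBayesPrior, pd.DataFrame]:
    """Shrink residual variances and compute moderated t and p values.

    If ``prior`` is given it is used as-is (useful for the d0 -> 0 and
    d0 -> inf limit checks); otherwise it is estimated from the
    ensemble of residual variances.
    """
    if np.all(fits["s2"].to_numpy() <= 1e-24):
        raise ValidationError("all residual variances are zero; moderation is degenerate")
    df = float(fits["df"].iloc[0])
    if prior is None:
        prior = estimate_prior(fits["s2"].to_numpy(), df)
    s2 = fits["s2"].to_numpy(dtype=float)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fits["delta_beta"].to_numpy() / np.sqrt(s2_post * fits["v"].to_numpy())
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = fits.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p"] = p
    out["q"] = bh_adjust(p)
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    return prior, out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DMPCalls:
    """Significant probes with direction labels and summary counts."""

    table: pd.DataFrame
    fdr: float

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def n_hyper(self) -> int:
        return int((self.table["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.table["direction"] == "hypo").sum())

    @property
    def pct_hyper(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.n_hyper / self.n_total

    def summary(self) -> dict:
        return {
            "fdr": self.fdr,
            "n_total": self.n_total,
            "n_hyper": self.n_hyper,
            "n_hypo": self.n_hypo,
            "pct_hyper": self.pct_hyper,
        }


def call_dmps(fits: pd.DataFrame, fdr: float = 0.10) -> DMPCalls:
    """Probes with q <= fdr, sorted by q then |effect| (order-invariant)."""
    if "q" not in fits.columns:
        raise ValidationError("fits must be moderated (missing q column)")
    sig = fits[fits["q"] <= fdr].copy()
    sig["_abs"] = sig["delta_beta"].abs()
    sig = sig.sort_index(kind="stable").sort_values(
        ["q", "_abs"], ascending=[True, False], kind="stable"
    )
    return DMPCalls(table=sig.drop(columns="_abs"), fdr=fdr)


class DifferentialMethylation:
    """Probe-wise differential methylation model on pool-level betas.

    Parameters
    ----------
    beta : BetaMatrix
        Pool- (or individual-) level methylation fractions.
    labels : pd.Series
        NN/AN class per sample, indexed by sample id.
    covariates : pd.DataFrame, optional
        Additional design columns (sample-indexed).
    """

    def __init__(
        self,
        beta: BetaMatrix,
        labels: pd.Series,
        covariates: pd.DataFrame | None = None,
    ) -> None:
        self.beta = beta
        self.labels = labels.reindex(beta.sample_ids)
        if self.labels.isna().any():
            raise ValidationError("labels missing for some samples")
        bad = set(self.labels.unique()) - {"NN", "AN"}
        if bad:
            raise ValidationError(f"labels must be NN/AN, got extra {sorted(bad)}")
        self.covariates = covariates

    @classmethod
    def from_cohort(cls, beta: BetaMatrix, cohort, pool_classes: pd.Series | None = None):
        if pool_classes is not None:
            return cls(beta, pool_classes)
        return cls(beta, cohort.labels.set_axis(cohort.df["subject_id"]))

    def fit(
        self,
        qc: bool = True,
        shapiro_alpha: float = 0.01,
        moderate: bool = True,
        prior: EBayesPrior | None = None,
    ) -> "DMPResults":
        beta = self.beta
        qc_log = pd.DataFrame(columns=["probe_id", "reason"])
        if qc:
            beta, qc_log = qc_filter_probes(beta, self.labels, shapiro_alpha)
        fits = fit_probe_models(beta, self.labels, self.covariates)
        fitted_prior = None
        if moderate:
            fitted_prior, fits = ebayes_moderate(fits, prior)
        return DMPResults(model=self, table=fits, prior=fitted_prior, qc_log=qc_log)


@dataclass
class DMPResults:
    """Fitted per-probe statistics with the moderation prior."""

    model: DifferentialMethylation
    table: pd.DataFrame
    prior: EBayesPrior | None
    qc_log: pd.DataFrame

    def call_dmps(self, fdr: float = 0.10) -> DMPCalls:
        return call_dmps(self.table, fdr=fdr)

    def summary(self, fdr: float = 0.10) -> pd.DataFrame:
        calls = self.call_dmps(fdr)
        rows = {
            "probes tested": len(self.table),
            "probes removed in QC": len(self.qc_log),
            f"DMPs at q <= {fdr:g}": calls.n_total,
            "hypermethylated": calls.n_hyper,
            "hypomethylated": calls.n_hypo,
            "% hypermethylated": round(calls.pct_hyper, 1) if calls.n_total else float("nan"),
            "prior df (d0)": None if self.prior is None else round(float(self.prior.d0), 3),
            "prior variance (s0^2)": None if self.prior is None else float(self.prior.s0_sq),
        }
        return pd.DataFrame({"value": rows})
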