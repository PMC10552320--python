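"""Evaluation-phase panel selection by penalized logistic regression.

Candidate pyrosequencing markers (plus age and sex) enter a LASSO or
elastic-net logistic regression; the penalty strength is chosen as the
minimizer of the mean cross-validated error along a log-spaced lambda
grid — misclassification error by default (ties resolved toward the
larger penalty, i.e. the sparser model), with binomial deviance as a
config alternative — and the nonzero coefficients at that lambda
define the panel.  Features are standardized before penalized fitting and the
scaling is retained so frozen models can be applied to new samples.

The log10 transform maps a percent x to log10(x + 1) so that zero
percent methylation (common in pyrosequencing of unmethylated
regions) maps to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import CohortTable, PyroTable, ValidationError

__all__ = [
    "DesignMatrix",
    "PenalizedFit",
    "PenalizedPanelSelector",
    "build_design",
    "derive_panels",
]


@dataclass
class DesignMatrix:
    """Standardized samples-x-features table with its scaling frozen."""

    X: pd.DataFrame  # standardized
    y: pd.Series  # 1 = AN, 0 = NN
    transform: str
    center: pd.Series
    scale: pd.Series
    raw: pd.DataFrame  # post-transform, pre-standardization
    dropped_samples: list = field(default_factory=list)
    dropped_features: list = field(default_factory=list)

    def transform_new(self, percent_wide: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
        """Apply the stored transform and scaling to new raw percents.

        ``percent_wide`` is samples x markers on the percent scale;
        non-marker features (age, sex) must already be columns if the
        requested feature list needs them.
        """
        features = features or [c for c in self.X.columns]
        out = {}
        for f in features:
            if f not in percent_wide.columns:
                raise ValidationError(f"feature {f!r} missing from new data")
            v = percent_wide[f].astype(float)
            if self.transform == "log10" and f not in ("age", "sex"):
                v = np.log10(v + 1.0)
            out[f] = (v - self.center[f]) / self.scale[f]
        return pd.DataFrame(out, index=percent_wide.index)


def build_design(
    pyro: PyroTable,
    cohort: CohortTable,
    transform: str = "log10",
    include_age_sex: bool = True,
) -> DesignMatrix:
    """Assemble the penalized-regression design from pyro measurements.

    Samples with any missing marker are dropped (and logged); features
    are marker percents (raw or log10(x+1)), age in years and a female
    indicator, each standardized to zero mean and unit variance.
    Zero-variance features are dropped with a warning.
    """
    if transform not in ("raw", "log10"):
        raise ValidationError(f"transform must be 'raw' or 'log10', got {transform!r}")
    wide = pyro.wide()
    meta = cohort.df.set_index("subject_id")
    wide = wide.reindex([s for s in wide.index if s in meta.index])
    dropped = sorted(set(pyro.df["sample_id"]) - set(wide.index))
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        dropped += incomplete
        wide = wide.drop(index=incomplete)
    if len(wide) == 0:
        raise ValidationError("no complete samples left for the design")
    feats = wide.astype(float).copy()
    if transform == "log10":
        feats = np.log10(feats + 1.0)
    if include_age_sex:
        feats["age"] = meta.loc[feats.index, "age"].astype(float)
        feats["sex"] = (meta.loc[feats.index, "sex"] == "female").astype(float)
    dropped_features = []
    for c in list(feats.columns):
        if feats[c].std(ddof=0) == 0:
            dropped_features.append(c)
            feats = feats.drop(columns=c)
            warnings.warn(f"dropping zero-variance feature {c!r}")
    center = feats.mean()
    scale = feats.std(ddof=0)
    X = (feats - center) / scale
    labels = meta.loc[feats.index, "finding"].map(
        lambda f: 1.0 if f in ("AA", "CRC") else 0.0
    )
    return DesignMatrix(
        X=X,
        y=labels.rename("y"),
        transform=transform,
        center=center,
        scale=scale,
        raw=feats,
        dropped_samples=dropped,
        dropped_features=dropped_features,
    )


@dataclass
class PenalizedFit:
    """A penalized logistic path with its CV-chosen operating point."""

    penalty: str  # lasso / elastic_net
    l1_ratio: float
    lambda_grid: np.ndarray
    cv_curve: np.ndarray  # mean CV deviance per lambda
    nonzero_path: np.ndarray  # nonzero count per lambda (descending lambda)
    lambda_opt: float
    coef: pd.Series  # at lambda_opt, original standardized scale
    intercept: float

    @property
    def selected(self) -> list[str]:
        return [f for f, c in self.coef.items() if c != 0.0]

    def summary(self) -> pd.DataFrame:
        sel = self.coef[self.coef != 0.0]
        return pd.DataFrame({"coefficient": sel}).assign(
            penalty=self.penalty, lambda_opt=self.lambda_opt
        )


class PenalizedPanelSelector:
    """LASSO / elastic-net logistic regression with CV-chosen penalty.

    Parameters
    ----------
    design : DesignMatrix
        Standardized features and binary outcome.
    penalty : {'lasso', 'elastic_net'}
    l1_ratio : float
        Elastic-net mixing parameter (ignored for the lasso).
    n_lambda : int
        Grid length, log-spaced from the smallest lambda that zeroes
        every coefficient down by three decades.
    folds : int
        Stratified CV folds for the error curve.
    loss : {'class', 'deviance'}
        CV loss defining the curve: mean misclassification at the 0.5
        cutoff, or mean binomial deviance.
    """

    def __init__(
        self,
        design: DesignMatrix,
        penalty: str = "lasso",
        l1_ratio: float = 0.5,
        n_lambda: int = 50,
        folds: int = 10,
        loss: str = "class",
        seed: int = 0,
    ) -> None:
        if penalty not in ("lasso", "elastic_net"):
            raise ValidationError(f"unknown penalty {penalty!r}")
        if loss not in ("class", "deviance"):
            raise ValidationError(f"unknown CV loss {loss!r}")
        self.design = design
        self.penalty = penalty
        self.l1_ratio = 1.0 if penalty == "lasso" else l1_ratio
        self.n_lambda = n_lambda
        self.folds = folds
        self.loss = loss
        self.seed = seed

    def _estimator(self, lam: float, n: int) -> LogisticRegression:
        C = 1.0 / (lam * n)
        if self.penalty == "lasso":
            return LogisticRegression(
                penalty="l1", C=C, solver="liblinear", max_iter=2000, random_state=0
            )
        return LogisticRegression(
            penalty="elasticnet",
            C=C,
            l1_ratio=self.l1_ratio,
            solver="saga",
            max_iter=5000,
            tol=1e-6,
        )

    def fit(self) -> PenalizedFit:
        X = self.design.X.to_numpy(dtype=float)
        y = self.design.y.to_numpy(dtype=float)
        n = len(y)
        counts = pd.Series(y).value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValidationError("need >= 2 samples per class")
        folds = min(self.folds, int(counts.min()))
        # lambda_max: smallest penalty that keeps all coefficients at zero
        lam_max = np.abs(X.T @ (y - y.mean())).max() / n
        lam_max = lam_max / max(self.l1_ratio, 1e-3)
        grid = np.geomspace(lam_max, lam_max * 1e-3, self.n_lambda)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.seed)
        dev = np.zeros((folds, len(grid)))
        ok = np.ones(len(grid), dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for fi, (tr, te) in enumerate(cv.split(X, y)):
                for li, lam in enumerate(grid):
                    if not ok[li]:
                        continue
                    try:
                        est = self._estimator(lam, len(tr)).fit(X[tr], y[tr])
                        p = np.clip(est.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
                        if self.loss == "class":
                            dev[fi, li] = float(np.mean((p >= 0.5) != (y[te] == 1)))
                        else:
                            dev[fi, li] = -2.0 * np.mean(
                                y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)
                            )
                    except Exception:
                        ok[li] = False
            if not ok.any():
                raise ValidationError("penalized path failed at every grid point")
            curve = dev.mean(axis=0)
            curve[~ok] = np.inf
            # grid is descending in lambda: the first minimizer is the
            # largest penalty attaining the minimum (sparsest model)
            li_opt = int(np.argmin(curve))
            lam_opt = float(grid[li_opt])
            nonzero = np.zeros(len(grid), dtype=int)
            full_coef = None
            intercept = 0.0
            for li, lam in enumerate(grid):
                if not ok[li]:
                    nonzero[li] = -1
                    continue
                est = self._estimator(lam, n).fit(X, y)
                nz = np.flatnonzero(np.abs(est.coef_[0]) > 1e-10)
                nonzero[li] = len(nz)
                if li == li_opt:
                    full_coef = est.coef_[0].copy()
                    full_coef[np.abs(full_coef) <= 1e-10] = 0.0
                    intercept = float(est.intercept_[0])
        coef = pd.Series(full_coef, index=self.design.X.columns)
        return PenalizedFit(
            penalty=self.penalty,
            l1_ratio=self.l1_ratio,
            lambda_grid=grid,
            cv_curve=curve,
            nonzero_path=nonzero,
            lambda_opt=lam_opt,
            coef=coef,
            intercept=intercept,
        )


def derive_panels(
    lasso_fit: PenalizedFit,
    enet_fit: PenalizedFit,
    enet_full_fit: PenalizedFit,
) -> dict:
    """Named marker panels from the three penalized fits.

    ``sparse_lasso`` and ``sparse_enet`` keep only methylation markers;
    ``large_enet`` keeps markers plus sex if selected.  A containment
    check (sparse panels inside the large panel) is reported as a
    warning when violated, never as an error — it is a data property.
    """
    def markers(fit: PenalizedFit) -> list[str]:
        return [f for f in fit.selected if f not in ("age", "sex")]

    panels = {
        "sparse_lasso": {"markers": markers(lasso_fit), "with_sex": "sex" in lasso_fit.selected},
        "sparse_enet": {"markers": markers(enet_fit), "with_sex": "sex" in enet_fit.selected},
        "large_enet": {
            "markers": markers(enet_full_fit),
            "with_sex": "sex" in enet_full_fit.selected,
        },
    }
    large = set(panels["large_enet"]["markers"])
    contained = set(panels["sparse_lasso"]["markers"]) <= large and set(
        panels["sparse_enet"]["markers"]
    ) <= large
    if not contained:
        warnings.warn("sparse panel markers are not all contained in the large panel")
    panels["containment"] = contained
    return panels
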