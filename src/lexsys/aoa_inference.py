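"""Statistical pipeline: transforms, nested OLS with delta-AIC, random-forest
regression, PCA disentanglement, correlations and simple slopes.

Conventions
-----------
- Box-Cox lambda is chosen by maximising the profile log-likelihood over the
  grid ``linspace(-3, 3, 601)``; non-positive variables are shifted by
  ``max(0, 1e-6 - min(x))`` first, and the shift is recorded for reuse.
- The response is never transformed; only independent variables are.
- AIC comes from the Gaussian log-likelihood with the additive constant
  included (statsmodels convention). Only differences are meaningful, and
  ``delta_aic = AIC(base) - AIC(augmented)``: positive means the augmented
  model fits better.
- Interaction columns are products of the (already z-scored) main effects
  and are not re-standardised, keeping the simple-slopes algebra exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

__all__ = [
    "TransformSpec",
    "ModelFit",
    "ModelComparison",
    "RFFit",
    "PCAResult",
    "boxcox_z",
    "fit_linear",
    "compare",
    "run_nested_suite",
    "simple_slopes",
    "rf_regression",
    "pca_disentangle",
    "correlation_report",
]

BOXCOX_GRID = np.linspace(-3.0, 3.0, 601)
_SHIFT_EPS = 1e-6


@dataclass
class TransformSpec:
    """Per-variable Box-Cox + z-scoring parameters, for exact reapplication."""

    shifts: dict = field(default_factory=dict)
    lambdas: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for var in self.lambdas:
            x = out[var].to_numpy(dtype=np.float64) + self.shifts[var]
            if np.any(x <= 0):
                raise ValueError(
                    f"column {var!r} has non-positive values after the recorded shift"
                )
            t = _boxcox_transform(x, self.lambdas[var])
            out[var] = (t - self.means[var]) / self.sds[var]
        return out


def _boxcox_transform(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.log(x)
    return (x**lam - 1.0) / lam


def _boxcox_mle(x: np.ndarray, grid: np.ndarray = BOXCOX_GRID) -> float:
    """Grid argmax of the Box-Cox profile log-likelihood.

    Vectorised over the whole grid; agrees with per-lambda
    ``scipy.stats.boxcox_llf`` up to the llf's additive constant.
    """
    n = len(x)
    logx = np.log(x)
    logsum = logx.sum()
    nonzero = grid[grid != 0.0]
    powers = x[None, :] ** nonzero[:, None]
    t = (powers - 1.0) / nonzero[:, None]
    var = t.var(axis=1)
    llf_nz = (nonzero - 1.0) * logsum - (n / 2.0) * np.log(var)
    llf0 = -logsum - (n / 2.0) * np.log(logx.var())
    llf = np.empty(len(grid))
    llf[grid != 0.0] = llf_nz
    llf[grid == 0.0] = llf0
    return float(grid[int(np.argmax(llf))])


def boxcox_z(
    table: pd.DataFrame,
    variables: Sequence[str],
    lambdas: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, TransformSpec]:
    """Box-Cox then z-standardise the named columns.

    ``lambdas`` may force a lambda per variable (e.g. 1 for affine, 0 for
    log); otherwise lambda is estimated by grid maximum likelihood.
    """
    out = table.copy()
    spec = TransformSpec()
    for var in variables:
        x = out[var].to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"column {var!r} contains non-finite values")
        if np.ptp(x) == 0:
            raise ValueError(f"column {var!r} is constant; cannot standardise")
        shift = max(0.0, _SHIFT_EPS - float(x.min()))
        y = x + shift
        lam = (
            float(lambdas[var])
            if lambdas is not None and var in lambdas
            else _boxcox_mle(y)
        )
        t = _boxcox_transform(y, lam)
        mean = float(t.mean())
        sd = float(t.std(ddof=0))
        if sd == 0:
            raise ValueError(f"column {var!r} is constant after transformation")
        out[var] = (t - mean) / sd
        spec.shifts[var] = shift
        spec.lambdas[var] = lam
        spec.means[var] = mean
        spec.sds[var] = sd
    return out, spec


@dataclass
class ModelFit:
    response: str
    predictors: list[str]  # without the constant
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    aic: float
    llf: float
    n: int
    r2: float
    result: object = field(repr=False, default=None)

    def table(self) -> pd.DataFrame:
        """Coefficient table mirroring the usual beta/SE/t/p layout."""
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def _design(
    table: pd.DataFrame,
    predictors: Sequence[str],
    interactions: Sequence[tuple] = (),
) -> pd.DataFrame:
    X = table[list(predictors)].astype(np.float64).copy()
    for a, b in interactions:
        for name in (a, b):
            if name not in X.columns:
                raise ValueError(
                    f"interaction ({a}, {b}) requires main effect {name!r} "
                    "among the predictors"
                )
        X[f"{a}:{b}"] = table[a].to_numpy(np.float64) * table[b].to_numpy(np.float64)
    return X


def fit_linear(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    interactions: Sequence[tuple] = (),
) -> ModelFit:
    """OLS of ``response`` on ``predictors`` (+ product interaction terms)."""
    used = [response, *predictors] + [c for pair in interactions for c in pair]
    if table[list(dict.fromkeys(used))].isna().any().any():
        raise ValueError("missing values in columns used by the model")
    X = _design(table, predictors, interactions)
    Xc = sm.add_constant(X, has_constant="raise")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify aliased columns via the QR diagonal
        _, r = np.linalg.qr(Xc.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [
            Xc.columns[i]
            for i in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {bad}")
    y = table[response].to_numpy(dtype=np.float64)
    res = sm.OLS(y, Xc).fit()
    return ModelFit(
        response=response,
        predictors=list(X.columns),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        aic=float(res.aic),
        llf=float(res.llf),
        n=int(res.nobs),
        r2=float(res.rsquared),
        result=res,
    )


@dataclass
class ModelComparison:
    base: ModelFit
    augmented: ModelFit
    delta_aic: float

    @property
    def added(self) -> list[str]:
        return [p for p in self.augmented.predictors if p not in self.base.predictors]


def compare(base: ModelFit, augmented: ModelFit) -> ModelComparison:
    """delta_aic = AIC(base) - AIC(augmented); positive favours the augmented fit."""
    if not set(base.predictors) <= set(augmented.predictors):
        raise ValueError("base predictors must be a subset of augmented predictors")
    if base.n != augmented.n:
        raise ValueError(
            f"models fit on different row counts ({base.n} vs {augmented.n}); "
            "AIC values are not comparable"
        )
    return ModelComparison(base, augmented, float(base.aic - augmented.aic))


DEFAULT_CONTROLS = [
    "frequency",
    "concreteness",
    "length_phonemes",
    "valence",
    "morph_complex",
    "pnd",
    "snd",
]


def run_nested_suite(
    table: pd.DataFrame,
    response: str = "aoa",
    controls: Sequence[str] = tuple(DEFAULT_CONTROLS),
    te_column: str = "fsc_te",
    ld_column: str = "fsc_ld",
    iconicity_column: Optional[str] = None,
) -> dict[str, ModelComparison]:
    """The full ladder of nested comparisons, keyed by name.

    ``pnd_x_snd``  baseline vs + PND:SND interaction
    ``te``         baseline vs + target-embedding score
    ``ld``         baseline vs + edit-distance score
    ``snd_x_ld``   baseline vs + SND main/interaction with the ld score
    ``icon_ld``    (iconicity branch) baseline+iconicity vs + ld score,
                   restricted to rows where iconicity is present

    The table is expected analysis-ready: transformed predictors, no missing
    values outside the optional iconicity column.
    """
    controls = list(controls)
    out: dict[str, ModelComparison] = {}
    base = fit_linear(table, response, controls)

    aug = fit_linear(table, response, controls, interactions=[("pnd", "snd")])
    out["pnd_x_snd"] = compare(base, aug)

    if te_column is not None and te_column in table.columns:
        out["te"] = compare(base, fit_linear(table, response, controls + [te_column]))
    if ld_column is not None and ld_column in table.columns:
        out["ld"] = compare(base, fit_linear(table, response, controls + [ld_column]))
        out["snd_x_ld"] = compare(
            base,
            fit_linear(
                table,
                response,
                controls + [ld_column],
                interactions=[("snd", ld_column)],
            ),
        )

    if iconicity_column is not None:
        if iconicity_column not in table.columns:
            raise ValueError(
                f"iconicity branch requested but column {iconicity_column!r} is missing"
            )
        sub = table.dropna(subset=[iconicity_column])
        icon_base = fit_linear(sub, response, controls + [iconicity_column])
        icon_aug = fit_linear(sub, response, controls + [iconicity_column, ld_column])
        out["icon_ld"] = compare(icon_base, icon_aug)
    return out


def simple_slopes(
    fit: ModelFit,
    table: pd.DataFrame,
    predictor: str,
    moderator: str,
    quantiles: Sequence[float] = (0.05, 0.5, 0.95),
) -> pd.DataFrame:
    """Slope of ``predictor`` at sample quantiles of ``moderator``.

    ``slope(q) = beta_predictor + beta_interaction * moderator_q`` — exact
    because interactions are raw products of the model columns.
    """
    inter = f"{moderator}:{predictor}"
    if inter not in fit.params.index:
        inter = f"{predictor}:{moderator}"
    if inter not in fit.params.index:
        raise ValueError(
            f"fit has no {predictor} x {moderator} interaction term"
        )
    if predictor not in fit.params.index:
        raise ValueError(f"fit has no main effect for {predictor!r}")
    b_main = float(fit.params[predictor])
    b_int = float(fit.params[inter])
    qvals = np.quantile(table[moderator].to_numpy(dtype=np.float64), list(quantiles))
    return pd.DataFrame(
        {
            "quantile": list(quantiles),
            "moderator_value": qvals,
            "slope": b_main + b_int * qvals,
        }
    )


@dataclass
class RFFit:
    n_trees: int
    max_features: int
    importances: pd.Series
    oob_r2: float
    test_r2: float
    seed: int
    importance_mode: str


def rf_regression(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "permutation",
    test_size: float = 0.25,
    n_repeats: int = 5,
) -> RFFit:
    """Random-forest regression with a third of the variables per split.

    The forest is fit on a train split with out-of-bag scoring; variable
    importance is measured out-of-sample, by permuting each predictor on the
    held-out split (``importance='impurity'`` uses the in-training impurity
    decrease instead).
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("at least one predictor is required")
    if importance not in ("permutation", "impurity"):
        raise ValueError(f"unknown importance mode {importance!r}")
    X = table[predictors].to_numpy(dtype=np.float64)
    y = table[response].to_numpy(dtype=np.float64)
    max_features = max(1, len(predictors) // 3)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed
    )
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X_tr, y_tr)
    if importance == "permutation":
        imp = permutation_importance(
            forest, X_te, y_te, n_repeats=n_repeats, random_state=seed
        ).importances_mean
    else:
        imp = forest.feature_importances_
    return RFFit(
        n_trees=n_trees,
        max_features=max_features,
        importances=pd.Series(imp, index=predictors),
        oob_r2=float(forest.oob_score_),
        test_r2=float(forest.score(X_te, y_te)),
        seed=seed,
        importance_mode=importance,
    )


@dataclass
class PCAResult:
    variables: list[str]
    loadings: np.ndarray  # columns = components, rows = input variables
    explained_variance: np.ndarray  # eigenvalues, descending
    scores: pd.DataFrame  # per-row component scores (pc1, pc2, ...)

    @property
    def explained_shares(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


def pca_disentangle(
    table: pd.DataFrame,
    variables: Sequence[str] = ("pnd", "snd", "fsc_ld"),
    controls: Sequence[str] = (),
    response: str = "aoa",
) -> tuple[PCAResult, ModelFit]:
    """PCA on the correlation matrix of ``variables``; regress the response on
    the component scores plus ``controls``.

    Loadings carry a fixed sign convention: within each component, the
    largest-magnitude loading is positive. Explained variances sum to the
    number of (standardised) inputs.
    """
    variables = list(variables)
    Z = table[variables].to_numpy(dtype=np.float64)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
    corr = np.corrcoef(Z, rowvar=False)
    if np.linalg.matrix_rank(corr) < len(variables):
        raise ValueError("singular correlation matrix among the PCA inputs")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    names = [f"pc{j + 1}" for j in range(len(variables))]
    scores = pd.DataFrame(Z @ eigvecs, columns=names, index=table.index)
    result = PCAResult(
        variables=variables,
        loadings=eigvecs,
        explained_variance=eigvals,
        scores=scores,
    )
    work = pd.concat([table.reset_index(drop=True), scores.reset_index(drop=True)], axis=1)
    fit = fit_linear(work, response, list(controls) + names)
    return result, fit


def correlation_report(
    table: pd.DataFrame,
    variables: Sequence[str],
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Pairwise Pearson correlations with Fisher-z CIs, t statistics and p values.

    One row per unordered pair. Pairs with fewer than 3 complete observations
    are flagged (``ok = False``) with NaN statistics rather than dropped.
    """
    variables = list(variables)
    zcrit = scipy.stats.norm.ppf(0.5 + confidence / 2.0)
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            pair = table[[a, b]].dropna()
            n = len(pair)
            if n < 3:
                rows.append(
                    dict(var1=a, var2=b, n=n, r=np.nan, ci_low=np.nan,
                         ci_high=np.nan, t=np.nan, df=np.nan, p=np.nan, ok=False)
                )
                continue
            x = pair[a].to_numpy(dtype=np.float64)
            y = pair[b].to_numpy(dtype=np.float64)
            r = float(np.corrcoef(x, y)[0, 1])
            df = n - 2
            if abs(r) >= 1.0:
                t = np.inf * np.sign(r)
                p = 0.0
                lo = hi = r
            else:
                t = r * np.sqrt(df / (1.0 - r * r))
                p = 2.0 * scipy.stats.t.sf(abs(t), df)
                zr = np.arctanh(r)
                se = 1.0 / np.sqrt(n - 3)
                lo = float(np.tanh(zr - zcrit * se))
                hi = float(np.tanh(zr + zcrit * se))
            rows.append(
                dict(var1=a, var2=b, n=n, r=r, ci_low=lo, ci_high=hi,
                     t=float(t), df=df, p=float(p), ok=True)
            )
    return pd.DataFrame(rows)
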