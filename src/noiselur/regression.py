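"""Supervised stepwise variable selection for noise land-use regression.

The selection procedure, run on the candidate predictor grid against the
per-site ``L_den`` response, is:

1. *Univariate screen* — an ordinary least-squares fit of the response on
   each candidate alone.
2. *Best buffer per variable type* — within each type, keep the buffer with
   the highest univariate R² among those whose coefficient has the expected
   sign; a type with no correctly signed buffer is dropped.
3. *Forward selection* — candidates enter in decreasing order of univariate
   R²; a candidate is added only if its absolute Pearson correlation with
   every variable already in the model is below 0.7 **and** the adjusted R²
   strictly increases on refit.
4. *Backward pruning* — variables with p > 0.2 are removed one by one,
   largest p first, refitting after each removal.
5. *Challenge* — each retained variable is challenged, in model order, by
   every candidate of the full grid (any type, any buffer); the best
   replacement is accepted if it strictly improves the adjusted R², keeps
   all pairwise correlations below 0.7, and carries the expected sign.
6. *Final augmentation* — at most one additional variable is admitted if it
   improves the adjusted R², passes the correlation gate, and has p ≤ 0.2.

Every decision is logged to a replayable trace, and the whole pipeline is
deterministic: ties are broken by higher adjusted R², then smaller buffer,
then variable name.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .gis import FeatureMatrix
from .variables import CandidateVariable

__all__ = [
    "SelectionConfig",
    "RegressionFit",
    "UnivariateResult",
    "TraceEvent",
    "LURModel",
    "fit_ols",
    "univariate_screen",
    "select_best_buffer",
    "forward_selection",
    "backward_prune",
    "challenge_variables",
    "final_augment",
    "build_lur",
    "replay_trace",
    "exhaustive_subset_search",
    "LURRegressor",
    "RankDeficiencyError",
]


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns among {self.columns}")


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the selection procedure."""

    corr_threshold: float = 0.7
    p_remove: float = 0.2
    p_keep: float = 0.2


@dataclass
class RegressionFit:
    """An OLS fit with intercept on a chosen set of predictors."""

    variables: list[str]
    coefficients: pd.Series  # indexed by variable name
    intercept: float
    standard_errors: pd.Series
    p_values: pd.Series  # two-sided t tests, per coefficient
    r2: float
    adjusted_r2: float
    residuals: pd.Series
    fitted: pd.Series
    nobs: int

    def predict(self, X: pd.DataFrame) -> pd.Series:
        missing = set(self.variables) - set(X.columns)
        if missing:
            raise KeyError(f"missing predictor columns: {sorted(missing)}")
        vals = self.intercept + X[self.variables].to_numpy() @ self.coefficients.to_numpy()
        return pd.Series(vals, index=X.index)


@dataclass(frozen=True)
class UnivariateResult:
    """Single-predictor fit summary used by the screen."""

    variable: CandidateVariable
    coefficient: float
    r2: float
    sign_ok: bool


@dataclass(frozen=True)
class TraceEvent:
    """One logged decision of the selection pipeline."""

    action: str  # screened | buffer_chosen | added | rejected_correlation |
    # rejected_no_gain | removed_pvalue | challenged_swap | augmented |
    # type_dropped | not_augmented
    variable: str
    adj_r2_before: float
    adj_r2_after: float
    replaced: str | None = None
    note: str = ""


@dataclass
class LURModel:
    """Final fitted model, its selection trace, and the thresholds used."""

    fit: RegressionFit
    trace: list[TraceEvent]
    config: SelectionConfig
    screened: list[str] = field(default_factory=list)

    def to_dict(self, variables: dict[str, CandidateVariable] | None = None) -> dict:
        meta = {}
        if variables:
            for name in self.fit.variables:
                v = variables[name]
                meta[name] = {
                    "category": v.category,
                    "buffer_m": v.buffer_m,
                    "unit": v.unit,
                    "expected_sign": v.expected_sign,
                }
        return {
            "variables": self.fit.variables,
            "variable_metadata": meta,
            "coefficients": self.fit.coefficients.to_dict(),
            "intercept": self.fit.intercept,
            "standard_errors": self.fit.standard_errors.to_dict(),
            "p_values": self.fit.p_values.to_dict(),
            "r2": self.fit.r2,
            "adjusted_r2": self.fit.adjusted_r2,
            "n_sites": self.fit.nobs,
            "config": asdict(self.config),
            "trace": [asdict(e) for e in self.trace],
        }


def fit_ols(X: pd.DataFrame, y: pd.Series | np.ndarray) -> RegressionFit:
    """OLS with intercept; adjusted R² = 1 − (1−R²)(n−1)/(n−p−1)."""
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more sites than predictors + 1 (n={n}, p={p})")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise RankDeficiencyError(list(X.columns))
    res = sm.OLS(y, design).fit()
    if p == 0:
        r2, adj = 0.0, 0.0
    else:
        r2, adj = float(res.rsquared), float(res.rsquared_adj)
    coef = res.params.drop("const")
    return RegressionFit(
        variables=list(X.columns),
        coefficients=coef,
        intercept=float(res.params["const"]),
        standard_errors=res.bse.drop("const"),
        p_values=res.pvalues.drop("const"),
        r2=r2,
        adjusted_r2=adj,
        residuals=pd.Series(res.resid, index=X.index),
        fitted=pd.Series(res.fittedvalues, index=X.index),
        nobs=n,
    )


def _fast_ols(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(adjusted R², coefficients, p-values) by direct least squares.

    Numerically the same model as :func:`fit_ols`; used in the inner
    selection loops where building a full statsmodels results object per
    trial would dominate the runtime. Final models are always refit with
    :func:`fit_ols`.
    """
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more sites than predictors + 1 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        raise RankDeficiencyError([f"col{i}" for i in range(p)])
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if p == 0 or ss_tot == 0.0:
        return 0.0, beta[1:], np.ones(p)
    r2 = 1.0 - ss_res / ss_tot
    dof = n - p - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    sigma2 = ss_res / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    return adj, beta[1:], pvals[1:]


def _fast_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(R², slope) of the single-predictor fit, via the Pearson correlation."""
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0, 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r, r * sy / sx


class _Cols:
    """Column array cache with a pairwise |correlation| matrix."""

    def __init__(self, features: FeatureMatrix):
        self.names = list(features.df.columns)
        self.idx = {n: i for i, n in enumerate(self.names)}
        self.arr = features.df.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(self.arr.T) if self.arr.shape[1] > 1 else np.ones((1, 1))
        corr = np.atleast_2d(corr)
        self.abs_corr = np.abs(np.where(np.isfinite(corr), corr, 1.0))

    def X(self, names: Sequence[str]) -> np.ndarray:
        return self.arr[:, [self.idx[n] for n in names]]

    def gate(self, candidate: str, included: Sequence[str], threshold: float) -> bool:
        i = self.idx[candidate]
        return all(self.abs_corr[i, self.idx[v]] < threshold for v in included)


def univariate_screen(
    features: FeatureMatrix, y: pd.Series | np.ndarray
) -> list[UnivariateResult]:
    """One single-predictor fit per candidate variable."""
    yv = np.asarray(y, dtype=float)
    results = []
    for name, var in features.variables.items():
        x = features.df[name].to_numpy(dtype=float)
        if x.std() == 0.0:
            # constant column: no information, treated as wrong-signed zero fit
            results.append(UnivariateResult(var, 0.0, 0.0, sign_ok=False))
            continue
        r2, coef = _fast_r2(x, yv)
        sign_ok = var.expected_sign == 0 or np.sign(coef) == var.expected_sign
        results.append(UnivariateResult(var, coef, r2, bool(sign_ok)))
    return results


def _buffer_key(var: CandidateVariable) -> float:
    return var.buffer_m if var.buffer_m is not None else 0.0


def select_best_buffer(
    results: Sequence[UnivariateResult],
) -> tuple[list[UnivariateResult], list[TraceEvent]]:
    """Keep at most one buffer per variable type: the correctly signed buffer
    with the highest univariate R², ties toward the smaller radius."""
    trace: list[TraceEvent] = []
    by_type: dict[str, list[UnivariateResult]] = {}
    for res in results:
        by_type.setdefault(res.variable.var_type, []).append(res)
    chosen: list[UnivariateResult] = []
    for var_type in sorted(by_type):
        ok = [r for r in by_type[var_type] if r.sign_ok]
        if not ok:
            trace.append(
                TraceEvent("type_dropped", var_type, np.nan, np.nan, note="no buffer with expected sign")
            )
            continue
        best = min(ok, key=lambda r: (-r.r2, _buffer_key(r.variable), r.variable.name))
        chosen.append(best)
        trace.append(
            TraceEvent("buffer_chosen", best.variable.name, np.nan, best.r2)
        )
    return chosen, trace


def _abs_corr(x: np.ndarray, z: np.ndarray) -> float:
    if x.std() == 0 or z.std() == 0:
        return 1.0  # degenerate: block the pairing
    return abs(float(np.corrcoef(x, z)[0, 1]))


def forward_selection(
    screened: Sequence[UnivariateResult],
    features: FeatureMatrix,
    y: pd.Series | np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[RegressionFit, list[TraceEvent]]:
    """Greedy forward pass in decreasing univariate-R² order."""
    order = sorted(screened, key=lambda r: (-r.r2, r.variable.name))
    cols = _Cols(features)
    yv = np.asarray(y, dtype=float)
    included: list[str] = []
    current_adj = 0.0
    trace: list[TraceEvent] = []
    for res in order:
        name = res.variable.name
        before = current_adj
        if not cols.gate(name, included, config.corr_threshold):
            trace.append(TraceEvent("rejected_correlation", name, before, before))
            continue
        try:
            adj, _, _ = _fast_ols(cols.X(included + [name]), yv)
        except RankDeficiencyError:
            trace.append(
                TraceEvent("rejected_correlation", name, before, before, note="rank deficient")
            )
            continue
        except ValueError:
            # adding would exhaust the residual degrees of freedom
            trace.append(
                TraceEvent("rejected_no_gain", name, before, before, note="insufficient dof")
            )
            continue
        if adj > before:
            included.append(name)
            current_adj = adj
            trace.append(TraceEvent("added", name, before, adj))
        else:
            trace.append(TraceEvent("rejected_no_gain", name, before, before))
    return fit_ols(features.df[included], y), trace


def backward_prune(
    fit: RegressionFit,
    features: FeatureMatrix,
    y: pd.Series | np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[RegressionFit, list[TraceEvent]]:
    """Remove variables with p > 0.2 one at a time, largest p first."""
    trace: list[TraceEvent] = []
    current = fit
    while current.variables:
        pvals = current.p_values
        worst = pvals.idxmax()
        if pvals[worst] <= config.p_remove:
            break
        remaining = [v for v in current.variables if v != worst]
        before = current.adjusted_r2
        current = fit_ols(features.df[remaining], y)
        trace.append(
            TraceEvent(
                "removed_pvalue", worst, before, current.adjusted_r2,
                note=f"p={pvals[worst]:.4g}",
            )
        )
    return current, trace


def challenge_variables(
    fit: RegressionFit,
    features: FeatureMatrix,
    y: pd.Series | np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[RegressionFit, list[TraceEvent]]:
    """One full pass: try to replace each model variable with any candidate.

    A swap is accepted when the replacement strictly improves the adjusted
    R², keeps all pairwise |r| below the threshold, and its coefficient has
    the expected sign in the new fit.
    """
    trace: list[TraceEvent] = []
    cols = _Cols(features)
    yv = np.asarray(y, dtype=float)
    model = list(fit.variables)
    current_adj = fit.adjusted_r2
    for pos in range(len(model)):
        incumbent = model[pos]
        others = [v for i, v in enumerate(model) if i != pos]
        best_name, best_adj = None, None
        best_key: tuple | None = None
        for name, var in features.variables.items():
            if name in model:
                continue
            if not cols.gate(name, others, config.corr_threshold):
                continue
            try:
                adj, coefs, _ = _fast_ols(cols.X(others + [name]), yv)
            except RankDeficiencyError:
                continue
            if adj <= current_adj:
                continue
            if var.expected_sign != 0 and np.sign(coefs[-1]) != var.expected_sign:
                continue
            key = (-adj, _buffer_key(var), name)
            if best_key is None or key < best_key:
                best_key, best_name, best_adj = key, name, adj
        if best_name is not None:
            trace.append(
                TraceEvent(
                    "challenged_swap", best_name, current_adj, best_adj,
                    replaced=incumbent,
                )
            )
            model[pos] = best_name
            current_adj = best_adj
    return fit_ols(features.df[model], y), trace


def final_augment(
    fit: RegressionFit,
    features: FeatureMatrix,
    y: pd.Series | np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[RegressionFit, list[TraceEvent]]:
    """Admit at most one extra variable (adjusted-R² gain, gate, p ≤ 0.2)."""
    current = fit
    cols = _Cols(features)
    yv = np.asarray(y, dtype=float)
    best_name, best_key = None, None
    for name, var in features.variables.items():
        if name in current.variables:
            continue
        if not cols.gate(name, current.variables, config.corr_threshold):
            continue
        try:
            adj, _, _ = _fast_ols(cols.X(current.variables + [name]), yv)
        except (RankDeficiencyError, ValueError):
            continue
        if adj <= current.adjusted_r2:
            continue
        key = (-adj, _buffer_key(var), name)
        if best_key is None or key < best_key:
            best_key, best_name = key, name
    if best_name is None:
        return current, []
    best_fit = fit_ols(features.df[current.variables + [best_name]], y)
    p_new = float(best_fit.p_values[best_name])
    if p_new <= config.p_keep:
        return best_fit, [
            TraceEvent(
                "augmented", best_name, current.adjusted_r2, best_fit.adjusted_r2,
                note=f"p={p_new:.4g}",
            )
        ]
    return current, [
        TraceEvent(
            "not_augmented", best_name, current.adjusted_r2, current.adjusted_r2,
            note=f"best addition had p={p_new:.4g} > {config.p_keep}",
        )
    ]


def build_lur(
    features: FeatureMatrix,
    y: pd.Series | np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> LURModel:
    """Run the full selection pipeline and return the model with its trace."""
    y = pd.Series(np.asarray(y, dtype=float), index=features.df.index)
    uni = univariate_screen(features, y)
    screened, trace = select_best_buffer(uni)
    fit, t = forward_selection(screened, features, y, config)
    trace += t
    fit, t = backward_prune(fit, features, y, config)
    trace += t
    fit, t = challenge_variables(fit, features, y, config)
    trace += t
    fit, t = final_augment(fit, features, y, config)
    trace += t
    return LURModel(
        fit=fit, trace=trace, config=config,
        screened=[r.variable.name for r in screened],
    )


def replay_trace(
    trace: Sequence[TraceEvent],
    features: FeatureMatrix,
    y: pd.Series | np.ndarray,
) -> RegressionFit:
    """Reconstruct the final fit purely from the logged decisions."""
    model: list[str] = []
    for ev in trace:
        if ev.action in ("added", "augmented"):
            model.append(ev.variable)
        elif ev.action == "removed_pvalue":
            model.remove(ev.variable)
        elif ev.action == "challenged_swap":
            model[model.index(ev.replaced)] = ev.variable
    return fit_ols(features.df[model], y)


def exhaustive_subset_search(
    features: FeatureMatrix,
    y: pd.Series | np.ndarray,
    corr_threshold: float = 0.7,
    max_size: int | None = None,
) -> list[str]:
    """Best-subset oracle: maximise adjusted R² over all variable subsets
    whose pairwise |Pearson r| stays below the threshold.

    Exponential in the number of candidates; intended for small screened
    sets as an independent cross-check of the greedy pipeline. Ties go to
    the smaller subset, then lexicographic order.
    """
    names = list(features.df.columns)
    if max_size is None:
        max_size = len(names)
    y = pd.Series(np.asarray(y, dtype=float), index=features.df.index)
    best: tuple[float, int, tuple[str, ...]] | None = None
    for k in range(0, max_size + 1):
        for combo in itertools.combinations(names, k):
            ok = all(
                _abs_corr(features.df[a].to_numpy(), features.df[b].to_numpy())
                < corr_threshold
                for a, b in itertools.combinations(combo, 2)
            )
            if not ok:
                continue
            adj = fit_ols(features.df[list(combo)], y).adjusted_r2
            key = (-adj, k, combo)
            if best is None or key < best:
                best = key
    return list(best[2])


class LURRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style interface to the supervised LUR selection.

    Parameters
    ----------
    corr_threshold : float, default 0.7
        Maximum absolute pairwise Pearson correlation allowed in the model.
    p_remove : float, default 0.2
        Backward-pruning removal threshold on coefficient p-values.
    p_keep : float, default 0.2
        p-value gate for the single final augmentation variable.

    ``fit`` accepts a :class:`~noiselur.gis.FeatureMatrix`, or a DataFrame /
    array (column metadata is then synthesised with unconstrained signs and
    one type per column, so only the buffer-selection stage is a no-op).

    Attributes (after fit)
    ----------------------
    model_ : LURModel with the full selection trace.
    variables_ : names of the selected predictors.
    coef_, intercept_ : fitted linear parameters.
    r2_, adj_r2_ : in-sample coefficients of determination.
    """

    def __init__(self, corr_threshold: float = 0.7, p_remove: float = 0.2, p_keep: float = 0.2):
        self.corr_threshold = corr_threshold
        self.p_remove = p_remove
        self.p_keep = p_keep

    def _as_feature_matrix(self, X) -> FeatureMatrix:
        if isinstance(X, FeatureMatrix):
            return X
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        variables = {
            str(c): CandidateVariable(
                name=str(c), var_type=str(c), category="generic",
                buffer_m=None, expected_sign=0, unit="",
            )
            for c in X.columns
        }
        return FeatureMatrix(X.astype(float), variables)

    def fit(self, X, y) -> "LURRegressor":
        fm = self._as_feature_matrix(X)
        config = SelectionConfig(self.corr_threshold, self.p_remove, self.p_keep)
        model = build_lur(fm, y, config)
        self.model_ = model
        self.variables_ = list(model.fit.variables)
        self.coef_ = model.fit.coefficients.to_numpy()
        self.intercept_ = model.fit.intercept
        self.r2_ = model.fit.r2
        self.adj_r2_ = model.fit.adjusted_r2
        self.n_features_in_ = fm.df.shape[1]
        self.feature_names_in_ = np.asarray(fm.df.columns, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if isinstance(X, FeatureMatrix):
            X = X.df
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.feature_names_in_)
        return self.model_.fit.predict(X).to_numpy()
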