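"""ESCAPE-style supervised land-use-regression model building.

The procedure: every candidate GIS variable is first regressed individually
against the measured concentrations; a forward stepwise search then grows the
model, at each step adding the candidate that maximizes adjusted R² subject
to two admissibility rules — the new coefficient's sign must match its
a-priori direction of effect, and no coefficient already in the model may
flip against its prior. A step is accepted only if it improves adjusted R²
by more than ``gain`` (0.01 by default, the ESCAPE convention). The final
model is pruned of coefficients with p >= 0.1, screened for collinearity
(drop predictors until every VIF < 5), and validated with leave-one-out
cross-validation.

LOOCV R² is defined as 1 - SSE_loo/SST — a coefficient of determination of
the held-out predictions, not a squared correlation — so anti-correlated
predictions are penalized and the value can be negative. Predictor selection
is not repeated inside the folds: the folds re-estimate coefficients of the
already-developed model, which mirrors validating a finished model and gives
slightly optimistic values compared to re-running the search per fold (an
``honest`` mode is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SingularDesignError
from .geo_predictors import (
    PredictorMatrix,
    PredictorSpec,
    SIGN_FREE,
    SIGN_NEGATIVE,
    SIGN_POSITIVE,
)

DEFAULT_GAIN = 0.01
DEFAULT_P_MAX = 0.1
DEFAULT_VIF_MAX = 5.0


@dataclass(frozen=True)
class FitResult:
    """OLS fit summary: coefficients with conventional t-based inference."""

    params: pd.Series  # index: 'const' + predictor names
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    rmse: float  # sqrt(SSE / n)
    df_resid: int
    nobs: int
    resid: np.ndarray

    @property
    def predictor_names(self) -> list[str]:
        return [n for n in self.params.index if n != "const"]


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Columns that do not increase the rank of the design."""
    bad = []
    cur = np.ones((len(X), 1))
    rank = 1
    for name in X.columns:
        cand = np.column_stack([cur, X[name].to_numpy()])
        r = np.linalg.matrix_rank(cand)
        if r == rank:
            bad.append(name)
        else:
            cur, rank = cand, r
    return bad


def fit_ols(y, X: pd.DataFrame | None = None) -> FitResult:
    """Ordinary least squares of concentrations on predictor columns.

    ``X`` may be None/empty for an intercept-only fit. Raises
    :class:`SingularDesignError` naming dependent columns if the design is
    rank deficient.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        X = pd.DataFrame(index=pd.RangeIndex(n))
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    zero_var = [c for c in X.columns if np.std(X[c].to_numpy()) == 0]
    if zero_var:
        raise SingularDesignError(zero_var)
    Xc = sm.add_constant(X.reset_index(drop=True), has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise SingularDesignError(_dependent_columns(X))
    res = sm.OLS(y, Xc).fit()
    sse = float(np.sum(res.resid**2))
    return FitResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared) if k else 0.0,
        adj_r2=float(res.rsquared_adj) if k else 0.0,
        rmse=float(np.sqrt(sse / n)),
        df_resid=int(res.df_resid),
        nobs=n,
        resid=np.asarray(res.resid),
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R²_j) of column j regressed
    on the remaining columns (plus intercept). Perfect collinearity reports
    +inf."""
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    out = {}
    for name in X.columns:
        others = X.drop(columns=[name])
        yj = X[name].to_numpy(dtype=float)
        Z = sm.add_constant(others.reset_index(drop=True), has_constant="add").to_numpy()
        beta, _, rank, _ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[name] = float("inf") if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _quick_fit(y: np.ndarray, Xv: np.ndarray):
    """Fast lstsq fit: returns (beta incl intercept first, r2, adj_r2, rmse)
    or None on a singular design."""
    n = len(y)
    Z = np.column_stack([np.ones(n), Xv])
    k = Xv.shape[1]
    if n <= k + 1:
        return None
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        return None
    resid = y - Z @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return None
    r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return beta, r2, adj, float(np.sqrt(sse / n))


def _sign_ok(beta: float, prior: str) -> bool:
    if prior == SIGN_POSITIVE:
        return beta > 0
    if prior == SIGN_NEGATIVE:
        return beta < 0
    return True


def univariate_screen(y, matrix: PredictorMatrix) -> pd.DataFrame:
    """Single-predictor regressions of every candidate, ranked by adjusted R²
    among prior-consistent candidates; prior-violating candidates are listed
    after them with ``sign_ok = False``."""
    y = np.asarray(y, dtype=float)
    priors = matrix.sign_priors()
    rows = []
    for name in matrix.data.columns:
        xv = matrix.data[name].to_numpy(dtype=float).reshape(-1, 1)
        if np.std(xv) == 0:
            rows.append((name, priors[name], np.nan, np.nan, np.nan, np.nan, False))
            continue
        fit = fit_ols(y, matrix.data[[name]])
        slope = float(fit.params[name])
        rows.append(
            (
                name,
                priors[name],
                slope,
                fit.r2,
                fit.adj_r2,
                float(fit.pvalues[name]),
                _sign_ok(slope, priors[name]),
            )
        )
    df = pd.DataFrame(
        rows, columns=["name", "sign_prior", "slope", "r2", "adj_r2", "p", "sign_ok"]
    )
    df = df.sort_values(
        ["sign_ok", "adj_r2", "name"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


@dataclass
class LurModel:
    """A selected land-use-regression model for one pollutant and scope.

    Construction enforces the model's own contract: every retained
    coefficient obeys its sign prior (unconstrained priors exempt), every
    coefficient p-value is below ``p_max``, and every VIF is below
    ``vif_max``. Worked-example models built from published coefficient
    tables (:meth:`from_coefficients`) skip enforcement since no fit
    statistics exist for them.
    """

    pollutant: str
    scope: str
    specs: list[PredictorSpec]
    fit: FitResult
    loocv_r2: float
    training_ranges: dict[str, tuple[float, float]]
    selection_log: list = field(default_factory=list)
    p_max: float = DEFAULT_P_MAX
    vif_max: float = DEFAULT_VIF_MAX
    vifs: pd.Series | None = None
    enforce: bool = True

    def __post_init__(self):
        if not self.enforce:
            return
        priors = {s.name: s.sign_prior for s in self.specs}
        for name in self.fit.predictor_names:
            beta = float(self.fit.params[name])
            if not _sign_ok(beta, priors[name]):
                raise AssertionError(f"{name}: coefficient sign violates its prior")
            if float(self.fit.pvalues[name]) >= self.p_max:
                raise AssertionError(f"{name}: p >= {self.p_max}")
        if self.vifs is not None and len(self.vifs) and self.vifs.max() >= self.vif_max:
            raise AssertionError("max VIF >= limit in emitted model")
        if self.loocv_r2 > 1 + 1e-12:
            raise AssertionError("LOOCV R2 cannot exceed 1")

    @property
    def predictor_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def intercept(self) -> float:
        return float(self.fit.params["const"])

    @property
    def intercept_only(self) -> bool:
        return len(self.specs) == 0

    @classmethod
    def from_coefficients(
        cls,
        intercept: float,
        coefficients: dict[str, float] | None = None,
        pollutant: str = "",
        scope: str = "",
        specs: list[PredictorSpec] | None = None,
        training_ranges: dict | None = None,
    ) -> "LurModel":
        """Build a model directly from known coefficients (e.g. a published
        table) for prediction; no inference statistics are attached."""
        coefficients = coefficients or {}
        names = list(coefficients)
        if specs is None:
            specs = [PredictorSpec(n, "elevation", None, None, SIGN_FREE) for n in names]
        idx = ["const"] + names
        nanseries = pd.Series([np.nan] * len(idx), index=idx)
        fitres = FitResult(
            params=pd.Series([intercept] + [coefficients[n] for n in names], index=idx),
            bse=nanseries,
            tvalues=nanseries,
            pvalues=nanseries,
            r2=np.nan,
            adj_r2=np.nan,
            rmse=np.nan,
            df_resid=0,
            nobs=0,
            resid=np.zeros(0),
        )
        return cls(
            pollutant,
            scope,
            specs,
            fitres,
            loocv_r2=np.nan,
            training_ranges=training_ranges or {},
            enforce=False,
        )


def loocv(y, X: pd.DataFrame | None) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validation of a fixed predictor set.

    Coefficients are re-estimated on each n-1 subset and the left-out site
    predicted; returns (LOOCV R², per-site held-out predictions). Singular
    folds are excluded with a warning. R² = 1 - SSE/SST and may be negative.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 observations")
    Xv = np.zeros((n, 0)) if X is None or X.shape[1] == 0 else X.to_numpy(dtype=float)
    Z = np.column_stack([np.ones(n), Xv])
    preds = np.full(n, np.nan)
    for i in range(n):
        mask = np.arange(n) != i
        beta, _, rank, _ = np.linalg.lstsq(Z[mask], y[mask], rcond=None)
        if rank < Z.shape[1]:
            warnings.warn(f"LOOCV fold {i} singular; excluded", stacklevel=2)
            continue
        preds[i] = Z[i] @ beta
    ok = ~np.isnan(preds)
    sse = float(np.sum((y[ok] - preds[ok]) ** 2))
    sst = float(np.sum((y[ok] - y[ok].mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return float(r2), preds


def supervised_forward_select(
    y,
    matrix: PredictorMatrix,
    *,
    gain: float = DEFAULT_GAIN,
    p_max: float = DEFAULT_P_MAX,
    vif_max: float = DEFAULT_VIF_MAX,
    min_n: int = 10,
    pollutant: str = "",
    scope: str = "",
    honest_loocv: bool = False,
) -> LurModel:
    """Supervised forward selection with direction-of-effect constraints.

    See the module docstring for the full procedure. An intercept-only model
    is a valid outcome (flagged in the selection log) when no admissible
    candidate clears the adjusted-R² gain threshold.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_n:
        raise ValueError(f"need at least {min_n} sites to fit (got {n})")
    data = matrix.data
    priors = matrix.sign_priors()
    log: list[dict] = []

    selected: list[str] = []
    current_adj = 0.0
    step = 0
    while True:
        step += 1
        best = None  # (adj_r2, rmse, name, beta_vector)
        rejects = []
        for name in data.columns:
            if name in selected:
                continue
            cols = selected + [name]
            res = _quick_fit(y, data[cols].to_numpy(dtype=float))
            if res is None:
                rejects.append({"candidate": name, "reason": "singular"})
                continue
            beta, r2, adj, rmse = res
            betas = dict(zip(cols, beta[1:]))
            if not _sign_ok(betas[name], priors[name]):
                rejects.append({"candidate": name, "reason": "sign-prior"})
                continue
            flipped = [c for c in selected if not _sign_ok(betas[c], priors[c])]
            if flipped:
                rejects.append(
                    {"candidate": name, "reason": f"flips-sign:{','.join(flipped)}"}
                )
                continue
            key = (-adj, rmse, name)
            if best is None or key < best[0]:
                best = (key, name, adj, rmse)
        if best is None:
            log.append({"step": step, "action": "stop", "reason": "no admissible candidate",
                        "rejected": rejects})
            break
        _, name, adj, rmse = best
        if adj - current_adj <= gain:
            log.append({"step": step, "action": "stop",
                        "reason": f"best gain {adj - current_adj:.4f} <= {gain}",
                        "candidate": name, "rejected": rejects})
            break
        selected.append(name)
        current_adj = adj
        log.append({"step": step, "action": "add", "candidate": name,
                    "adj_r2": adj, "rmse": rmse, "rejected": rejects})

    def refit(names):
        return fit_ols(y, data[names]) if names else fit_ols(y, None)

    fitres = refit(selected)

    def prune(fitres, selected):
        while selected:
            pv = fitres.pvalues.drop("const")
            worst = pv.idxmax()
            if pv[worst] < p_max:
                break
            selected = [c for c in selected if c != worst]
            log.append({"action": "prune-p", "removed": worst, "p": float(pv[worst])})
            fitres = refit(selected)
        return fitres, selected

    fitres, selected = prune(fitres, selected)

    removed_by_vif = False
    while len(selected) >= 2:
        v = vif(data[selected])
        if v.max() < vif_max:
            break
        worst = v.idxmax()
        selected = [c for c in selected if c != worst]
        removed_by_vif = True
        log.append({"action": "prune-vif", "removed": worst, "vif": float(v[worst])})
        fitres = refit(selected)
    if removed_by_vif:
        fitres, selected = prune(fitres, selected)

    # removals can in principle flip a remaining coefficient against its
    # prior; drop such predictors until the emitted model is consistent
    while selected:
        bad = [
            c
            for c in selected
            if not _sign_ok(float(fitres.params[c]), priors[c])
        ]
        if not bad:
            break
        worst = max(bad, key=lambda c: float(fitres.pvalues[c]))
        selected = [c for c in selected if c != worst]
        log.append({"action": "prune-sign", "removed": worst})
        fitres = refit(selected)
        fitres, selected = prune(fitres, selected)

    if not selected:
        log.append({"action": "final", "note": "intercept-only model"})

    vifs = vif(data[selected]) if len(selected) >= 2 else pd.Series(dtype=float)
    if honest_loocv:
        loo_r2 = _honest_loocv(y, matrix, gain=gain, p_max=p_max, vif_max=vif_max)
    else:
        loo_r2, _ = loocv(y, data[selected] if selected else None)
    spec_by_name = {s.name: s for s in matrix.specs}
    ranges = {
        c: (float(data[c].min()), float(data[c].max())) for c in selected
    }
    return LurModel(
        pollutant,
        scope,
        [spec_by_name[c] for c in selected],
        fitres,
        loo_r2,
        ranges,
        selection_log=log,
        p_max=p_max,
        vif_max=vif_max,
        vifs=vifs,
    )


def _honest_loocv(y, matrix: PredictorMatrix, **options) -> float:
    """LOOCV that re-runs the whole selection per fold (slower, less
    optimistic)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.full(n, np.nan)
    for i in range(n):
        mask = np.arange(n) != i
        sub = PredictorMatrix(
            matrix.data.iloc[mask], matrix.specs, dict(matrix.provenance)
        )
        m = supervised_forward_select(
            y[mask], sub, min_n=3, honest_loocv=False, **options
        )
        row = matrix.data.iloc[[i]][m.predictor_names]
        preds[i] = m.intercept + float(
            row.to_numpy() @ np.asarray([m.fit.params[c] for c in m.predictor_names])
        ) if m.predictor_names else m.intercept
    sse = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst if sst > 0 else np.nan
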