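"""Statistics linking photoreceptor excitations to normalised fly catches.

The analysis chain mirrors how field-catch data are treated: normalised
catches (percent of a standard bait's catch) are averaged over repeat
presentations of each bait, log10(x+1)-transformed, and joined with the
bait's calculated excitations (:func:`collate`). Because excitations of the
five receptor classes are highly multicollinear, exploration proceeds by

* Spearman rank correlations among excitations (:func:`spearman_matrix`),
* multivariate partial least squares regression with leave-one-out PRESS
  factor selection (:class:`CatchPLS`), and
* directed, sequential ordinary least squares in which receptors are added
  one at a time and each addition is judged by an F-test of the change in r²
  (:class:`SequentialExcitationOLS`),

plus a dummy-coded comparison of Troje colour categories
(:func:`category_regression`). Models follow the statsmodels convention:
construct from a DataFrame, call ``fit()``, get a results object with a
``summary()``.

OLS fits, p-values and variance-inflation factors are delegated to
statsmodels; the PLS2 engine (NIPALS on z-scored predictors and responses,
coefficients back-transformed to raw scale, LOO PRESS and predicted r²) is
implemented here because no factor-selection-aware PLS is otherwise
available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .receptors import RECEPTOR_CLASSES

logger = logging.getLogger(__name__)

EXCITATION_COLUMNS = [f"E_{c}" for c in RECEPTOR_CLASSES]

#: Order in which receptors enter the sequential regressions: the two most
#: explanatory first, then the remaining classes by decreasing median
#: importance in the cross-study coefficient ranking.
SEQUENTIAL_ORDER = ["R7y", "R8y", "R7p", "R8p", "R1-6"]


class CatchStatsError(ValueError):
    pass


def log_catch_transform(catch_pct: np.ndarray | pd.Series, base: float = 10.0) -> np.ndarray:
    """log(x+1) of a normalised catch percentage; base 10 by default."""
    x = np.asarray(catch_pct, dtype=float)
    return np.log(x + 1.0) / np.log(base)


# ---------------------------------------------------------------------------
# collation

def collate(
    records: pd.DataFrame,
    excitations: pd.DataFrame,
    *,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Collapse repeat presentations to one row per (study, sex, bait).

    ``records`` needs columns ``study``, ``sex``, ``bait_id``, ``catch_pct``
    (and optionally ``species``/``presentation``). ``excitations`` is indexed
    by ``bait_id`` with ``E_*`` columns (as produced by ``excite_panel``).
    Per unique (study, sex, bait) the mean catch over presentations is taken
    and log(x+1)-transformed into ``log_catch``; the bait's excitations are
    joined on.
    """
    required = {"study", "sex", "bait_id", "catch_pct"}
    missing = required - set(records.columns)
    if missing:
        raise CatchStatsError(f"catch records missing columns: {sorted(missing)}")
    if (records["catch_pct"] < 0).any() or not np.isfinite(records["catch_pct"]).all():
        raise CatchStatsError("catch_pct must be finite and >= 0")

    absent = sorted(set(records["bait_id"]) - set(excitations.index))
    if absent:
        raise CatchStatsError(f"no excitations for baits: {absent}")

    grouped = (records.groupby(["study", "sex", "bait_id"], sort=False)["catch_pct"]
               .mean().reset_index().rename(columns={"catch_pct": "mean_catch_pct"}))
    grouped["log_catch"] = log_catch_transform(grouped["mean_catch_pct"], base=log_base)
    table = grouped.join(excitations[EXCITATION_COLUMNS], on="bait_id")
    logger.info("collated %d presentations into %d unique bait rows",
                len(records), len(table))
    return table


# ---------------------------------------------------------------------------
# correlation structure

def spearman_matrix(
    table: pd.DataFrame,
    columns: Sequence[str] = tuple(EXCITATION_COLUMNS),
) -> pd.DataFrame:
    """Spearman rank-correlation matrix of the given columns.

    Average ranks for ties. A constant column has no defined rank
    correlation; its entries are NaN and a warning names the column rather
    than silently reporting 0.
    """
    if len(table) < 3:
        raise CatchStatsError("need at least 3 rows for rank correlations")
    data = table[list(columns)].to_numpy(dtype=float)
    constant = [col for col, v in zip(columns, data.T) if np.ptp(v) == 0]
    if constant:
        warnings.warn(f"constant columns have undefined rank correlation: {constant}")
    out = table[list(columns)].corr(method="spearman")
    np.fill_diagonal(out.values, 1.0)
    for col in constant:
        out.loc[col, :] = np.nan
        out.loc[:, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# sequential OLS

@dataclass
class OLSStep:
    """One nested model in a sequential regression."""

    predictors: list[str]
    params: pd.Series                 # raw coefficients incl. 'const'
    std_params: pd.Series             # standardised coefficients (no const)
    r2: float
    adj_r2: float
    f_value: float
    f_df: tuple[int, int]
    f_pvalue: float
    delta_r2: float
    delta_f: float
    delta_f_df: tuple[int, int]
    delta_f_pvalue: float
    vif: pd.Series
    nobs: int
    sm_result: object = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "predictors": "+".join(self.predictors),
            "r2": self.r2, "adj_r2": self.adj_r2,
            "F": self.f_value, "df1": self.f_df[0], "df2": self.f_df[1],
            "p": self.f_pvalue,
            "delta_r2": self.delta_r2, "delta_F": self.delta_f,
            "delta_df1": self.delta_f_df[0], "delta_df2": self.delta_f_df[1],
            "delta_p": self.delta_f_pvalue,
        }


class SequentialOLSResults:
    """Results of a nested sequence of OLS fits with r²-change F-tests."""

    def __init__(self, steps: list[OLSStep], response: str):
        self.steps = steps
        self.response = response

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_row() for s in self.steps])

    @property
    def final(self) -> OLSStep:
        return self.steps[-1]

    def summary(self) -> str:
        lines = [f"Sequential OLS of {self.response} "
                 f"({self.steps[0].nobs} baits)", "-" * 72]
        for s in self.steps:
            lines.append(
                f"  {'+'.join(s.predictors):<28s} r2={s.r2:.3f} adj={s.adj_r2:.3f} "
                f"F({s.f_df[0]},{s.f_df[1]})={s.f_value:.3f} p={s.f_pvalue:.4g}"
            )
            lines.append(
                f"  {'':28s} dr2={s.delta_r2:.3f} "
                f"dF({s.delta_f_df[0]},{s.delta_f_df[1]})={s.delta_f:.3f} "
                f"p={s.delta_f_pvalue:.4g}"
            )
        return "\n".join(lines)


class SequentialExcitationOLS:
    """OLS of log catch on nested sets of receptor excitations.

    Parameters
    ----------
    data : DataFrame
        One row per unique bait with the response column and predictor
        columns (``E_<class>`` by default).
    response : str
        Response column, typically ``log_catch``.
    sequence : sequence of str or of sequences
        Receptor classes (or column names) in entry order; each element may
        add one or several predictors at once. Defaults to the cross-study
        importance order R7y, R8y entering together, then R7p, R8p, R1-6.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "log_catch",
        sequence: Sequence | None = None,
    ):
        self.data = data
        self.response = response
        if sequence is None:
            sequence = [["R7y", "R8y"], ["R7p"], ["R8p"], ["R1-6"]]
        norm: list[list[str]] = []
        for block in sequence:
            if isinstance(block, str):
                block = [block]
            norm.append([self._column(b) for b in block])
        self.sequence = norm
        n_predictors = sum(len(b) for b in norm)
        if len(data) <= n_predictors + 1:
            raise CatchStatsError(
                f"{len(data)} rows cannot support {n_predictors} predictors")

    def _column(self, name: str) -> str:
        if name in self.data.columns:
            return name
        if f"E_{name}" in self.data.columns:
            return f"E_{name}"
        raise CatchStatsError(f"predictor column '{name}' not found")

    def fit(self) -> SequentialOLSResults:
        y = self.data[self.response].to_numpy(dtype=float)
        steps: list[OLSStep] = []
        current: list[str] = []
        prev_r2 = 0.0
        n = len(self.data)
        for block in self.sequence:
            current = current + block
            X = self.data[current].to_numpy(dtype=float)
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < len(current) + 1:
                raise CatchStatsError(f"singular design: collinear predictors {current}")
            exog = sm.add_constant(pd.DataFrame(X, columns=current))
            res = sm.OLS(y, exog).fit()
            r2 = float(res.rsquared)
            q = len(block)
            df2 = int(res.df_resid)
            delta_r2 = r2 - prev_r2
            if 1.0 - r2 <= np.finfo(float).tiny:
                delta_f, delta_p = np.inf, 0.0
            else:
                delta_f = (delta_r2 / q) / ((1.0 - r2) / df2)
                delta_p = float(sps.f.sf(delta_f, q, df2))
            sd_y = np.std(y, ddof=1)
            sd_x = np.std(X, axis=0, ddof=1)
            std_params = pd.Series(res.params[1:].to_numpy() * sd_x / sd_y, index=current)
            vif = pd.Series(
                [variance_inflation_factor(exog.to_numpy(), i + 1)
                 for i in range(len(current))],
                index=current,
            )
            steps.append(OLSStep(
                predictors=list(current),
                params=res.params,
                std_params=std_params,
                r2=r2,
                adj_r2=float(res.rsquared_adj),
                f_value=float(res.fvalue),
                f_df=(int(res.df_model), df2),
                f_pvalue=float(res.f_pvalue),
                delta_r2=delta_r2,
                delta_f=float(delta_f),
                delta_f_df=(q, df2),
                delta_f_pvalue=delta_p,
                vif=vif,
                nobs=n,
                sm_result=res,
            ))
            prev_r2 = r2
        return SequentialOLSResults(steps, self.response)


# ---------------------------------------------------------------------------
# PLS2 with PRESS factor selection

def _nipals_pls2(X0: np.ndarray, Y0: np.ndarray, n_factors: int,
                 tol: float = 1e-12, max_iter: int = 1000):
    """NIPALS PLS2 on centred/scaled matrices; returns W, P, C (columns per factor).

    Extraction stops early when the predictor residual is exhausted (rank
    deficiency), so fewer than ``n_factors`` columns may come back.
    """
    X = X0.copy()
    Y = Y0.copy()
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    C = np.zeros((m, n_factors))
    x_scale = max(float((X ** 2).sum()), 1.0)
    extracted = 0
    for a in range(n_factors):
        if (X ** 2).sum() < 1e-12 * x_scale:
            break
        # start u from the Y column with largest variance
        u = Y[:, np.argmax(Y.var(axis=0))].copy()
        if np.allclose(Y, 0):
            u = X[:, np.argmax(X.var(axis=0))].copy()
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            t = X @ w
            c = Y.T @ t / (t @ t)
            cn = np.linalg.norm(c)
            u = Y @ c / (cn ** 2) if cn > 0 else t
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        t = X @ w
        tt = t @ t
        if tt == 0:
            break
        p_load = X.T @ t / tt
        c = Y.T @ t / tt
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, c)
        W[:, a], P[:, a], C[:, a] = w, p_load, c
        extracted = a + 1
    return W[:, :extracted], P[:, :extracted], C[:, :extracted]


def _pls_coefficients(W: np.ndarray, P: np.ndarray, C: np.ndarray) -> np.ndarray:
    """B such that Ŷ0 = X0 @ B on the standardised scale."""
    M = P.T @ W
    try:
        inner = np.linalg.solve(M, C.T)
    except np.linalg.LinAlgError:
        inner = np.linalg.pinv(M) @ C.T
    return W @ inner


@dataclass
class PLSResults:
    """Fitted PLS2 regression with cross-validation statistics.

    ``coefficients``/``std_coefficients`` are predictor-by-response frames
    (raw scale incl. an intercept row 'const'; standardised without it).
    ``press`` indexes candidate factor counts; ``n_factors`` is the selected
    count after the parsimony rule.
    """

    n_factors: int
    coefficients: pd.DataFrame
    std_coefficients: pd.DataFrame
    r2: pd.Series
    predicted_r2: pd.Series
    press: pd.DataFrame                 # rows: factor count; cols: responses + 'total'
    responses: list[str]
    predictors: list[str]
    nobs: int
    parsimony_applied: bool = False

    def summary(self) -> str:
        lines = [f"PLS2 regression: {self.nobs} baits, "
                 f"{len(self.predictors)} predictors, "
                 f"{self.n_factors} latent factor(s)"
                 + (" [parsimony override]" if self.parsimony_applied else ""),
                 "-" * 72,
                 "standardised coefficients:"]
        lines.append(self.std_coefficients.round(3).to_string())
        lines.append("r2:            " + "  ".join(
            f"{r}={v:.3f}" for r, v in self.r2.items()))
        lines.append("predicted r2:  " + "  ".join(
            f"{r}={v:.3f}" for r, v in self.predicted_r2.items()))
        return "\n".join(lines)


class CatchPLS:
    """Multivariate PLS2 of (male, female) log catches on the five excitations.

    Predictors and responses are z-scored before the NIPALS decomposition
    and coefficients are back-transformed to the raw scale. The number of
    latent factors is chosen to minimise the leave-one-out predicted error
    sum of squares (PRESS), with a parsimony override: a factor is kept only
    if it improves total PRESS by more than ``parsimony_tol`` (relative)
    over the next simpler model.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        responses: Sequence[str],
        predictors: Sequence[str] = tuple(EXCITATION_COLUMNS),
    ):
        self.data = data
        self.responses = list(responses)
        self.predictors = list(predictors)
        for col in self.responses + self.predictors:
            if col not in data.columns:
                raise CatchStatsError(f"column '{col}' not in data")
        if data[self.responses].isna().any().any():
            raise CatchStatsError("both responses must be present for every bait")

    # -- core fit on given matrices -------------------------------------
    @staticmethod
    def _fit_standardised(X: np.ndarray, Y: np.ndarray, n_factors: int):
        mx, sx = X.mean(axis=0), X.std(axis=0, ddof=1)
        my, sy = Y.mean(axis=0), Y.std(axis=0, ddof=1)
        if np.any(sx == 0):
            raise CatchStatsError("constant predictor column")
        sy = np.where(sy == 0, 1.0, sy)
        X0 = (X - mx) / sx
        Y0 = (Y - my) / sy
        W, P, C = _nipals_pls2(X0, Y0, n_factors)
        B_std = _pls_coefficients(W, P, C)
        B_raw = B_std * (sy[None, :] / sx[:, None])
        intercept = my - mx @ B_raw
        return B_std, B_raw, intercept

    def _predict(self, X: np.ndarray, B_raw: np.ndarray, intercept: np.ndarray):
        return X @ B_raw + intercept

    def loo_press(self, max_factors: int | None = None) -> pd.DataFrame:
        """Leave-one-out PRESS per candidate factor count, on the raw scale."""
        X = self.data[self.predictors].to_numpy(dtype=float)
        Y = self.data[self.responses].to_numpy(dtype=float)
        n = len(X)
        A = max_factors or len(self.predictors)
        if A > len(self.predictors):
            raise CatchStatsError(
                f"{A} factors requested for {len(self.predictors)} predictors")
        press = np.zeros((A, Y.shape[1]))
        for i in range(n):
            keep = np.arange(n) != i
            for a in range(1, A + 1):
                _, B_raw, intercept = self._fit_standardised(X[keep], Y[keep], a)
                err = Y[i] - self._predict(X[i:i + 1], B_raw, intercept)[0]
                press[a - 1] += err ** 2
        out = pd.DataFrame(press, index=pd.RangeIndex(1, A + 1, name="n_factors"),
                           columns=self.responses)
        out["total"] = out.sum(axis=1)
        return out

    def fit(
        self,
        n_factors: int | None = None,
        max_factors: int | None = None,
        parsimony_tol: float = 0.02,
    ) -> PLSResults:
        X = self.data[self.predictors].to_numpy(dtype=float)
        Y = self.data[self.responses].to_numpy(dtype=float)
        n = len(X)
        press = self.loo_press(max_factors)
        parsimony_applied = False
        if n_factors is None:
            totals = press["total"].to_numpy()
            a = int(np.argmin(totals)) + 1
            # parsimony: walk back while the simpler model is nearly as good
            while a > 1 and (totals[a - 2] - totals[a - 1]) <= parsimony_tol * totals[a - 2]:
                a -= 1
                parsimony_applied = True
            n_factors = a
        elif n_factors > len(self.predictors):
            raise CatchStatsError(
                f"{n_factors} factors requested for {len(self.predictors)} predictors")

        B_std, B_raw, intercept = self._fit_standardised(X, Y, n_factors)
        fitted = self._predict(X, B_raw, intercept)
        ss_res = ((Y - fitted) ** 2).sum(axis=0)
        ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        r2 = 1.0 - ss_res / ss_tot
        pred_r2 = 1.0 - press.loc[n_factors, self.responses].to_numpy() / ss_tot

        coef = pd.DataFrame(B_raw, index=self.predictors, columns=self.responses)
        coef.loc["const"] = intercept
        std_coef = pd.DataFrame(B_std, index=self.predictors, columns=self.responses)
        return PLSResults(
            n_factors=n_factors,
            coefficients=coef,
            std_coefficients=std_coef,
            r2=pd.Series(r2, index=self.responses),
            predicted_r2=pd.Series(pred_r2, index=self.responses),
            press=press,
            responses=self.responses,
            predictors=self.predictors,
            nobs=n,
            parsimony_applied=parsimony_applied,
        )


# ---------------------------------------------------------------------------
# coefficient ranking across studies

def rank_coefficients(std_coefficients: pd.DataFrame) -> pd.DataFrame:
    """Rank predictors by |standardised coefficient| within each analysis.

    ``std_coefficients``: rows are predictors, columns are analyses (e.g.
    one per study/sex). Rank 1 is the largest magnitude; ties receive
    average ranks (and are logged). Returns the per-analysis ranks plus a
    ``median_rank`` column.
    """
    ranks = {}
    for col in std_coefficients.columns:
        mags = std_coefficients[col].abs().to_numpy(dtype=float)
        r = sps.rankdata(-mags, method="average")
        if len(np.unique(mags)) < len(mags):
            logger.info("tied coefficient magnitudes in '%s'; average ranks used", col)
        ranks[col] = r
    out = pd.DataFrame(ranks, index=std_coefficients.index)
    out["median_rank"] = out.median(axis=1)
    return out


# ---------------------------------------------------------------------------
# colour-category regression

def category_regression(
    table: pd.DataFrame,
    categories: pd.Series,
    response: str = "log_catch",
    reference: str = "y+p-",
) -> "CategoryRegressionResult":
    """OLS of log catch on 1-0 dummy-coded colour categories.

    ``reference`` (default the category of phthalogen-blue standards) is the
    omitted level; each dummy coefficient is that category's mean difference
    from the reference. Requires at least two categories present.
    """
    cats = pd.Series(categories, index=table.index).astype(str)
    levels = [lv for lv in ["y+p-", "y+p+", "y-p-", "y-p+"] if lv in set(cats)]
    if len(levels) < 2:
        raise CatchStatsError("need at least two colour categories represented")
    if reference not in levels:
        reference = levels[0]
    dummies = pd.get_dummies(cats).astype(float)
    dummy_cols = [lv for lv in levels if lv != reference]
    exog = sm.add_constant(dummies[dummy_cols])
    res = sm.OLS(table[response].to_numpy(dtype=float), exog).fit()
    return CategoryRegressionResult(
        reference=reference,
        params=res.params,
        tvalues=res.tvalues,
        pvalues=pd.Series(res.pvalues, index=res.params.index),
        r2=float(res.rsquared),
        f_value=float(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue),
        group_counts=cats.value_counts().to_dict(),
        sm_result=res,
    )


@dataclass
class CategoryRegressionResult:
    reference: str
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    f_value: float
    f_df: tuple[int, int]
    f_pvalue: float
    group_counts: dict
    sm_result: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"Colour-category OLS (reference {self.reference}); "
                 f"F({self.f_df[0]},{self.f_df[1]})={self.f_value:.3f} "
                 f"p={self.f_pvalue:.4g} r2={self.r2:.3f}"]
        for name in self.params.index:
            lines.append(f"  {name:<8s} b={self.params[name]:+.3f} "
                         f"t={self.tvalues[name]:+.3f} p={self.pvalues[name]:.4g}")
        return "\n".join(lines)
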