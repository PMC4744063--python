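"""Design-based logistic regression for stratified cluster samples.

Implements weighted pseudo-maximum-likelihood estimation with
Taylor-linearized (sandwich) variance using between-PSU variability of
score totals within strata, subpopulation (domain) estimation, Rubin's
rules for pooling across multiply-imputed datasets with the
Barnard-Rubin small-sample degrees of freedom, and a design-adjusted
(F-corrected) goodness-of-fit test on grouped mean residuals.

Inference is t-based on the design degrees of freedom
(#PSUs - #strata), the convention for complex-survey analyses where the
effective number of independent units is the number of PSUs, not the
number of participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SurveyDataset
from .exceptions import ConfigurationError, ConvergenceError, DesignError, SeparationError

__all__ = [
    "SurveyDesign",
    "SurveyLogit",
    "SurveyLogitResults",
    "PooledFit",
    "GofResult",
    "pool_rubin",
    "gof_design_adjusted",
    "build_design_matrix",
]


# ---------------------------------------------------------------------------
# design


class SurveyDesign:
    """Stratum and PSU labels plus weights for variance estimation.

    ``design_df = #distinct stratum-PSU pairs - #strata``.  Strata with a
    single PSU cannot contribute a between-PSU variance term; by default they
    raise, and ``collapse=True`` merges each single-PSU stratum into the
    next stratum in label order instead (logged via a warning).
    """

    def __init__(self, strata, psus, weights, collapse: bool = False):
        strata = np.asarray(strata)
        psus = np.asarray(psus)
        weights = np.asarray(weights, dtype=float)
        if not (len(strata) == len(psus) == len(weights)):
            raise ConfigurationError("strata, psus, weights must have equal length")
        if (weights <= 0).any():
            raise ConfigurationError("weights must be strictly positive")
        if collapse:
            strata = self._collapse_single_psu(strata, psus)
        self.strata = strata
        self.psus = psus
        self.weights = weights
        # PSUs are identified within stratum
        counts = pd.DataFrame({"h": strata, "c": psus}).drop_duplicates().groupby("h").size()
        self.psus_per_stratum = counts
        self.n_strata = len(counts)
        self.n_psus = int(counts.sum())
        self.design_df = self.n_psus - self.n_strata
        if self.design_df < 1:
            raise DesignError("design df < 1: need more PSUs than strata")
        singles = counts[counts < 2]
        if len(singles) > 0:
            raise DesignError(
                f"strata with a single PSU: {list(singles.index)}; "
                "pass collapse=True to merge them with a neighbouring stratum"
            )

    @staticmethod
    def _collapse_single_psu(strata, psus):
        counts = pd.DataFrame({"h": strata, "c": psus}).drop_duplicates().groupby("h").size()
        singles = sorted(counts[counts < 2].index)
        if not singles:
            return strata
        order = sorted(counts.index)
        relabel = {}
        for h in singles:
            pos = order.index(h)
            target = order[pos + 1] if pos + 1 < len(order) else order[pos - 1]
            relabel[h] = target
        warnings.warn(f"collapsing single-PSU strata: {relabel}")
        return np.asarray([relabel.get(h, h) for h in strata])

    @classmethod
    def from_dataset(cls, ds: SurveyDataset, collapse: bool = False) -> "SurveyDesign":
        return cls(ds.strata, ds.psus, ds.weights, collapse=collapse)

    @classmethod
    def independent(cls, n: int, weights=None) -> "SurveyDesign":
        """Degenerate design: one stratum, every record its own PSU."""
        w = np.ones(n) if weights is None else weights
        return cls(np.zeros(n, dtype=int), np.arange(n), w)


# ---------------------------------------------------------------------------
# design matrices


def _interaction_parts(term: str) -> list[str]:
    return term.split(":")


def build_design_matrix(values: pd.DataFrame, terms, add_intercept: bool = True) -> pd.DataFrame:
    """Assemble columns for main-effect and ``a:b`` product terms."""
    cols = {}
    if add_intercept:
        cols["const"] = np.ones(len(values))
    for term in terms:
        parts = _interaction_parts(term)
        for p in parts:
            if p not in values.columns:
                raise ConfigurationError(f"unknown predictor column {p!r}")
        x = values[parts[0]].to_numpy(dtype=float).copy()
        for p in parts[1:]:
            x = x * values[p].to_numpy(dtype=float)
        cols[term] = x
    return pd.DataFrame(cols, index=values.index)


# ---------------------------------------------------------------------------
# IRLS pseudo-MLE


def _irls(X, y, w, tol=1e-10, max_iter=100):
    """Weighted logistic IRLS.  Returns (beta, XtWX at solution)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = w * p * (1 - p)
        score = X.T @ (w * (y - p))
        A = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(A, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(A + 1e-10 * np.eye(k), score)
        new = beta + step
        if np.abs(new).max() > 15:
            j = int(np.abs(new).argmax())
            raise SeparationError(f"separation suspected: |beta| > 15 for term index {j}")
        if np.abs(step).max() < tol:
            beta = new
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            A = (X * (w * p * (1 - p))[:, None]).T @ X
            return beta, A, p
        beta = new
    raise ConvergenceError("IRLS failed to converge in %d iterations" % max_iter,
                           last_iterate=beta)


def _psu_total_cov(u: np.ndarray, strata: np.ndarray, psus: np.ndarray) -> np.ndarray:
    """Between-PSU covariance of score totals with the n_h/(n_h-1) factor.

    ``u`` holds per-record score (or linearized) contributions; rows outside
    the analysis domain must already be zero.  All PSUs of the full design
    contribute, which is what makes domain estimation design-consistent.
    """
    k = u.shape[1]
    G = np.zeros((k, k))
    df = pd.DataFrame({"h": strata, "c": psus})
    for h, idx in df.groupby("h").groups.items():
        idx = np.asarray(idx)
        sub = pd.DataFrame(u[idx])
        sub["c"] = psus[idx]
        totals = sub.groupby("c").sum().to_numpy()
        n_h = totals.shape[0]
        if n_h < 2:
            continue  # guarded at SurveyDesign construction
        dev = totals - totals.mean(axis=0)
        G += (n_h / (n_h - 1)) * dev.T @ dev
    return G


class SurveyLogit:
    """Survey-weighted logistic regression model.

    Parameters
    ----------
    endog : array-like of 0/1
    exog : pandas.DataFrame
        Design matrix including any intercept column.
    design : SurveyDesign, optional
        Defaults to the degenerate independent design (one stratum, one PSU
        per record, unit weights), under which the estimator reduces to the
        ordinary logistic MLE with a robust sandwich variance.
    subpop : boolean array, optional
        Domain indicator.  Estimation uses only domain records; variance
        estimation zeroes out-of-domain score contributions while keeping
        every PSU, the standard design-consistent domain estimator.
    """

    def __init__(self, endog, exog: pd.DataFrame, design: SurveyDesign | None = None,
                 subpop=None):
        self.exog = pd.DataFrame(exog)
        self.endog = np.asarray(endog, dtype=float)
        n = len(self.endog)
        if len(self.exog) != n:
            raise ConfigurationError("endog and exog lengths differ")
        self.design = design if design is not None else SurveyDesign.independent(n)
        if len(self.design.weights) != n:
            raise ConfigurationError("design size does not match data")
        self.subpop = (np.ones(n, dtype=bool) if subpop is None
                       else np.asarray(subpop, dtype=bool))

    @classmethod
    def from_dataset(cls, ds: SurveyDataset, terms, subpop=None,
                     design: SurveyDesign | None = None) -> "SurveyLogit":
        if design is None and ds.has_design:
            design = SurveyDesign.from_dataset(ds)
        exog = build_design_matrix(ds.values, terms)
        return cls(ds.outcome, exog, design=design, subpop=subpop)

    def fit(self, tol: float = 1e-10, max_iter: int = 100) -> "SurveyLogitResults":
        X_full = self.exog.to_numpy(dtype=float)
        y_full = self.endog
        # complete cases within the domain
        usable = self.subpop & ~np.isnan(X_full).any(axis=1) & ~np.isnan(y_full)
        if usable.sum() == 0:
            raise ConfigurationError("no usable records in the analysis domain")
        yd = y_full[usable]
        if len(np.unique(yd)) < 2:
            raise ConfigurationError("analysis domain contains a single outcome class")
        Xd = X_full[usable]
        const_cols = np.nanstd(Xd, axis=0) == 0
        names = list(self.exog.columns)
        for j, c in enumerate(const_cols):
            if c and names[j] != "const":
                raise ConfigurationError(f"term {names[j]!r} is constant in the domain")
        w = self.design.weights
        beta, A, p_d = _irls(Xd, yd, w[usable], tol=tol, max_iter=max_iter)

        score = Xd.T @ (w[usable] * (yd - p_d))
        assert np.abs(score).max() < 1e-5 * max(1.0, np.abs(w[usable]).sum()), \
            "weighted score not zero at solution"

        # per-record score contributions, zero outside the domain
        u = np.zeros((len(y_full), Xd.shape[1]))
        u[usable] = (w[usable] * (yd - p_d))[:, None] * Xd
        G = _psu_total_cov(u, self.design.strata, self.design.psus)
        Ainv = np.linalg.inv(A)
        V = Ainv @ G @ Ainv
        V = (V + V.T) / 2
        eig = np.linalg.eigvalsh(V)
        assert eig.min() >= -1e-10 * max(1.0, eig.max()), "covariance not PSD"

        fitted = np.full(len(y_full), np.nan)
        fitted[usable] = p_d
        return SurveyLogitResults(
            model=self,
            params=pd.Series(beta, index=self.exog.columns),
            cov=pd.DataFrame(V, index=self.exog.columns, columns=self.exog.columns),
            design_df=self.design.design_df,
            n_used=int(usable.sum()),
            usable=usable,
            fitted=fitted,
        )


@dataclass
class SurveyLogitResults:
    """Design-based logistic fit: coefficients, linearized covariance, t inference."""

    model: SurveyLogit
    params: pd.Series
    cov: pd.DataFrame
    design_df: int
    n_used: int
    usable: np.ndarray
    fitted: np.ndarray
    converged: bool = True

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), df=self.design_df),
            index=self.params.index,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = stats.t.ppf(1 - alpha / 2, df=self.design_df)
        lo = self.params - tcrit * self.bse
        hi = self.params + tcrit * self.bse
        return pd.DataFrame({"low": lo, "high": hi})

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Odds-ratio scale table: OR, SE(OR), p, CI bounds."""
        ci = self.conf_int(alpha)
        orr = np.exp(self.params)
        return pd.DataFrame(
            {
                "odds_ratio": orr,
                "std_err": orr * self.bse,  # delta method on the OR scale
                "p_value": self.pvalues,
                "ci_low": np.exp(ci["low"]),
                "ci_high": np.exp(ci["high"]),
            }
        )


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass
class PooledFit:
    """Rubin-pooled estimates across m imputations with Barnard-Rubin df."""

    params: pd.Series          # pooled coefficients (Qbar)
    within: pd.Series          # W, mean squared SE
    between: pd.Series         # B
    total: pd.Series           # T = W + (1+1/m) B
    df: pd.Series              # per-term pooled degrees of freedom
    m: int
    complete_data_df: float

    @property
    def bse(self) -> pd.Series:
        return np.sqrt(self.total)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), df=self.df),
            index=self.params.index,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = pd.Series(stats.t.ppf(1 - alpha / 2, df=self.df), index=self.params.index)
        return pd.DataFrame({"low": self.params - tcrit * self.bse,
                             "high": self.params + tcrit * self.bse})

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        orr = np.exp(self.params)
        return pd.DataFrame(
            {
                "odds_ratio": orr,
                "std_err": orr * self.bse,
                "p_value": self.pvalues,
                "ci_low": np.exp(ci["low"]),
                "ci_high": np.exp(ci["high"]),
            }
        )


def pool_rubin(fits, complete_data_df: float) -> PooledFit:
    """Pool m survey-logistic fits with Rubin's rules.

    Qbar = mean coefficient; W = mean squared SE; B = between-imputation
    variance; T = W + (1 + 1/m) B.  Degrees of freedom follow the
    Barnard-Rubin small-sample adjustment anchored at ``complete_data_df``
    (for survey data, conventionally the design df).
    """
    fits = list(fits)
    m = len(fits)
    if m == 0:
        raise ConfigurationError("no fits to pool")
    index = fits[0].params.index
    for f in fits[1:]:
        if not f.params.index.equals(index):
            raise ConfigurationError("fits have mismatched term sets")
    Q = np.stack([f.params.to_numpy() for f in fits])
    U = np.stack([f.bse.to_numpy() ** 2 for f in fits])
    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    if m == 1:
        B = np.zeros_like(qbar)
        T = W
        df = np.full_like(qbar, float(complete_data_df))
    else:
        B = Q.var(axis=0, ddof=1)
        T = W + (1 + 1 / m) * B
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (1 + 1 / m) * B / W
            # r = 0 gives nu_large = inf and df -> nu_obs, the Barnard-Rubin limit
            rinv = np.where(r > 0, 1.0 / r, np.inf)
            nu_large = (m - 1) * (1 + rinv) ** 2
            nu_obs = ((complete_data_df + 1) / (complete_data_df + 3)
                      * complete_data_df / (1 + r))
            df = 1.0 / (1.0 / nu_large + 1.0 / nu_obs)
    return PooledFit(
        params=pd.Series(qbar, index=index),
        within=pd.Series(W, index=index),
        between=pd.Series(B, index=index),
        total=pd.Series(T, index=index),
        df=pd.Series(df, index=index),
        m=m,
        complete_data_df=float(complete_data_df),
    )


# ---------------------------------------------------------------------------
# design-adjusted goodness of fit


@dataclass
class GofResult:
    """F-corrected Wald test of zero mean residual in probability groups."""

    statistic: float
    df_num: int
    df_den: int
    p_value: float
    n_groups: int
    group_means: np.ndarray = field(repr=False, default=None)


def _weighted_quantile_groups(p, w, g):
    """Assign records to g groups by weighted quantiles of predicted probability."""
    order = np.argsort(p, kind="mergesort")
    cw = np.cumsum(w[order]) - 0.5 * w[order]
    frac = cw / w.sum()
    grp = np.minimum((frac * g).astype(int), g - 1)
    out = np.empty(len(p), dtype=int)
    out[order] = grp
    return out


def gof_design_adjusted(results: SurveyLogitResults, g: int = 10) -> GofResult:
    """Design-adjusted goodness-of-fit test for a survey logistic fit.

    Records are grouped into ``g`` weighted quantile groups of predicted
    probability; the weighted mean residual of the first g-1 groups (the last
    is redundant because residuals sum to ~0) is tested jointly with a Wald
    statistic whose covariance comes from Taylor linearization of the group
    ratio means, converted to an F statistic on (g-1, design_df - g + 2)
    degrees of freedom.
    """
    if g < 2:
        raise ConfigurationError("need at least 2 groups")
    design = results.model.design
    d = results.design_df
    if d - g + 2 < 1:
        raise ConfigurationError("design df too small for this many groups")
    usable = results.usable
    p = results.fitted[usable]
    y = results.model.endog[usable]
    w = design.weights[usable]
    r = y - p
    grp = _weighted_quantile_groups(p, w, g)
    counts = np.bincount(grp, minlength=g)
    if (counts == 0).any():
        g_new = int((counts > 0).sum())
        warnings.warn(f"empty probability group; reducing g from {g} to {g_new}")
        return gof_design_adjusted(results, g_new)

    k = g - 1
    means = np.empty(g)
    Wk = np.empty(g)
    for j in range(g):
        sel = grp == j
        Wk[j] = w[sel].sum()
        means[j] = np.sum(w[sel] * r[sel]) / Wk[j]

    # linearized contributions for the first g-1 group means
    n_full = len(results.usable)
    z = np.zeros((n_full, k))
    idx_usable = np.where(usable)[0]
    for j in range(k):
        sel = grp == j
        z[idx_usable[sel], j] = w[sel] * (r[sel] - means[j]) / Wk[j]
    G = _psu_total_cov(z, design.strata, design.psus)
    m = means[:k]
    try:
        sol = np.linalg.solve(G, m)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(G + 1e-12 * np.trace(G) / k * np.eye(k), m)
    wald = float(m @ sol)
    F = (d - k + 1) / (d * k) * wald
    df_num, df_den = k, d - k + 1
    pval = float(stats.f.sf(F, df_num, df_den))
    return GofResult(statistic=F, df_num=df_num, df_den=df_den, p_value=pval,
                     n_groups=g, group_means=means)
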