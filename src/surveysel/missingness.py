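"""Missingness diagnostics: indicator association tests and Little's MCAR test.

Two complementary checks of whether imputation is warranted:

* per-variable missing-indicator logistic regressions on the study outcome
  (design-based when design columns are present) — a significant association
  says missingness depends on the outcome, i.e. the data are not MCAR with
  respect to it;
* Little's chi-squared test, which compares pattern-wise observed means to
  EM-estimated grand means under multivariate normality and rejects MCAR
  globally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SurveyDataset
from .exceptions import ConvergenceError
from .survey import SurveyDesign, SurveyLogit

__all__ = ["MissingnessReport", "LittleResult", "missing_indicator_tests", "littles_mcar_test"]


@dataclass
class LittleResult:
    d2: float
    df: int
    p_value: float
    n_iter: int
    converged: bool
    loglik: float


@dataclass
class MissingnessReport:
    """Per-variable indicator tests plus (optionally) Little's global test."""

    indicator_table: pd.DataFrame
    little: LittleResult | None = None

    def to_json(self) -> str:
        import json

        out = {"indicator_tests": self.indicator_table.reset_index().to_dict("records")}
        if self.little is not None:
            out["little"] = {
                "d2": self.little.d2,
                "df": self.little.df,
                "p_value": self.little.p_value,
                "n_iter": self.little.n_iter,
                "converged": self.little.converged,
            }
        return json.dumps(out, indent=2, default=float)


def missing_indicator_tests(ds: SurveyDataset) -> MissingnessReport:
    """Regress each predictor's missingness indicator on the study outcome.

    Uses the survey design when present, otherwise ordinary logistic
    regression (via the same pseudo-MLE with a degenerate design).  Variables
    with no missing cells — or with every cell missing, where the indicator
    is constant — are reported as not applicable.
    """
    design = SurveyDesign.from_dataset(ds) if ds.has_design else None
    rows = []
    y = ds.outcome
    for name in ds.predictor_names:
        observed = ds.mask[name].to_numpy()
        frac = 1.0 - observed.mean()
        row = {"variable": name, "frac_missing": frac, "estimate": np.nan,
               "se": np.nan, "p_value": np.nan, "applicable": False}
        if 0 < frac < 1:
            indicator = (~observed).astype(float)
            exog = pd.DataFrame({"const": np.ones(ds.n), "outcome": y})
            try:
                res = SurveyLogit(indicator, exog, design=design).fit()
                row.update(
                    estimate=res.params["outcome"],
                    se=res.bse["outcome"],
                    p_value=res.pvalues["outcome"],
                    applicable=True,
                )
            except Exception as exc:  # degenerate fits stay not-applicable
                row["note"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("variable")
    table = table[table["frac_missing"] > 0] if len(table) else table
    return MissingnessReport(indicator_table=table)


# ---------------------------------------------------------------------------
# Little's MCAR test


def _pattern_groups(mask: np.ndarray):
    """Group row indices by missingness pattern (rows with >=1 observed cell)."""
    keys = [tuple(row) for row in mask]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items() if any(k)}


def _safe_inv(S, ridge_scale=1e-10):
    try:
        return np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance sub-block; ridge-stabilized inverse used")
        k = S.shape[0]
        return np.linalg.inv(S + ridge_scale * np.trace(S) / k * np.eye(k))


def _em_mvnorm(Y, mask, tol, max_iter):
    """EM for the mean and covariance of a multivariate normal with missing cells.

    Returns (mu, sigma, loglik, n_iter, ll_trace).  The observed-data
    log-likelihood is asserted non-decreasing at every iteration.
    """
    n, p = Y.shape
    complete = mask.all(axis=1)
    if complete.sum() >= 10:
        mu = Y[complete].mean(axis=0)
        sigma = np.cov(Y[complete], rowvar=False, ddof=0)
    else:  # available-case moments
        Y0 = np.where(mask, Y, np.nan)
        mu = np.nanmean(Y0, axis=0)
        sigma = pd.DataFrame(Y0).cov(ddof=0).to_numpy()
        sigma = np.where(np.isnan(sigma), 0.0, sigma)
    sigma = sigma + 1e-8 * np.eye(p)

    groups = _pattern_groups(mask)
    n_eff = sum(len(idx) for idx in groups.values())  # rows with >=1 observed cell
    prev_ll = -np.inf
    ll = -np.inf
    for it in range(1, max_iter + 1):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        ll = 0.0
        for pattern, idx in groups.items():
            obs = np.asarray(pattern)
            o = np.where(obs)[0]
            m = np.where(~obs)[0]
            Yo = Y[np.ix_(idx, o)]
            Soo = sigma[np.ix_(o, o)]
            Soo_inv = _safe_inv(Soo)
            dev = Yo - mu[o]
            sign, logdet = np.linalg.slogdet(Soo)
            ll += (-0.5 * len(idx) * (len(o) * np.log(2 * np.pi) + logdet)
                   - 0.5 * np.einsum("ij,jk,ik->", dev, Soo_inv, dev))
            Yfull = np.zeros((len(idx), p))
            Yfull[:, o] = Yo
            if len(m) > 0:
                B = sigma[np.ix_(m, o)] @ Soo_inv
                Yfull[:, m] = mu[m] + dev @ B.T
                C = sigma[np.ix_(m, m)] - B @ sigma[np.ix_(o, m)]
                S2[np.ix_(m, m)] += len(idx) * C
            S1 += Yfull.sum(axis=0)
            S2 += Yfull.T @ Yfull
        assert ll >= prev_ll - 1e-8 * (abs(prev_ll) + 1), "EM log-likelihood decreased"
        mu_new = S1 / n_eff
        sigma_new = S2 / n_eff - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2
        converged = (prev_ll > -np.inf
                     and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12))
        mu, sigma = mu_new, sigma_new
        prev_ll = ll
        if converged:
            return mu, sigma, ll, it, True
    raise ConvergenceError(f"EM did not converge in {max_iter} iterations",
                           last_iterate=(mu, sigma))


def littles_mcar_test(values, mask=None, tol: float = 1e-8,
                      max_iter: int = 500) -> LittleResult:
    """Little's MCAR chi-squared test.

    ``values`` is an n x p numeric table (DataFrame or array) whose missing
    cells are NaN, or an explicit boolean ``mask`` may be given.  The grand
    mean and covariance are estimated by EM under multivariate normality;
    records are grouped by missingness pattern j (n_j records, p_j observed
    columns) and

        d^2 = sum_j n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j)

    restricted to pattern-j observed coordinates, with df = sum_j p_j - p.
    Under MCAR, d^2 is asymptotically chi-squared(df).  Complete data (a
    single all-observed pattern) yields d^2 = 0 with df = 0.
    """
    Y = np.asarray(pd.DataFrame(values), dtype=float)
    if mask is None:
        mask = ~np.isnan(Y)
    else:
        mask = np.asarray(mask, dtype=bool)
    Y = np.where(mask, Y, 0.0)
    n, p = Y.shape
    mu, sigma, ll, n_iter, converged = _em_mvnorm(Y, mask, tol, max_iter)
    d2 = 0.0
    df = -p
    for pattern, idx in _pattern_groups(mask).items():
        o = np.where(np.asarray(pattern))[0]
        df += len(o)
        ybar = Y[np.ix_(idx, o)].mean(axis=0)
        dev = ybar - mu[o]
        d2 += len(idx) * float(dev @ _safe_inv(sigma[np.ix_(o, o)]) @ dev)
    df = max(df, 0)
    p_value = float(stats.chi2.sf(d2, df)) if df > 0 else 1.0
    return LittleResult(d2=float(d2), df=int(df), p_value=p_value,
                        n_iter=n_iter, converged=converged, loglik=float(ll))
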