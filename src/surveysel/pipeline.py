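"""Confirmatory selection stages and the full three-step pipeline.

Stage order: missingness diagnostics -> chained imputation -> boosted-tree
importance screening -> survey-weighted univariate screen on training and
validation halves -> collinearity and mediation elimination -> final pooled
multivariate model with confounder covariates and screened interactions.
Two baseline comparators are provided for validation studies: backward
stepwise logistic regression and L1-penalized (lasso) selection frequency
across imputations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boost import BoostConfig
from .dataset import SurveyDataset, split_train_validation
from .exceptions import ConfigurationError, SeparationError
from .importance import SelectionRule, importance_across_datasets, select_by_importance
from .mice import ChainedImputer, ImputationConfig, MultipleImputation
from .missingness import littles_mcar_test, missing_indicator_tests
from .survey import SurveyDesign, SurveyLogit, pool_rubin

__all__ = [
    "PipelineConfig", "SelectionReport", "BaselineResult",
    "univariate_screen", "collinearity_check", "mediation_check",
    "fit_final_model", "backward_stepwise_logistic", "l1_selection_frequency",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# pooled fitting helper


def _pooled_fit(mi: MultipleImputation, terms, subpop=None):
    """Fit each completed copy and pool with Rubin's rules.

    ``subpop`` is a set/array of record ids defining the analysis domain.
    The complete-data df for the Barnard-Rubin adjustment is the design df.
    """
    fits = []
    for ds in mi.completed:
        ind = None
        if subpop is not None:
            ind = ds.values.index.isin(subpop)
        design = SurveyDesign.from_dataset(ds) if ds.has_design else None
        fits.append(SurveyLogit.from_dataset(ds, terms, subpop=ind, design=design).fit())
    return pool_rubin(fits, complete_data_df=fits[0].design_df)


# ---------------------------------------------------------------------------
# stage operations


def univariate_screen(mi: MultipleImputation, candidates, train_ids, val_ids,
                      alpha: float = 0.05):
    """Pooled univariate survey fits on both halves; keep p <= alpha in both.

    Boundary equality counts as significant, so a candidate sitting exactly
    at the threshold in one half is retained.  Fit failures exclude the
    candidate with the reason recorded.
    """
    if len(list(candidates)) == 0:
        raise ConfigurationError("no candidates to screen")
    rows = []
    selected = []
    for cand in candidates:
        row = {"variable": cand}
        try:
            tr = _pooled_fit(mi, [cand], subpop=train_ids)
            va = _pooled_fit(mi, [cand], subpop=val_ids)
            s_tr, s_va = tr.summary().loc[cand], va.summary().loc[cand]
            row.update(
                train_or=s_tr["odds_ratio"], train_p=s_tr["p_value"],
                val_or=s_va["odds_ratio"], val_p=s_va["p_value"],
            )
            keep = s_tr["p_value"] <= alpha and s_va["p_value"] <= alpha
            row["decision"] = "selected" if keep else "not significant in both halves"
            if keep:
                selected.append(cand)
        except Exception as exc:
            row["decision"] = f"fit failure: {exc}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable"), selected


def _weighted_corr(values: pd.DataFrame, weights: np.ndarray, cols) -> pd.DataFrame:
    X = values[list(cols)].to_numpy(dtype=float)
    w = weights / weights.sum()
    mu = w @ X
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    return pd.DataFrame(cov / np.outer(sd, sd), index=cols, columns=cols)


def collinearity_check(mi: MultipleImputation, variables, r_threshold: float = 0.95,
                       importance: pd.DataFrame | None = None):
    """Flag near-singular pairs and keep the more important member.

    Pairwise weighted correlations are averaged over the completed copies.
    From each flagged pair the member with lower mean importance is dropped;
    with chained collinearity this resolves transitively by importance rank.
    Without an importance table, rank falls back to the given variable order.
    """
    variables = list(variables)
    if len(variables) < 2:
        return [], variables
    acc = None
    for ds in mi.completed:
        R = _weighted_corr(ds.values, ds.weights, variables)
        acc = R if acc is None else acc + R
    R = acc / mi.m
    if importance is not None:
        rank = {v: -float(importance.loc[v, "mean"]) for v in variables}
    else:
        rank = {v: i for i, v in enumerate(variables)}
    ordered = sorted(variables, key=lambda v: rank[v])
    retained, flagged = [], []
    for v in ordered:
        clash = [u for u in retained if abs(R.loc[v, u]) >= r_threshold]
        if clash:
            flagged.append({"dropped": v, "kept": clash[0],
                            "r": float(R.loc[v, clash[0]])})
        else:
            retained.append(v)
    retained = [v for v in variables if v in retained]  # original order
    return flagged, retained


def mediation_check(mi: MultipleImputation, variables, alpha: float = 0.05,
                    corr_threshold: float = 0.3):
    """Detect full mediation among the candidate set and drop mediated drivers.

    X is declared fully mediated by M when (i) X is significant univariately,
    (ii) in the joint model {X, M} X loses significance while M keeps it, and
    (iii) X and M are associated (|pooled weighted correlation| >= the
    threshold).  Circular verdicts (each mediating the other) drop neither
    and are flagged for manual review.
    """
    variables = list(variables)
    if len(variables) < 2:
        return [], variables
    uni = {}
    for v in variables:
        uni[v] = _pooled_fit(mi, [v]).pvalues[v]
    acc = None
    for ds in mi.completed:
        R = _weighted_corr(ds.values, ds.weights, variables)
        acc = R if acc is None else acc + R
    R = acc / mi.m

    mediated_by: dict[str, list] = {v: [] for v in variables}
    for x in variables:
        if uni[x] > alpha:
            continue  # not univariately significant: nothing to mediate
        for mvar in variables:
            if mvar == x or abs(R.loc[x, mvar]) < corr_threshold:
                continue
            try:
                joint = _pooled_fit(mi, [x, mvar])
            except Exception:
                continue
            if joint.pvalues[x] > alpha and joint.pvalues[mvar] <= alpha:
                mediated_by[x].append(mvar)

    triples, dropped, circular = [], set(), set()
    for x, meds in mediated_by.items():
        for mvar in meds:
            if x in mediated_by.get(mvar, []):
                circular.update((x, mvar))
                triples.append({"driver": x, "mediator": mvar, "action": "flagged-circular"})
            else:
                triples.append({"driver": x, "mediator": mvar, "action": "drop"})
                dropped.add(x)
    dropped -= circular
    retained = [v for v in variables if v not in dropped]
    return triples, retained


def fit_final_model(mi: MultipleImputation, biomarkers, covariates=(),
                    interaction_candidates=(), alpha: float = 0.05, subpop=None):
    """Pooled confounder-adjusted model with one-at-a-time interaction screen.

    Each candidate interaction term (``cov:bio`` product) is added to the
    base model alone and retained when its pooled p-value reaches ``alpha``;
    the final joint model refits with all retained interactions.  If the
    joint model fails to converge the weakest retained interaction is
    dropped and the fit retried.
    """
    biomarkers = list(biomarkers)
    if not biomarkers:
        raise ConfigurationError("no biomarkers for the final model")
    base_terms = biomarkers + list(covariates)
    retained = []
    pvals = {}
    for term in interaction_candidates:
        try:
            fit = _pooled_fit(mi, base_terms + [term], subpop=subpop)
            pvals[term] = float(fit.pvalues[term])
            if pvals[term] <= alpha:
                retained.append(term)
        except Exception as exc:
            warnings.warn(f"interaction screen failed for {term!r}: {exc}")
    while True:
        try:
            final = _pooled_fit(mi, base_terms + retained, subpop=subpop)
            break
        except Exception as exc:
            if not retained:
                raise
            weakest = max(retained, key=lambda t: pvals.get(t, 1.0))
            warnings.warn(f"joint model failed ({exc}); dropping {weakest!r}")
            retained.remove(weakest)
    return final, retained


# ---------------------------------------------------------------------------
# baselines


def backward_stepwise_logistic(X: pd.DataFrame, y, alpha_remove: float = 0.05):
    """Backward elimination on ordinary logistic regression.

    Repeatedly removes the highest-p term while its p exceeds
    ``alpha_remove``; returns the surviving column names.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    while cols:
        exog = sm.add_constant(X[cols], has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, exog).fit(disp=0)
        except Exception as exc:
            raise SeparationError(f"stepwise logistic fit failed: {exc}") from exc
        p = res.pvalues.drop("const")
        worst = p.idxmax()
        if p[worst] > alpha_remove:
            cols.remove(worst)
        else:
            break
    return cols


@dataclass
class BaselineResult:
    """Per-dataset selections of a baseline method and their frequencies."""

    method: str
    selected_sets: list
    frequency: pd.Series
    config: dict = field(default_factory=dict)


def l1_selection_frequency(mi: MultipleImputation, split_fraction: float = 0.6,
                           penalty_grid=None, seed: int = 0,
                           predictors=None) -> BaselineResult:
    """Lasso-logistic selection frequency over original + imputed datasets.

    For each dataset: predictors are standardized, rows split
    ``split_fraction``/(1-``split_fraction``) into train/test, the penalty
    minimizing held-out deviance is chosen from the (decreasing) grid, and
    the variables with non-zero coefficients are recorded.  The frequency of
    selection across the m+1 datasets is the baseline importance measure.
    The original dataset enters through its complete cases.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss

    if penalty_grid is None:
        penalty_grid = np.geomspace(0.5, 1e-4, 12)
    penalty_grid = np.asarray(penalty_grid, dtype=float)
    if (np.diff(penalty_grid) >= 0).any() or (penalty_grid <= 0).any():
        raise ConfigurationError("penalty_grid must be decreasing positive reals")

    predictors = predictors if predictors is not None else mi.original.predictor_names
    datasets = [mi.original] + list(mi.completed)
    rng = np.random.default_rng(seed)
    selected_sets = []
    counts = pd.Series(0, index=predictors, dtype=int)
    for ds in datasets:
        sub = ds.values[predictors + [ds.outcome_name]].dropna()
        X = sub[predictors].to_numpy(dtype=float)
        y = sub[ds.outcome_name].to_numpy(dtype=float)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
        n = len(y)
        perm = rng.permutation(n)
        n_tr = int(round(split_fraction * n))
        tr, te = perm[:n_tr], perm[n_tr:]
        best = (np.inf, None)
        for lam in penalty_grid:
            C = 1.0 / (lam * n_tr)
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=2000, tol=1e-7)
            try:
                clf.fit(X[tr], y[tr])
            except Exception:
                continue
            dev = log_loss(y[te], clf.predict_proba(X[te])[:, 1], labels=[0, 1])
            if dev < best[0]:
                best = (dev, clf)
        if best[1] is None:
            selected_sets.append(None)
            continue
        nz = np.abs(best[1].coef_.ravel()) > 1e-8
        chosen = [predictors[j] for j in range(len(predictors)) if nz[j]]
        selected_sets.append(chosen)
        counts[chosen] += 1
    return BaselineResult(
        method="l1_selection_frequency",
        selected_sets=selected_sets,
        frequency=counts,
        config={"split_fraction": split_fraction, "seed": seed,
                "penalty_grid": penalty_grid.tolist()},
    )


# ---------------------------------------------------------------------------
# the full pipeline


@dataclass
class PipelineConfig:
    """One configuration object driving the full three-step run."""

    m: int = 20
    burn_in: int = 10
    boost: BoostConfig = field(default_factory=BoostConfig)
    cutoff_pct: float = 2.0
    alpha: float = 0.05
    r_threshold: float = 0.95
    mediation_corr_threshold: float = 0.3
    split_fraction: float = 0.5
    covariates: tuple = ()
    interaction_candidates: tuple = ()
    seed: int = 0


@dataclass
class SelectionReport:
    """Stage-by-stage record of which variables survived each filter and why."""

    initial_candidates: list
    diagnostics: dict
    importance_summary: pd.DataFrame
    importance_selected: list
    screen_table: pd.DataFrame
    screened: list
    collinear_flagged: list
    collinear_retained: list
    mediation_triples: list
    mediation_retained: list
    final_terms: list
    retained_interactions: list
    final_summary: pd.DataFrame
    config: PipelineConfig
    seeds: dict

    def removals(self) -> dict:
        """Stage at which each importance-selected variable was removed."""
        out = {}
        for v in self.importance_selected:
            if v in self.final_terms:
                out[v] = "final model"
            elif v not in self.screened:
                out[v] = "univariate screen"
            elif v not in self.collinear_retained:
                out[v] = "collinearity"
            elif v not in self.mediation_retained:
                out[v] = "mediation"
            else:
                out[v] = "final model"
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "initial_candidates": self.initial_candidates,
                "diagnostics": self.diagnostics,
                "importance_selected": self.importance_selected,
                "screen": self.screen_table.reset_index().to_dict("records"),
                "screened": self.screened,
                "collinear_flagged": self.collinear_flagged,
                "collinear_retained": self.collinear_retained,
                "mediation_triples": self.mediation_triples,
                "mediation_retained": self.mediation_retained,
                "final_terms": self.final_terms,
                "retained_interactions": self.retained_interactions,
                "final_summary": self.final_summary.reset_index().to_dict("records"),
                "seeds": self.seeds,
            },
            indent=2,
            default=float,
        )


def run_pipeline(ds: SurveyDataset, config: PipelineConfig | None = None) -> SelectionReport:
    """Execute the full three-step selection on one dataset.

    All stage seeds derive from ``config.seed``, so re-running with the same
    dataset and configuration is bit-identical.
    """
    cfg = config if config is not None else PipelineConfig()
    ss = np.random.SeedSequence(cfg.seed)
    seed_imp, seed_split, seed_boost = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)
    )
    seeds = {"imputation": seed_imp, "split": seed_split, "boost": seed_boost}

    # Step 1: diagnostics + imputation
    diagnostics: dict = {}
    any_missing = not ds.mask[ds.predictor_names].to_numpy().all()
    if any_missing:
        ind = missing_indicator_tests(ds)
        diagnostics["indicator_tests"] = ind.indicator_table.reset_index().to_dict("records")
        pred_vals = ds.values[ds.predictor_names]
        n_patterns = ds.mask[ds.predictor_names].drop_duplicates().shape[0]
        if n_patterns >= 2:
            little = littles_mcar_test(pred_vals)
            diagnostics["little"] = {"d2": little.d2, "df": little.df,
                                     "p_value": little.p_value}
    mi = ChainedImputer(
        ds, ImputationConfig(m=cfg.m, burn_in=cfg.burn_in, seed=seed_imp)
    ).fit()

    # participant-level split shared by every completed copy
    train_ids, val_ids = split_train_validation(ds, cfg.split_fraction, seed_split)

    # Step 2: importance screening
    boost_cfg = replace(cfg.boost, seed=seed_boost)
    im = importance_across_datasets(mi, boost_cfg)
    imp_selected, _rationale = select_by_importance(im, SelectionRule(cfg.cutoff_pct))
    summary = im.summary()

    # Step 3: univariate screen, collinearity, mediation, final model
    screen_table, screened = univariate_screen(
        mi, imp_selected, train_ids, val_ids, alpha=cfg.alpha
    )
    flagged, col_retained = collinearity_check(
        mi, screened, r_threshold=cfg.r_threshold, importance=summary
    )
    triples, med_retained = mediation_check(
        mi, col_retained, alpha=cfg.alpha, corr_threshold=cfg.mediation_corr_threshold
    )
    final, interactions = fit_final_model(
        mi, med_retained, covariates=cfg.covariates,
        interaction_candidates=cfg.interaction_candidates, alpha=cfg.alpha,
    )
    final_biomarkers = [v for v in med_retained if final.pvalues[v] <= cfg.alpha]

    return SelectionReport(
        initial_candidates=ds.predictor_names,
        diagnostics=diagnostics,
        importance_summary=summary,
        importance_selected=imp_selected,
        screen_table=screen_table,
        screened=screened,
        collinear_flagged=flagged,
        collinear_retained=col_retained,
        mediation_triples=triples,
        mediation_retained=med_retained,
        final_terms=final_biomarkers,
        retained_interactions=interactions,
        final_summary=final.summary(),
        config=cfg,
        seeds=seeds,
    )
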