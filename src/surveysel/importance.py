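"""Boosted-tree importance across imputed datasets and the inclusion rule.

Runs the booster on the original (incomplete) dataset and on each completed
imputation, assembles the variables x datasets importance matrix, and
applies the inclusion rule: a variable enters the candidate set when its
importance in the original dataset exceeds the cutoff (strictly), or its
mean importance across the imputations reaches the cutoff.  The default
cutoff of 2% is deliberately inclusive — the goal of this stage is to drop
clearly uninformative variables while retaining a majority of the total
relative importance for the confirmatory regression stage.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boost import BernoulliBoost, BoostConfig
from .exceptions import ConfigurationError
from .mice import MultipleImputation

__all__ = ["ImportanceMatrix", "SelectionRule", "importance_across_datasets",
           "select_by_importance", "coverage", "load_biomarker_importance"]


@dataclass
class SelectionRule:
    """Inclusion cutoff in importance percentage points (default 2)."""

    cutoff_pct: float = 2.0

    def __post_init__(self):
        if self.cutoff_pct <= 0:
            raise ConfigurationError("cutoff_pct must be positive")


class ImportanceMatrix:
    """Variables x datasets table of importance percentages.

    Column ``original`` holds the incomplete-data run; ``imp1`` .. ``impm``
    the runs on completed copies.  Every complete column sums to 100.
    """

    def __init__(self, matrix: pd.DataFrame, failures: dict | None = None):
        self.matrix = matrix
        self.failures = failures or {}
        for c in matrix.columns:
            col = matrix[c]
            if col.notna().all() and abs(col.sum() - 100.0) > 1e-6 and col.sum() > 0:
                raise ConfigurationError(f"importance column {c!r} does not sum to 100")

    @property
    def complete(self) -> bool:
        return not self.failures

    @property
    def imputation_columns(self) -> list[str]:
        return [c for c in self.matrix.columns if c != "original"]

    def summary(self) -> pd.DataFrame:
        """Per-variable original value plus mean/SD/min/max over imputations."""
        imp = self.matrix[self.imputation_columns]
        return pd.DataFrame(
            {
                "original": self.matrix["original"],
                "mean": imp.mean(axis=1),
                "sd": imp.std(axis=1, ddof=1) if imp.shape[1] > 1 else 0.0,
                "min": imp.min(axis=1),
                "max": imp.max(axis=1),
            }
        )


def importance_across_datasets(mi: MultipleImputation, cfg: BoostConfig,
                               predictors=None) -> ImportanceMatrix:
    """One boosted model per dataset (original + each imputation).

    Per-dataset seeds are derived as ``cfg.seed + dataset_index`` so each
    run is independently reproducible.  Boosting failures are recorded and
    leave an all-NaN column rather than aborting.
    """
    from dataclasses import replace

    datasets = [("original", mi.original)] + [
        (f"imp{k}", ds) for k, ds in enumerate(mi.completed, start=1)
    ]
    predictors = predictors if predictors is not None else mi.original.predictor_names
    cols = {}
    failures = {}
    for idx, (name, ds) in enumerate(datasets):
        run_cfg = replace(cfg, seed=cfg.seed + idx)
        try:
            res = BernoulliBoost(ds.outcome, ds.values[predictors], run_cfg).fit()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                imp = res.variable_importance()
            if imp.sum() == 0:  # stopped at the constant model: no splits
                raise ConfigurationError("no retained splits; importance undefined")
            cols[name] = imp
        except Exception as exc:
            failures[name] = str(exc)
            cols[name] = pd.Series(np.nan, index=predictors)
    if failures:
        warnings.warn(f"boosting failed for datasets: {sorted(failures)}")
    return ImportanceMatrix(pd.DataFrame(cols), failures)


def select_by_importance(importance, rule: SelectionRule = SelectionRule()):
    """Apply the inclusion rule; returns (selected names, rationale table).

    ``importance`` is an :class:`ImportanceMatrix` or a summary frame with
    ``original`` and ``mean`` columns.  A variable is selected iff its
    original importance strictly exceeds the cutoff OR its mean importance
    across imputations is at least the cutoff (the asymmetry is part of the
    rule).  The rationale records which clause fired.
    """
    summ = importance.summary() if isinstance(importance, ImportanceMatrix) else importance
    if summ.isna().any().any():
        raise ConfigurationError("importance matrix incomplete; cannot select")
    orig_clause = summ["original"] > rule.cutoff_pct
    mean_clause = summ["mean"] >= rule.cutoff_pct
    rationale = pd.DataFrame(
        {
            "original": summ["original"],
            "mean": summ["mean"],
            "original_clause": orig_clause,
            "mean_clause": mean_clause,
            "selected": orig_clause | mean_clause,
        }
    )
    selected = list(rationale.index[rationale["selected"]])
    return selected, rationale


def coverage(importance, selected):
    """Share of total importance captured by the selected set.

    Returns ``(original_pct, mean_pct)``: the sums of the selected
    variables' original-column and mean importances.
    """
    summ = importance.summary() if isinstance(importance, ImportanceMatrix) else importance
    unknown = [v for v in selected if v not in summ.index]
    if unknown:
        raise ConfigurationError(f"selected variables not in matrix: {unknown}")
    sel = summ.loc[list(selected)]
    return float(sel["original"].sum()), float(sel["mean"].sum())


def load_biomarker_importance() -> pd.DataFrame:
    """Worked-example importance summary for a 67-biomarker depression screen.

    A transcription of a published relative-importance table (original
    incomplete dataset plus mean/SD/min/max over 20 imputations) from a
    large NHANES-based depression study; used to exercise the inclusion rule
    without refitting anything.
    """
    ref = importlib.resources.files("surveysel") / "datasets" / "biomarker_importance.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, index_col="biomarker")
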