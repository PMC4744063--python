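"""Survey dataset container, column-role configuration, exclusions and splits.

The central object is :class:`SurveyDataset`: a participants x variables table
with an explicit observed-cell mask, per-variable metadata (kind and role),
and optional complex-survey design columns (weight, stratum, primary sampling
unit).  Missing cells are stored as NaN; the boolean mask is authoritative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigurationError,
    DegenerateSplitError,
    EmptyDatasetError,
    ParseError,
)

VALID_KINDS = ("continuous", "binary")
VALID_ROLES = ("outcome", "predictor", "covariate", "weight", "stratum", "psu", "id", "group")
#: roles whose columns may never contain a missing cell
COMPLETE_ROLES = ("outcome", "weight", "stratum", "psu", "id")


@dataclass(frozen=True)
class VariableMeta:
    """Name, measurement kind, and analysis role of one column."""

    name: str
    kind: str
    role: str

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ConfigurationError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.role not in VALID_ROLES:
            raise ConfigurationError(f"unknown role {self.role!r} for {self.name!r}")


@dataclass
class ExclusionReport:
    """Accounting of record exclusions: every input row lands in exactly one bucket."""

    n_input: int
    n_excluded_missing: int
    n_excluded_outlier: int
    n_final: int
    reasons: dict = field(default_factory=dict)  # record id -> reason string

    def __post_init__(self):
        if self.n_input != self.n_excluded_missing + self.n_excluded_outlier + self.n_final:
            raise ValueError("exclusion report does not account for every record")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_excluded_missing": self.n_excluded_missing,
                "n_excluded_outlier": self.n_excluded_outlier,
                "n_final": self.n_final,
                "reasons": {str(k): v for k, v in self.reasons.items()},
            },
            indent=2,
        )


class SurveyDataset:
    """Rectangular participants x variables table with design metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric table, one row per participant; NaN marks missing cells.
        The index holds the unique record identifiers.
    meta : sequence of VariableMeta
        One entry per used column of ``values``.
    mask : pandas.DataFrame of bool, optional
        True where a cell is observed.  Defaults to ``values.notna()``;
        when given it must agree with the NaN pattern (the mask is
        authoritative, so disagreement is an error rather than silently
        resolved).
    """

    def __init__(self, values: pd.DataFrame, meta, mask: pd.DataFrame | None = None):
        meta = list(meta)
        names = [m.name for m in meta]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate variable names in metadata")
        missing_cols = [n for n in names if n not in values.columns]
        if missing_cols:
            raise ConfigurationError(f"metadata names absent from table: {missing_cols}")
        values = values[names].astype(float).copy()
        if not values.index.is_unique:
            raise ConfigurationError("record identifiers must be unique")
        if mask is None:
            mask = values.notna()
        else:
            mask = mask[names].astype(bool).copy()
            if not (mask.to_numpy() == values.notna().to_numpy()).all():
                raise ConfigurationError("mask disagrees with NaN pattern of values")
        self.values = values
        self.mask = mask
        self.meta = {m.name: m for m in meta}
        self._validate()

    # -- role helpers ------------------------------------------------------
    def _names_with_role(self, role: str) -> list[str]:
        return [n for n, m in self.meta.items() if m.role == role]

    @property
    def outcome_name(self) -> str:
        return self._names_with_role("outcome")[0]

    @property
    def predictor_names(self) -> list[str]:
        return self._names_with_role("predictor")

    @property
    def covariate_names(self) -> list[str]:
        return self._names_with_role("covariate")

    @property
    def group_name(self) -> str | None:
        g = self._names_with_role("group")
        return g[0] if g else None

    def _single_role_col(self, role: str) -> str | None:
        cols = self._names_with_role(role)
        return cols[0] if cols else None

    @property
    def weight_name(self):
        return self._single_role_col("weight")

    @property
    def stratum_name(self):
        return self._single_role_col("stratum")

    @property
    def psu_name(self):
        return self._single_role_col("psu")

    @property
    def has_design(self) -> bool:
        return self.stratum_name is not None and self.psu_name is not None

    @property
    def ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def outcome(self) -> np.ndarray:
        return self.values[self.outcome_name].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        if self.weight_name is None:
            return np.ones(self.n)
        return self.values[self.weight_name].to_numpy()

    @property
    def strata(self) -> np.ndarray:
        if self.stratum_name is None:
            return np.zeros(self.n, dtype=int)
        return self.values[self.stratum_name].to_numpy().astype(int)

    @property
    def psus(self) -> np.ndarray:
        if self.psu_name is None:
            return np.arange(self.n)
        return self.values[self.psu_name].to_numpy().astype(int)

    @property
    def design_df(self) -> int:
        """Design degrees of freedom: distinct stratum-PSU pairs minus strata."""
        pairs = set(zip(self.strata.tolist(), self.psus.tolist()))
        strata = set(self.strata.tolist())
        return len(pairs) - len(strata)

    # -- validation --------------------------------------------------------
    def _validate(self):
        outcomes = self._names_with_role("outcome")
        if len(outcomes) != 1:
            raise ConfigurationError(f"need exactly one outcome column, found {len(outcomes)}")
        if self.meta[outcomes[0]].kind != "binary":
            raise ConfigurationError("outcome must be binary")
        for role in ("weight", "stratum", "psu", "id", "group"):
            if len(self._names_with_role(role)) > 1:
                raise ConfigurationError(f"role {role!r} assigned to more than one column")
        for role in COMPLETE_ROLES:
            for name in self._names_with_role(role):
                if not self.mask[name].all():
                    raise ConfigurationError(f"{role} column {name!r} contains missing cells")
        y = self.values[outcomes[0]]
        if not y.isin([0.0, 1.0]).all():
            raise ConfigurationError("outcome values must be 0/1")
        if self.weight_name is not None and (self.values[self.weight_name] <= 0).any():
            raise ConfigurationError("weights must be strictly positive")
        if self.has_design and self.design_df < 1:
            raise ConfigurationError("design df < 1: need more PSUs than strata")
        for name, m in self.meta.items():
            if m.kind == "binary" and m.role in ("predictor", "covariate", "group"):
                col = self.values[name].dropna()
                if not col.isin([0.0, 1.0]).all() and m.role != "group":
                    raise ConfigurationError(f"binary column {name!r} has values outside 0/1")

    # -- construction / serialisation -------------------------------------
    def config_dict(self) -> dict:
        return {n: {"role": m.role, "kind": m.kind} for n, m in self.meta.items()}

    def replace_values(self, values: pd.DataFrame) -> "SurveyDataset":
        """Return a new dataset with the same metadata and fresh values."""
        return SurveyDataset(values, list(self.meta.values()))

    def subset(self, ids) -> "SurveyDataset":
        return self.replace_values(self.values.loc[list(ids)])

    def copy(self) -> "SurveyDataset":
        return self.replace_values(self.values.copy())

    def write_csv(self, path) -> None:
        """Emit the table as CSV with a ``_row_id`` column; missing cells empty."""
        out = self.values.copy()
        out.insert(0, "_row_id", self.values.index)
        out.to_csv(path, index=False)


def _load_config(config_path) -> dict:
    with open(config_path) as fh:
        text = fh.read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError("column-role config must map column -> {role, kind}")
    if "columns" in cfg and isinstance(cfg["columns"], dict):
        cfg = cfg["columns"]
    return cfg


#: default kind by role for design/bookkeeping columns left unspecified
_DEFAULT_KIND = {
    "weight": "continuous",
    "stratum": "continuous",
    "psu": "continuous",
    "id": "continuous",
    "outcome": "binary",
    "group": "binary",
}


def read_dataset(table_path, config_path) -> SurveyDataset:
    """Read a CSV table and a YAML/JSON column-role config into a SurveyDataset.

    Empty cells and the literal strings ``NA``/``NaN`` are treated as missing.
    Columns not named in the config are ignored; row order is preserved.
    """
    cfg = _load_config(config_path)
    raw = pd.read_csv(table_path, na_values=["NA", "NaN"], keep_default_na=True, dtype=str,
                      skipinitialspace=True)
    meta = []
    id_col = None
    for name, entry in cfg.items():
        if not isinstance(entry, dict) or "role" not in entry:
            raise ConfigurationError(f"config entry for {name!r} must provide a role")
        role = entry["role"]
        kind = entry.get("kind", _DEFAULT_KIND.get(role, "continuous"))
        if name not in raw.columns:
            raise ConfigurationError(f"configured column {name!r} absent from table")
        if role == "id":
            id_col = name
            continue
        meta.append(VariableMeta(name=name, kind=kind, role=role))
    if not any(m.role == "outcome" for m in meta):
        raise ConfigurationError("config assigns no outcome role")

    used = [m.name for m in meta]
    values = pd.DataFrame(index=raw.index)
    for name in used:
        col = raw[name]
        parsed = pd.to_numeric(col, errors="coerce")
        bad = parsed.isna() & col.notna() & (col.str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"non-numeric value {col[row]!r} in column {name!r}, row {row}"
            )
        values[name] = parsed
    if id_col is not None:
        values.index = pd.Index(raw[id_col].to_numpy(), name=id_col)
    return SurveyDataset(values, meta)


# ---------------------------------------------------------------------------
# exclusions


def robust_outlier_rule(k: float = 8.0):
    """Flag records holding any predictor value beyond ``k`` robust SDs.

    The robust SD of a column is MAD/0.6745 computed from observed cells;
    a record is flagged when any observed predictor cell deviates from the
    column median by more than ``k`` robust SDs.  Intended for gross outliers
    that destabilise imputation, hence the conservative default ``k=8``.
    """

    def rule(ds: SurveyDataset) -> np.ndarray:
        flags = np.zeros(ds.n, dtype=bool)
        for name in ds.predictor_names:
            col = ds.values[name].to_numpy()
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                continue
            med = np.median(obs)
            mad = np.median(np.abs(obs - med))
            robust_sd = mad / 0.6745
            if robust_sd <= 0:
                continue
            with np.errstate(invalid="ignore"):
                flags |= np.abs(col - med) > k * robust_sd
        return flags

    return rule


def apply_exclusions(ds: SurveyDataset, max_missing: int, outlier_rule=None):
    """Drop records with >= ``max_missing`` missing predictor cells, then outliers.

    Returns the filtered dataset and an :class:`ExclusionReport` accounting for
    every removal.  ``outlier_rule`` is a callable mapping the (already
    missing-filtered) dataset to a boolean flag array; it defaults to off.
    """
    if max_missing < 0:
        raise ConfigurationError("max_missing must be >= 0")
    pred_mask = ds.mask[ds.predictor_names].to_numpy()
    n_missing = (~pred_mask).sum(axis=1)
    keep_missing = n_missing < max_missing
    reasons = {}
    for rid, nm in zip(ds.ids[~keep_missing], n_missing[~keep_missing]):
        reasons[rid] = f"missing {int(nm)} predictor cells (threshold {max_missing})"
    stage1 = ds.subset(ds.ids[keep_missing]) if keep_missing.any() else None
    if stage1 is None:
        raise EmptyDatasetError("all records excluded by the missing-count filter")

    n_outlier = 0
    final = stage1
    if outlier_rule is not None:
        flags = np.asarray(outlier_rule(stage1), dtype=bool)
        n_outlier = int(flags.sum())
        for rid in stage1.ids[flags]:
            reasons[rid] = "outlier rule"
        if flags.all():
            raise EmptyDatasetError("all records excluded by the outlier rule")
        final = stage1.subset(stage1.ids[~flags])

    report = ExclusionReport(
        n_input=ds.n,
        n_excluded_missing=int((~keep_missing).sum()),
        n_excluded_outlier=n_outlier,
        n_final=final.n,
        reasons=reasons,
    )
    return final, report


# ---------------------------------------------------------------------------
# train/validation split


def split_train_validation(ds: SurveyDataset, fraction: float, seed: int):
    """Participant-level split stratified on the outcome.

    Returns ``(train_ids, validation_ids)`` as sorted arrays forming a
    partition of all record ids.  Within each outcome level the assignment is
    a seeded permutation, so prevalence is balanced across the halves and the
    same ids land in the same half of every imputed copy.
    """
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    y = ds.outcome
    ids = ds.ids
    train, val = [], []
    for level in np.unique(y):
        level_ids = ids[y == level]
        perm = rng.permutation(level_ids)
        n_train = int(round(fraction * len(level_ids)))
        train.extend(perm[:n_train])
        val.extend(perm[n_train:])
    train = np.sort(np.asarray(train))
    val = np.sort(np.asarray(val))
    for half, label in ((train, "training"), (val, "validation")):
        yh = ds.values.loc[half, ds.outcome_name]
        if len(half) == 0 or yh.nunique() < 2:
            raise DegenerateSplitError(f"{label} half lacks both outcome classes")
    return train, val
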