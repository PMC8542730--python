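"""Cohort preparation: eligibility exclusions, complete-case filtering,
rhythm stratification and encoding of the prespecified baseline variables
into a typed feature matrix.

The analysis is restricted to heart failure with reduced ejection fraction
(LVEF < 50%) and to patients with an interpretable baseline ECG rhythm;
atrial flutter is analysed with atrial fibrillation.  Clustering features are
baseline-only: randomised arm, vital status and follow-up never enter the
feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: the 13 clustering features (order is the FeatureMatrix column order)
FEATURE_SCHEMA: tuple[tuple[str, str], ...] = (
    ("age", "continuous"),
    ("female", "binary"),
    ("bmi", "continuous"),
    ("heart_rate", "continuous"),
    ("sbp", "continuous"),
    ("lvef", "continuous"),
    ("prior_mi", "binary"),
    ("nyha_34", "binary"),
    ("creatinine", "continuous"),
    ("acei_arb", "binary"),
    ("diuretic", "binary"),
    ("anticoagulant", "binary"),
    ("digoxin", "binary"),
)

#: raw table columns the complete-case rule inspects by default
DEFAULT_COMPLETE_CASE_VARS = (
    "age",
    "gender",
    "bmi",
    "heart_rate",
    "sbp",
    "lvef",
    "prior_mi",
    "nyha",
    "creatinine",
    "acei_arb",
    "diuretic",
    "anticoagulant",
    "digoxin",
)


@dataclass
class FeatureMatrix:
    """Encoded design matrix with a typed column schema.

    ``values`` is complete (no NaN); binary columns are exactly {0, 1};
    continuous columns are standardised with the stratum's own mean/SD,
    retained in ``scaling_params`` as ``name -> (centre, spread)``.
    ``index`` carries the patient ids so cluster labels can be joined back.
    """

    values: np.ndarray
    schema: tuple[tuple[str, str], ...]
    scaling_params: Mapping[str, tuple[float, float]]
    index: pd.Index

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.schema]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column_kinds(self) -> np.ndarray:
        return np.array([k for _, k in self.schema])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names, index=self.index)


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the eligibility rules and return (filtered table, count report).

    Removes LVEF >= 50%, missing-ECG / paced / other rhythms; relabels atrial
    flutter as AF.  Idempotent.
    """
    report: dict[str, int] = {"input": len(table)}
    out = table.copy()

    # NaN LVEF is left to the complete-case rule, not excluded here
    lvef_excl = out["lvef"].ge(50.0)
    report["lvef_ge_50"] = int(lvef_excl.sum())
    out = out[~lvef_excl]

    rhythm = out["rhythm"].astype("object").where(out["rhythm"].notna(), "missing")
    rhythm = rhythm.replace({"flutter": "AF"})
    bad_rhythm = ~rhythm.isin(["SR", "AF"])
    report["rhythm_excluded"] = int(bad_rhythm.sum())
    out = out[~bad_rhythm].copy()
    out["rhythm"] = rhythm[~bad_rhythm]

    report["output"] = len(out)
    if len(out) == 0:
        import warnings

        warnings.warn("all rows excluded", stacklevel=2)
    return out, report


def complete_case_filter(
    table: pd.DataFrame, variables: Sequence[str] = DEFAULT_COMPLETE_CASE_VARS
) -> tuple[pd.DataFrame, dict]:
    """Drop rows with any missing value among ``variables``.

    The report counts missingness per variable and the overall number of rows
    removed (rows missing several variables are counted once overall).
    """
    for v in variables:
        if v not in table.columns:
            raise KeyError(f"unknown variable {v!r}")
    if not variables:
        return table.copy(), {"removed": 0, "per_variable": {}}
    missing = table[list(variables)].isna()
    per_var = {v: int(missing[v].sum()) for v in variables}
    drop = missing.any(axis=1)
    report = {
        "removed": int(drop.sum()),
        "per_variable": per_var,
        "multi_variable": int((missing.sum(axis=1) > 1).sum()),
    }
    return table[~drop].copy(), report


def stratify_by_rhythm(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (sinus rhythm, atrial fibrillation) tables."""
    sr = table[table["rhythm"] == "SR"].copy()
    af = table[table["rhythm"] == "AF"].copy()
    return sr, af


def _derive_feature_columns(table: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(index=table.index)
    for name, _kind in FEATURE_SCHEMA:
        if name == "female":
            df[name] = (table["gender"] == "female").astype(float)
        elif name == "nyha_34":
            df[name] = table["nyha"].isin([3, 4]).astype(float)
        else:
            df[name] = pd.to_numeric(table[name], errors="raise").astype(float)
    return df


def encode_features(
    table: pd.DataFrame,
    scaling_params: Mapping[str, tuple[float, float]] | None = None,
) -> FeatureMatrix:
    """Encode the prespecified baseline variables into a FeatureMatrix.

    Continuous variables are standardised to zero mean / unit SD using the
    stratum's own statistics (population SD, ddof=0), or with externally
    supplied ``scaling_params`` (used when projecting a held-out trial onto a
    reference stratum).  NYHA is binarised to III-or-IV, gender to
    female=1.
    """
    df = _derive_feature_columns(table)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in feature columns {bad}; "
                         "run complete_case_filter first")
    scaling: dict[str, tuple[float, float]] = {}
    for name, kind in FEATURE_SCHEMA:
        if kind != "continuous":
            continue
        if scaling_params is not None:
            centre, spread = scaling_params[name]
        else:
            if len(df) < 2:
                raise ValueError("need at least 2 rows to estimate spread")
            centre = float(df[name].mean())
            spread = float(df[name].std(ddof=0))
            if spread == 0.0:
                raise ValueError(f"zero spread in continuous column {name!r}")
        if spread <= 0.0:
            raise ValueError(f"non-positive spread for column {name!r}")
        df[name] = (df[name] - centre) / spread
        scaling[name] = (centre, spread)
    return FeatureMatrix(
        values=df.to_numpy(dtype=float),
        schema=FEATURE_SCHEMA,
        scaling_params=scaling,
        index=table.index,
    )


def prepare_stratum(
    table: pd.DataFrame, stratum: str
) -> tuple[pd.DataFrame, FeatureMatrix, dict]:
    """Exclusions + complete cases + stratification + encoding in one call."""
    excluded, report = apply_exclusions(table)
    complete, cc_report = complete_case_filter(excluded)
    sr, af = stratify_by_rhythm(complete)
    sub = {"SR": sr, "AF": af}[stratum]
    features = encode_features(sub)
    report = {"exclusions": report, "complete_case": cc_report,
              "stratum": stratum, "n_stratum": len(sub)}
    return sub, features, report
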