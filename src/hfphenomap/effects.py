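"""Per-cluster intention-to-treat effect estimation from 2x2 mortality tables.

For each cluster the patients are split by randomised arm and all-cause
deaths are counted; the module computes the crude odds ratio with a Woolf
(log-OR) 95% confidence interval, the crude risk ratio, the absolute risk
reduction (ARR) with a Wald interval, the number needed to treat
(NNT = 1/ARR, reported only when the ARR interval excludes zero), a
two-tailed Pearson chi-square p-value, and — when follow-up times are
available — annualised mortality per 100 person-years.

A Haldane-Anscombe correction (0.5 added to every cell) is applied to the
ratio estimates if and only if some cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "odds_ratio",
    "risk_ratio",
    "arr_nnt",
    "annualised_mortality",
    "cluster_effect_table",
    "effects_from_counts",
    "load_reference_counts",
]

_Z = 1.959963984540054  # 97.5% normal quantile


@dataclass(frozen=True)
class TwoByTwo:
    """Mortality counts for one cluster: deaths / randomised per arm."""

    deaths_bb: int
    n_bb: int
    deaths_placebo: int
    n_placebo: int

    def __post_init__(self) -> None:
        for deaths, n in ((self.deaths_bb, self.n_bb),
                          (self.deaths_placebo, self.n_placebo)):
            if n <= 0:
                raise ValueError("each arm needs at least one patient")
            if not 0 <= deaths <= n:
                raise ValueError("deaths must be between 0 and n")

    def cells(self) -> tuple[float, float, float, float]:
        """(a, b, c, d) = (deaths bb, alive bb, deaths placebo, alive placebo),
        Haldane-corrected iff any cell is zero."""
        a = float(self.deaths_bb)
        b = float(self.n_bb - self.deaths_bb)
        c = float(self.deaths_placebo)
        d = float(self.n_placebo - self.deaths_placebo)
        if min(a, b, c, d) == 0.0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return a, b, c, d

    def swap_arms(self) -> "TwoByTwo":
        return TwoByTwo(self.deaths_placebo, self.n_placebo,
                        self.deaths_bb, self.n_bb)


def odds_ratio(t: TwoByTwo) -> tuple[float, tuple[float, float], float]:
    """Crude odds ratio with Woolf 95% CI and chi-square p (no continuity
    correction).  Returns (or, (lo, hi), p)."""
    if t.deaths_bb == 0 and t.deaths_placebo == 0:
        return float("nan"), (float("nan"), float("nan")), float("nan")
    a, b, c, d = t.cells()
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - _Z * se)
    hi = math.exp(math.log(or_) + _Z * se)
    table = np.array([[t.deaths_bb, t.n_bb - t.deaths_bb],
                      [t.deaths_placebo, t.n_placebo - t.deaths_placebo]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        p = float("nan")
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return or_, (lo, hi), float(p)


def risk_ratio(t: TwoByTwo) -> tuple[float, tuple[float, float]]:
    """Crude risk ratio with log-RR 95% CI (Haldane rule on zero cells)."""
    if t.deaths_bb == 0 and t.deaths_placebo == 0:
        return float("nan"), (float("nan"), float("nan"))
    if t.deaths_bb == 0 or t.deaths_placebo == 0:
        a = t.deaths_bb + 0.5
        c = t.deaths_placebo + 0.5
        n1, n0 = t.n_bb + 1.0, t.n_placebo + 1.0
    else:
        a, c = float(t.deaths_bb), float(t.deaths_placebo)
        n1, n0 = float(t.n_bb), float(t.n_placebo)
    rr = (a / n1) / (c / n0)
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    lo = math.exp(math.log(rr) - _Z * se)
    hi = math.exp(math.log(rr) + _Z * se)
    return rr, (lo, hi)


def arr_nnt(t: TwoByTwo) -> tuple[float, tuple[float, float], float]:
    """Absolute risk reduction (placebo risk - bb risk) with Wald CI, and
    NNT = 1/ARR, NaN (not applicable) unless the ARR interval excludes 0."""
    p1 = t.deaths_bb / t.n_bb
    p0 = t.deaths_placebo / t.n_placebo
    arr = p0 - p1
    se = math.sqrt(p1 * (1 - p1) / t.n_bb + p0 * (1 - p0) / t.n_placebo)
    lo, hi = arr - _Z * se, arr + _Z * se
    significant = lo > 0.0 or hi < 0.0
    nnt = 1.0 / arr if (significant and arr != 0.0) else float("nan")
    return arr, (lo, hi), nnt


def annualised_mortality(deaths: int, person_years: float) -> float:
    """Deaths per 100 person-years of follow-up."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 100.0 * deaths / person_years


def _effect_row(cluster_id, t: TwoByTwo, person_years: float | None) -> dict:
    or_, or_ci, p = odds_ratio(t)
    rr, rr_ci = risk_ratio(t)
    arr, arr_ci, nnt = arr_nnt(t)
    row = {
        "cluster": cluster_id,
        "deaths_placebo": t.deaths_placebo,
        "n_placebo": t.n_placebo,
        "deaths_bb": t.deaths_bb,
        "n_bb": t.n_bb,
        "risk_placebo": t.deaths_placebo / t.n_placebo,
        "risk_bb": t.deaths_bb / t.n_bb,
        "or": or_, "or_lo": or_ci[0], "or_hi": or_ci[1],
        "rr": rr, "rr_lo": rr_ci[0], "rr_hi": rr_ci[1],
        "arr": arr, "arr_lo": arr_ci[0], "arr_hi": arr_ci[1],
        "nnt": nnt, "p_value": p,
    }
    if person_years is not None:
        deaths = t.deaths_bb + t.deaths_placebo
        row["annualised_mortality"] = annualised_mortality(deaths, person_years)
    return row


def cluster_effect_table(
    table: pd.DataFrame,
    labels: np.ndarray,
    cluster_names: dict | None = None,
) -> pd.DataFrame:
    """One effect row per cluster (canonical order) plus an overall row.

    ``table`` needs columns ``arm`` (bb/placebo) and ``death``; if
    ``followup_years`` is present annualised mortality is added.  Clusters
    whose population is confined to a single arm are flagged with NaN
    estimates.
    """
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("labels must cover every row of the table")
    has_fu = "followup_years" in table.columns
    arm = table["arm"].to_numpy()
    death = table["death"].to_numpy().astype(int)
    fu = table["followup_years"].to_numpy() if has_fu else None

    def counts(mask: np.ndarray):
        bb = mask & (arm == "bb")
        pl = mask & (arm == "placebo")
        if bb.sum() == 0 or pl.sum() == 0:
            return None, None
        t = TwoByTwo(
            deaths_bb=int(death[bb].sum()), n_bb=int(bb.sum()),
            deaths_placebo=int(death[pl].sum()), n_placebo=int(pl.sum()),
        )
        py = float(fu[mask].sum()) if has_fu else None
        return t, py

    rows = []
    for cl in np.unique(labels):
        name = cluster_names.get(cl, cl) if cluster_names else cl
        t, py = counts(labels == cl)
        if t is None:
            rows.append({"cluster": name, "flag": "single-arm cluster"})
            continue
        rows.append(_effect_row(name, t, py))
    t, py = counts(np.ones(len(table), dtype=bool))
    rows.append(_effect_row("all", t, py))
    return pd.DataFrame(rows)


def effects_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Effect table from a bare counts table (columns: cluster, deaths_bb,
    n_bb, deaths_placebo, n_placebo)."""
    rows = []
    for _, r in counts.iterrows():
        t = TwoByTwo(int(r["deaths_bb"]), int(r["n_bb"]),
                     int(r["deaths_placebo"]), int(r["n_placebo"]))
        rows.append(_effect_row(r["cluster"], t, None))
    return pd.DataFrame(rows)


def load_reference_counts() -> pd.DataFrame:
    """Published per-cluster all-cause mortality counts from the pooled
    nine-trial beta-blocker heart-failure dataset (sinus-rhythm clusters
    SR1-SR6 and atrial-fibrillation clusters AF1-AF5, plus stratum totals)."""
    with resources.files("hfphenomap").joinpath(
        "data/reference_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)
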