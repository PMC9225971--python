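"""Annual habitat budgets with Gaussian error propagation and scenarios.

Period fluxes are summarised per habitat as plain means with standard errors
(SD/sqrt(n)); the annual rate is the sum of the five period means and its
uncertainty follows by Gaussian error propagation, ``se = sqrt(sum se_i^2)``,
treating period means as independent.  95% confidence intervals use the
normal quantile z = 1.96.  The net balance (delta) of a nutrient is annual
import minus annual export; a negative delta is a net removal from the
habitat.  Deposition scenarios weigh delta against an atmospheric input, the
conservative variant using the upper CI limit of delta (the smallest net
export compatible with the data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dung import DomainError, dung_quantity_table
from .ingest import SurveyDataset

Z95 = 1.96


@dataclass(frozen=True)
class PeriodSummary:
    """Mean, SE and contributing-plot count of one habitat x period variable."""

    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class AnnualRate:
    """An annual rate (kg ha^-1 a^-1) with propagated SE and 95% CI."""

    mean: float
    se: float
    ci_lo: float
    ci_hi: float

    @classmethod
    def from_mean_se(cls, mean: float, se: float, z: float = Z95) -> "AnnualRate":
        return cls(mean, se, mean - z * se, mean + z * se)


@dataclass(frozen=True)
class DepositionScenario:
    """Net nutrient input under a given atmospheric deposition rate.

    ``net_input = deposition + delta`` (delta negative when grazing export
    exceeds excretal import); the conservative variant replaces delta by the
    upper limit of its 95% CI.
    """

    deposition: float
    net_input: float
    conservative_net_input: float


def se_from_ci(ci_lo: float, ci_hi: float, z: float = Z95) -> float:
    """Back-compute a standard error from a symmetric CI: (hi - lo) / (2 z)."""
    if ci_hi < ci_lo:
        raise DomainError("CI upper limit below lower limit")
    return (ci_hi - ci_lo) / (2.0 * z)


def summarize_period(values: Iterable[float]) -> PeriodSummary:
    """Mean, SE (sample SD / sqrt(n)) and n over one habitat x period.

    Missing values are excluded and reduce n; they never enter as zero.  A
    single observation yields SE 0 with a warning (no spread information).
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        warnings.warn("no non-missing values; period summary is missing",
                      stacklevel=2)
        return PeriodSummary(float("nan"), float("nan"), 0)
    if n == 1:
        warnings.warn("single observation; SE set to 0", stacklevel=2)
        return PeriodSummary(float(arr[0]), 0.0, 1)
    return PeriodSummary(float(arr.mean()),
                         float(arr.std(ddof=1) / np.sqrt(n)), n)


def annualize(summaries: Sequence[PeriodSummary], z: float = Z95) -> AnnualRate:
    """Sum period means into an annual rate; propagate SEs in quadrature.

    Requires one non-missing summary per period (the annual rate is undefined
    otherwise).  Order of periods does not matter.
    """
    if any(s.n == 0 or np.isnan(s.mean) for s in summaries):
        raise DomainError("annual rate undefined: a period summary is missing")
    mean = float(sum(s.mean for s in summaries))
    se = float(np.sqrt(sum(s.se ** 2 for s in summaries)))
    return AnnualRate.from_mean_se(mean, se, z)


def net_balance(imp: AnnualRate, exp: AnnualRate, z: float = Z95) -> AnnualRate:
    """Delta = annual import - annual export, SE = sqrt(se_i^2 + se_e^2)."""
    delta = imp.mean - exp.mean
    se = float(np.sqrt(imp.se ** 2 + exp.se ** 2))
    return AnnualRate.from_mean_se(delta, se, z)


def np_export_ratio(delta_n: float, delta_p: float) -> float:
    """Ratio of net N to net P export, |delta_N| / |delta_P|, to one decimal."""
    if pd.isna(delta_p) or delta_p == 0:
        warnings.warn("net P balance is zero/missing; N:P ratio undefined",
                      stacklevel=2)
        return float("nan")
    return round(abs(delta_n) / abs(delta_p), 1)


def deposition_scenario(delta: AnnualRate, deposition: float) -> DepositionScenario:
    """Weigh the net balance against an atmospheric deposition rate."""
    if deposition < 0:
        raise DomainError("deposition must be non-negative")
    return DepositionScenario(
        deposition=deposition,
        net_input=deposition + delta.mean,
        conservative_net_input=deposition + delta.ci_hi,
    )


def fraction_of_production(net_removal: float, production_pool: float) -> float:
    """|net removal| as a fraction of the nutrient in annual aboveground biomass."""
    if production_pool <= 0:
        raise DomainError("production pool must be positive")
    return abs(net_removal) / production_pool


# ---------------------------------------------------------------------------
# Habitat-level tables
# ---------------------------------------------------------------------------

#: Budget variables, as (column in the flux table, nutrient) pairs.
BUDGET_VARIABLES = (
    ("faecal_N_import", "faecal_import", "N"),
    ("total_N_import", "total_import", "N"),
    ("N_export", "export", "N"),
    ("P_import", "faecal_import", "P"),
    ("P_export", "export", "P"),
)


def period_summary_table(flux: pd.DataFrame) -> pd.DataFrame:
    """Per habitat x period x variable means, SEs and n (plots pooled over
    treatments; missing plots reduce n)."""
    rows = []
    for habitat, hab in flux.groupby("habitat", sort=False):
        for name, col, nutrient in BUDGET_VARIABLES:
            sub = hab[hab["nutrient"] == nutrient]
            for period, per in sub.groupby("period"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    s = summarize_period(per[col])
                rows.append({"habitat": habitat, "variable": name,
                             "period": period, "mean": s.mean,
                             "se": s.se, "n": s.n})
    return pd.DataFrame(rows)


def annual_budget_table(flux: pd.DataFrame, z: float = Z95) -> pd.DataFrame:
    """Annual import/export/delta per habitat and nutrient, with SE and CI.

    One row per habitat x variable; variables cover faecal N import, total N
    import (faecal + urinary), N export, delta_N (total import - export),
    P import, P export and delta_P, mirroring the budget-table layout of
    grazing nutrient-balance studies.
    """
    summaries = period_summary_table(flux)
    rows = []
    for habitat, hab in summaries.groupby("habitat", sort=False):
        annual: dict[str, AnnualRate] = {}
        for name, _, _ in BUDGET_VARIABLES:
            sub = hab[hab["variable"] == name].sort_values("period")
            per_summaries = [PeriodSummary(r["mean"], r["se"], int(r["n"]))
                             for _, r in sub.iterrows()]
            annual[name] = annualize(per_summaries, z)
        annual["delta_N"] = net_balance(annual["total_N_import"],
                                        annual["N_export"], z)
        annual["delta_P"] = net_balance(annual["P_import"],
                                        annual["P_export"], z)
        for name, est in annual.items():
            rows.append({"habitat": habitat, "variable": name,
                         "mean": est.mean, "se": est.se,
                         "ci_lo": est.ci_lo, "ci_hi": est.ci_hi})
    return pd.DataFrame(rows)


def dung_summary_table(ds: SurveyDataset, z: float = Z95) -> pd.DataFrame:
    """Habitat-level dung statistics: mean corrected pellet-group count per
    plot and date, and annual imported dung dry mass (kg ha^-1) with SE."""
    dq = dung_quantity_table(ds)
    rows = []
    for habitat, hab in dq.groupby("habitat", sort=False):
        pg = hab["pg_cor"].dropna()
        per_summaries = []
        for _, per in hab.groupby("period"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_summaries.append(summarize_period(per["mass_kg_ha"]))
        annual = annualize(per_summaries, z)
        rows.append({
            "habitat": habitat,
            "mean_pg_cor": float(pg.mean()),
            "se_pg_cor": float(pg.std(ddof=1) / np.sqrt(len(pg))),
            "annual_dung_kg_ha": annual.mean,
            "annual_dung_se": annual.se,
        })
    return pd.DataFrame(rows)


def scenario_table(budget: pd.DataFrame, deposition_n: float,
                   deposition_p: float = 0.3) -> pd.DataFrame:
    """Deposition scenarios per habitat for N and P from a budget table."""
    rows = []
    for habitat, hab in budget.groupby("habitat", sort=False):
        hab = hab.set_index("variable")
        for nutrient, dep in (("N", deposition_n), ("P", deposition_p)):
            d = hab.loc[f"delta_{nutrient}"]
            est = AnnualRate(d["mean"], d["se"], d["ci_lo"], d["ci_hi"])
            sc = deposition_scenario(est, dep)
            rows.append({"habitat": habitat, "nutrient": nutrient,
                         "deposition": dep, "delta": est.mean,
                         "net_input": sc.net_input,
                         "conservative_net_input": sc.conservative_net_input})
    return pd.DataFrame(rows)
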