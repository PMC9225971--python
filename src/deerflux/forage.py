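"""Forage removal and period-level nutrient concentrations.

Forage removal by grazers is the difference between the biomass increment of
vegetation temporarily protected under a movable exclusion cage and the
increment on the surrounding, continuously grazed plot over the same period.
Standing biomass itself can be derived from rising-plate meter readings of
compressed sward height via a linear calibration against cut quadrats.

Nutrient concentrations (% dry mass) change over a sampling period, so every
flux computation uses the mean of the concentrations at the period's start
and end dates.  Missing endpoints are imputed with the habitat x date mean of
the existing values; a start date with no plant data at all (the first survey
date) borrows the same plot's value from the matching date one year later.
Every imputation is recorded in a provenance column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dung import DomainError
from .ingest import CONC_KINDS, NUTRIENTS, SurveyDataset

PROV_MEASURED = "measured_both_ends"
PROV_IMPUTED = "imputed_one_end"
PROV_IMPUTED_BOTH = "imputed_both_ends"
PROV_APR2016 = "substituted_apr2016"


@dataclass(frozen=True)
class Calibration:
    """Linear map from compressed sward height to standing biomass.

    ``biomass = intercept + slope * height`` in kg DM ha^-1, fitted by
    ordinary least squares on paired plate readings and calibration cuts.
    """

    intercept: float
    slope: float
    n: int
    residual_sd: float
    intercept_se: float
    slope_se: float

    def predict(self, height: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(height, dtype=float)


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> Calibration:
    """Fit the height-to-biomass calibration line by least squares.

    Parameters
    ----------
    pairs
        ``(height, cut_biomass)`` observations; at least three, with not all
        heights equal.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DomainError("calibration needs >= 3 (height, biomass) pairs")
    heights, biomass = arr[:, 0], arr[:, 1]
    if np.ptp(heights) == 0:
        raise DomainError("degenerate calibration: all heights equal")
    X = sm.add_constant(heights)
    fit = sm.OLS(biomass, X).fit()
    resid_sd = float(np.sqrt(fit.scale)) if len(arr) > 2 else float("nan")
    return Calibration(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        n=len(arr),
        residual_sd=resid_sd,
        intercept_se=float(fit.bse[0]),
        slope_se=float(fit.bse[1]),
    )


def forage_removal(protected_increment: float, grazed_increment: float) -> float:
    """Removal (kg DM ha^-1) = protected minus grazed biomass increment.

    Either increment missing propagates a missing result.  Negative values
    (measurement noise) are returned as-is; callers flag rather than truncate
    them, since zero-truncation would bias annual export upward.
    """
    if pd.isna(protected_increment) or pd.isna(grazed_increment):
        return float("nan")
    return float(protected_increment) - float(grazed_increment)


def removal_table(ds: SurveyDataset) -> pd.DataFrame:
    """Per-plot, per-period forage removal with a negative flag.

    Removal values supplied directly in the survey are passed through;
    missing cells stay missing (never zero).
    """
    out = ds.forage.copy()
    out["negative_flag"] = out["removal_kg_ha"] < 0
    return out[["habitat", "site", "treatment", "period",
                "removal_kg_ha", "negative_flag"]]


# ---------------------------------------------------------------------------
# Period concentrations
# ---------------------------------------------------------------------------

def period_concentration(start_value: float, end_value: float,
                         start_fallback: float = float("nan"),
                         end_fallback: float = float("nan"),
                         ) -> tuple[float, str]:
    """Mean concentration over a sampling period, with endpoint imputation.

    A missing endpoint is replaced by its habitat x date fallback mean before
    averaging.  If an endpoint has neither a value nor a fallback, the mean of
    the remaining endpoint(s) is used with a warning; with nothing at all the
    result is missing.
    Returns ``(value, provenance)``.
    """
    s = start_value if not pd.isna(start_value) else start_fallback
    e = end_value if not pd.isna(end_value) else end_fallback
    n_imputed = int(pd.isna(start_value)) + int(pd.isna(end_value))
    vals = [v for v in (s, e) if not pd.isna(v)]
    if not vals:
        warnings.warn("no endpoint value and no fallback; concentration missing",
                      stacklevel=2)
        return float("nan"), "missing"
    if len(vals) < 2:
        warnings.warn("one endpoint irrecoverable; using the other alone",
                      stacklevel=2)
    value = float(np.mean(vals))
    if n_imputed == 0:
        prov = PROV_MEASURED
    elif n_imputed == 1:
        prov = PROV_IMPUTED
    else:
        prov = PROV_IMPUTED_BOTH
    return value, prov


def _unit_frame(ds: SurveyDataset, kind: str) -> pd.DataFrame:
    d = ds.design
    if kind == "plant":
        units = [(h, s, t) for h in d.habitats for s in d.sites
                 for t in d.treatments]
        return pd.DataFrame(units, columns=["habitat", "site", "treatment"])
    units = [(h, s) for h in d.habitats for s in d.sites]
    df = pd.DataFrame(units, columns=["habitat", "site"])
    df["treatment"] = pd.NA
    return df


def concentration_period_table(ds: SurveyDataset) -> pd.DataFrame:
    """Period-mean N and P concentrations for plant and faecal samples.

    Plant concentrations are plot-level; faecal concentrations are site-level
    (collected per site) and are later broadcast to both plots of the site.
    Imputation order per endpoint: measured value; for the first schedule date
    with no plant data, the same unit's value at the last date (one year on);
    otherwise the habitat x date mean.  Provenance records what was applied.
    """
    d = ds.design
    dates = d.schedule.dates
    cc = ds.concentrations

    rows = []
    for kind in CONC_KINDS:
        units = _unit_frame(ds, kind)
        for nutrient in NUTRIENTS:
            sub = cc[(cc["kind"] == kind) & (cc["nutrient"] == nutrient)]
            # value per unit x date
            if kind == "plant":
                keyed = sub.set_index(["habitat", "site", "treatment", "date"])[
                    "value_pct"]
            else:
                keyed = sub.set_index(["habitat", "site", "date"])["value_pct"]
            hab_date_mean = sub.groupby(["habitat", "date"])["value_pct"].mean()

            def value_at(unit: pd.Series, date) -> float:
                if kind == "plant":
                    key = (unit["habitat"], unit["site"], unit["treatment"], date)
                else:
                    key = (unit["habitat"], unit["site"], date)
                try:
                    v = keyed.loc[key]
                except KeyError:
                    return float("nan")
                return float(v) if not pd.isna(v) else float("nan")

            def fallback_at(unit: pd.Series, date) -> float:
                try:
                    v = hab_date_mean.loc[(unit["habitat"], date)]
                except KeyError:
                    return float("nan")
                return float(v) if not pd.isna(v) else float("nan")

            for _, unit in units.iterrows():
                for period in range(1, d.schedule.n_periods + 1):
                    start_d, end_d = d.schedule.period_bounds(period)
                    sv, ev = value_at(unit, start_d), value_at(unit, end_d)
                    substituted = False
                    # first survey date without plant sampling: borrow the
                    # matching date one year later (same unit, else habitat mean)
                    if (kind == "plant" and start_d == dates[0]
                            and pd.isna(sv) and pd.isna(fallback_at(unit, start_d))):
                        sv = value_at(unit, dates[-1])
                        if pd.isna(sv):
                            sv = fallback_at(unit, dates[-1])
                        substituted = not pd.isna(sv)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        value, prov = period_concentration(
                            sv, ev,
                            fallback_at(unit, start_d), fallback_at(unit, end_d))
                    if substituted:
                        prov = PROV_APR2016
                    rows.append({
                        "kind": kind, "habitat": unit["habitat"],
                        "site": unit["site"], "treatment": unit["treatment"],
                        "period": period, "nutrient": nutrient,
                        "value_pct": value, "provenance": prov,
                    })
    return pd.DataFrame(rows)
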