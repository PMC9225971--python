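"""Dung accumulation: decay rates, count correction and dry mass per hectare.

The faecal accumulation rate method counts pellet groups accumulated on
cleared plots between sampling dates.  Some groups decay before the recount;
a site x period decay experiment (marked fresh groups checked at the next
date) yields the lost fraction ``r``.  Because deposition times are roughly
uniform within a period, a group is exposed to decay for half a period on
average, so the expected detection probability is ``1 - r/2`` and the
corrected count is ``pg_cor = pg_obs / (1 - r/2)``.

Dry mass per hectare follows from the corrected count, the site x date mean
dry mass of a pellet group, and the plot area.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .ingest import SUBPLOTS, SurveyDataset


class DomainError(ValueError):
    """An argument lies outside the operation's domain."""


def decay_fraction(n_placed: int, n_lost: int) -> float:
    """Fraction of marked pellet groups lost between consecutive dates.

    A marked group counts as lost when fewer than six pellets are retrieved.
    """
    if n_placed < 1:
        raise DomainError("decay trial needs n_placed >= 1")
    if not 0 <= n_lost <= n_placed:
        raise DomainError(f"n_lost={n_lost} outside [0, n_placed={n_placed}]")
    return n_lost / n_placed


def correct_pellet_count(pg_obs: float, r: float) -> float:
    """Decay-corrected pellet-group count ``pg_obs / (1 - r/2)``.

    With no decay (r = 0) the corrected count equals the observed one; at
    complete loss (r = 1) the observed count is doubled.  The result is kept
    as a real number because it feeds continuous mass arithmetic.
    """
    if not 0.0 <= r <= 1.0:
        raise DomainError(f"decay fraction r={r} outside [0, 1]")
    if pg_obs < 0:
        raise DomainError("pg_obs must be non-negative")
    return pg_obs / (1.0 - r / 2.0)


def dung_mass_per_ha(pg_cor: float, mean_pg_mass_g: float,
                     plot_area_m2: float) -> float:
    """Dung dry mass in kg DM ha^-1 from corrected count and mean group mass."""
    if plot_area_m2 <= 0:
        raise DomainError("plot area must be positive")
    if pg_cor < 0 or mean_pg_mass_g < 0:
        raise DomainError("count and mass must be non-negative")
    return pg_cor * (mean_pg_mass_g / 1000.0) / (plot_area_m2 / 10_000.0)


# ---------------------------------------------------------------------------
# Tables: site x period decay rates, site x date pellet masses
# ---------------------------------------------------------------------------

def decay_rate_table(ds: SurveyDataset) -> pd.DataFrame:
    """Per site x period decay fractions with the documented fallback chain.

    ``r`` comes from the site's own trial; if that trial is missing, from the
    habitat x period mean of the other sites' trials; if no trial exists for
    the period at all, ``r = 0`` (no correction) with a warning — the
    conservative choice, since an uncorrected count assumes no decay.
    """
    d = ds.design
    trials = ds.decay_trials.dropna(subset=["n_placed", "n_lost"]).copy()
    trials = trials[trials["n_placed"] >= 1]
    trials["r"] = trials["n_lost"] / trials["n_placed"]

    rows = []
    for habitat in d.habitats:
        hab = trials[trials["habitat"] == habitat]
        for period in range(1, d.schedule.n_periods + 1):
            hab_per = hab[hab["period"] == period]
            for site in d.sites:
                own = hab_per[hab_per["site"] == site]
                if len(own):
                    r = float(own["r"].mean())
                    source = "site_trial"
                elif len(hab_per):
                    r = float(hab_per["r"].mean())
                    source = "habitat_period_mean"
                else:
                    warnings.warn(
                        f"no decay trial for {habitat} period {period}; "
                        "assuming r=0 (no correction)", stacklevel=2,
                    )
                    r = 0.0
                    source = "assumed_zero"
                rows.append({"habitat": habitat, "site": site,
                             "period": period, "r": r, "r_source": source})
    return pd.DataFrame(rows)


def pellet_mass_table(ds: SurveyDataset) -> pd.DataFrame:
    """Site x date mean pellet-group dry mass (g), habitat x date fallback."""
    d = ds.design
    pm = ds.pellet_masses.dropna(subset=["mass_g"])
    rows = []
    for habitat in d.habitats:
        hab = pm[pm["habitat"] == habitat]
        for date in d.schedule.dates:
            hab_date = hab[hab["date"] == date]
            for site in d.sites:
                own = hab_date[hab_date["site"] == site]
                if len(own):
                    mass = float(own["mass_g"].mean())
                    source = "site_mean"
                elif len(hab_date):
                    mass = float(hab_date["mass_g"].mean())
                    source = "habitat_date_mean"
                else:
                    mass = np.nan
                    source = "missing"
                rows.append({"habitat": habitat, "site": site, "date": date,
                             "mean_pg_mass_g": mass, "mass_source": source})
    return pd.DataFrame(rows)


def average_u_plots(left: pd.Series | dict, right: pd.Series | dict) -> dict:
    """Arithmetic mean of the two U-treatment dung subplots of one site.

    Both subplots must refer to the same site and period.  If either value of
    a quantity is missing the mean is missing (never "half"), because the two
    subplots share equal exposure only when both were recorded.
    """
    lk = {k: left[k] for k in ("habitat", "site", "period")}
    rk = {k: right[k] for k in ("habitat", "site", "period")}
    if lk != rk:
        raise DomainError(f"subplot keys differ: {lk} vs {rk}")
    out = dict(lk)
    out["treatment"] = "U"
    for col in ("pg_obs", "pg_cor", "mass_kg_ha"):
        lv, rv = left.get(col, np.nan), right.get(col, np.nan)
        if pd.isna(lv) or pd.isna(rv):
            out[col] = np.nan
        else:
            out[col] = (lv + rv) / 2.0
    return out


def dung_quantity_table(ds: SurveyDataset) -> pd.DataFrame:
    """Corrected counts and dung dry mass per plot x period.

    Returns one row per habitat x site x treatment x period with columns
    ``pg_obs``, ``r``, ``pg_cor`` and ``mass_kg_ha``; the two U subplots are
    averaged into a single U record.  Pellet mass uses the period's end-date
    site mean (the date at which the accumulated dung was counted).
    """
    d = ds.design
    rates = decay_rate_table(ds).set_index(["habitat", "site", "period"])["r"]
    masses = pellet_mass_table(ds).set_index(
        ["habitat", "site", "date"])["mean_pg_mass_g"]

    def one_unit(habitat: str, site: int, treatment: str,
                 subplot: str | None, period: int) -> dict:
        dc = ds.dung_counts
        sel = (
            (dc["habitat"] == habitat) & (dc["site"] == site)
            & (dc["treatment"] == treatment) & (dc["period"] == period)
        )
        sel &= dc["subplot"].isna() if subplot is None else (dc["subplot"] == subplot)
        rec = dc[sel]
        r = float(rates.loc[(habitat, site, period)])
        end_date = d.schedule.period_bounds(period)[1]
        mass_g = masses.loc[(habitat, site, end_date)]
        row = {"habitat": habitat, "site": site, "period": period,
               "treatment": treatment, "r": r}
        if not len(rec) or pd.isna(rec["pg_obs"].iloc[0]):
            row.update(pg_obs=np.nan, pg_cor=np.nan, mass_kg_ha=np.nan)
            return row
        pg_obs = float(rec["pg_obs"].iloc[0])
        pg_cor = correct_pellet_count(pg_obs, r)
        mass = (dung_mass_per_ha(pg_cor, float(mass_g), d.plot_area_m2)
                if not pd.isna(mass_g) else np.nan)
        row.update(pg_obs=pg_obs, pg_cor=pg_cor, mass_kg_ha=mass)
        return row

    rows = []
    for habitat in d.habitats:
        for site in d.sites:
            for period in range(1, d.schedule.n_periods + 1):
                rows.append(one_unit(habitat, site, "B", None, period))
                subs = [one_unit(habitat, site, "U", sp, period) for sp in SUBPLOTS]
                merged = average_u_plots(subs[0], subs[1])
                merged["r"] = subs[0]["r"]
                rows.append(merged)
    cols = ["habitat", "site", "treatment", "period",
            "pg_obs", "r", "pg_cor", "mass_kg_ha"]
    return pd.DataFrame(rows)[cols]
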