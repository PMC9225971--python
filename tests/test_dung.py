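"""Decay correction, dung mass conversion and U-subplot averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import deerflux as dx
from deerflux.dung import DomainError


@pytest.mark.parametrize("placed,lost,expected", [
    (5, 0, 0.0),
    (20, 2, 0.10),   # pooled grassland winter trial: 2 of 4 x 5 groups decayed
    (5, 5, 1.0),
])
def test_decay_fraction(placed, lost, expected):
    assert dx.decay_fraction(placed, lost) == pytest.approx(expected)


@pytest.mark.parametrize("placed,lost", [(0, 0), (5, 6), (5, -1)])
def test_decay_fraction_domain_errors(placed, lost):
    with pytest.raises(DomainError):
        dx.decay_fraction(placed, lost)


@pytest.mark.parametrize("pg_obs,r,expected", [
    (10, 0.0, 10.0),            # no decay: corrected equals observed
    (10, 0.2, 10 / 0.9),
    (17, 0.3, 20.0),            # observed/corrected = 0.85, the lower bound
])
def test_correct_pellet_count(pg_obs, r, expected):
    assert dx.correct_pellet_count(pg_obs, r) == pytest.approx(expected)


def test_correct_pellet_count_domain_errors():
    with pytest.raises(DomainError):
        dx.correct_pellet_count(10, 1.2)
    with pytest.raises(DomainError):
        dx.correct_pellet_count(-1, 0.1)


@given(pg=st.integers(0, 500), r=st.floats(0, 1))
def test_corrected_count_bounds(pg, r):
    """pg_cor lies in [pg_obs, 2 pg_obs]; detection ratio is 1 - r/2."""
    cor = dx.correct_pellet_count(pg, r)
    assert pg <= cor <= 2 * pg + 1e-9
    if pg > 0:
        assert pg / cor == pytest.approx(1 - r / 2)


@given(pg=st.integers(1, 500), r1=st.floats(0, 1), r2=st.floats(0, 1))
def test_correction_monotone_in_decay(pg, r1, r2):
    if r1 + 1e-12 < r2:
        assert dx.correct_pellet_count(pg, r1) < dx.correct_pellet_count(pg, r2)


def test_detection_ratio_85_to_100_pct_for_observed_decay_range():
    """With all site-period decay fractions <= 0.3, observed counts represent
    85-100% of the groups actually deposited."""
    for r in np.linspace(0, 0.3, 31):
        ratio = 10 / dx.correct_pellet_count(10, r)
        assert 0.85 - 1e-12 <= ratio <= 1.0


@pytest.mark.parametrize("pg_cor,mass_g,area,expected", [
    (1, 100, 225, 0.1 / 0.0225),
    (0, 50, 225, 0.0),
    (22.5, 225, 225, 225.0),
])
def test_dung_mass_per_ha(pg_cor, mass_g, area, expected):
    assert dx.dung_mass_per_ha(pg_cor, mass_g, area) == pytest.approx(expected)


def test_dung_mass_requires_positive_area():
    with pytest.raises(DomainError):
        dx.dung_mass_per_ha(1, 100, 0)


def test_correction_recovers_true_deposition_monte_carlo():
    """Independent simulation oracle: groups deposited at uniform times decay
    before the recount with probability r/2, so observed ~ Binomial(N, 1-r/2)
    and the mean corrected count recovers N."""
    rng = np.random.default_rng(1234)
    n_true, r, reps = 200, 0.3, 4000
    # brute-force event-level simulation, independent of the estimator
    t_dep = rng.uniform(0, 1, size=(reps, n_true))
    u = rng.uniform(0, 1, size=(reps, n_true))
    # a group decays within a unit period with rate r; deposited at time t it
    # is exposed for 1 - t, hence survival prob 1 - r (1 - t)
    decayed = u < r * (1 - t_dep)
    observed = (~decayed).sum(axis=1)
    assert observed.mean() / n_true == pytest.approx(1 - r / 2, abs=0.01)
    corrected = observed / (1 - r / 2)
    mc_se = corrected.std(ddof=1) / np.sqrt(reps)
    assert abs(corrected.mean() - n_true) < 4 * mc_se + 0.1


def test_average_u_plots():
    base = {"habitat": "heathland", "site": 1, "period": 2}
    a = dict(base, pg_obs=10, pg_cor=11.0, mass_kg_ha=100.0)
    b = dict(base, pg_obs=10, pg_cor=11.0, mass_kg_ha=200.0)
    out = dx.average_u_plots(a, b)
    assert out["mass_kg_ha"] == pytest.approx(150.0)
    assert out["pg_cor"] == pytest.approx(11.0)  # mean of equal values
    # one subplot missing -> missing, not halved
    c = dict(base, pg_obs=np.nan, pg_cor=np.nan, mass_kg_ha=np.nan)
    out = dx.average_u_plots(a, c)
    assert np.isnan(out["mass_kg_ha"])
    with pytest.raises(DomainError):
        dx.average_u_plots(a, dict(a, site=2))


def test_decay_rate_fallback_chain(study_ds):
    """Missing site trial -> habitat x period mean; no trial at all -> 0."""
    ds = study_ds.copy()
    dt = ds.decay_trials
    # drop site 1's heathland trial for period 1, keep the others
    keep = ~((dt["habitat"] == "heathland") & (dt["site"] == 1)
             & (dt["period"] == 1))
    ds.decay_trials = dt[keep]
    rates = dx.decay_rate_table(ds).set_index(["habitat", "site", "period"])
    row = rates.loc[("heathland", 1, 1)]
    assert row["r_source"] == "habitat_period_mean"
    others = dt[(dt["habitat"] == "heathland") & (dt["period"] == 1)
                & (dt["site"] != 1)]
    assert row["r"] == pytest.approx((others["n_lost"] / others["n_placed"]).mean())
    # remove every heathland period-1 trial -> r = 0 with warning
    keep = ~((dt["habitat"] == "heathland") & (dt["period"] == 1))
    ds.decay_trials = dt[keep]
    with pytest.warns(UserWarning, match="no decay trial"):
        rates = dx.decay_rate_table(ds).set_index(["habitat", "site", "period"])
    assert rates.loc[("heathland", 2, 1), "r"] == 0.0


def test_dung_quantity_table_structure(study_ds):
    dq = dx.dung_quantity_table(study_ds)
    assert set(dq["treatment"]) == {"B", "U"}
    ok = dq.dropna(subset=["pg_obs"])
    assert (ok["pg_cor"] >= ok["pg_obs"] - 1e-12).all()
    assert (ok["mass_kg_ha"].dropna() >= 0).all()
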