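"""Period summaries, Gaussian error propagation, balances and scenarios."""

import itertools

import numpy as np
import pytest

import deerflux as dx
from deerflux.budget import PeriodSummary, Z95
from deerflux.dung import DomainError


def test_summarize_period_basic():
    s = dx.summarize_period([2, 4])
    assert (s.mean, s.se, s.n) == (3.0, 1.0, 2)


def test_summarize_period_missing_excluded():
    s = dx.summarize_period([2, np.nan, 4])
    assert s.n == 2 and s.mean == 3.0


def test_summarize_period_single_value_warns():
    with pytest.warns(UserWarning, match="single"):
        s = dx.summarize_period([5.0])
    assert (s.mean, s.se, s.n) == (5.0, 0.0, 1)


def test_annualize_sums_means_and_propagates_se():
    fives = [PeriodSummary(1.0, 0.0, 4)] * 5
    a = dx.annualize(fives)
    assert (a.mean, a.se) == (5.0, 0.0)
    tri = [PeriodSummary(0.0, se, 4) for se in (3, 4, 0, 0, 0)]
    assert dx.annualize(tri).se == pytest.approx(5.0)  # 3-4-5 triangle


def test_annualize_permutation_invariant():
    summaries = [PeriodSummary(m, s, 8)
                 for m, s in [(1, .1), (2, .4), (0.5, .2), (3, .3), (1.5, .25)]]
    ref = dx.annualize(summaries)
    for perm in itertools.permutations(summaries):
        a = dx.annualize(list(perm))
        assert a.mean == pytest.approx(ref.mean)
        assert a.se == pytest.approx(ref.se)


def test_annualize_missing_period_is_an_error():
    bad = [PeriodSummary(1, 0, 4)] * 4 + [PeriodSummary(float("nan"), float("nan"), 0)]
    with pytest.raises(DomainError, match="missing"):
        dx.annualize(bad)


def test_net_balance_reproduces_reported_deltas():
    imp = dx.AnnualRate.from_mean_se(4.91, 0)
    exp = dx.AnnualRate.from_mean_se(18.81, 0)
    assert dx.net_balance(imp, exp).mean == pytest.approx(-13.90)
    imp = dx.AnnualRate.from_mean_se(0.73, 0)
    exp = dx.AnnualRate.from_mean_se(4.02, 0)
    assert dx.net_balance(imp, exp).mean == pytest.approx(-3.29)


def test_net_balance_zero_case():
    a = dx.AnnualRate.from_mean_se(2.0, 0.0)
    d = dx.net_balance(a, a)
    assert (d.mean, d.ci_lo, d.ci_hi) == (0.0, 0.0, 0.0)


def test_ci_reconstruction_heathland_n():
    """Back-computed SEs from the printed import/export CIs re-propagate to
    the printed delta-N CI within +-0.01."""
    imp = dx.AnnualRate.from_mean_se(4.91, dx.se_from_ci(3.81, 6.01))
    exp = dx.AnnualRate.from_mean_se(18.81, dx.se_from_ci(9.91, 27.71))
    d = dx.net_balance(imp, exp)
    assert d.ci_lo == pytest.approx(-22.87, abs=0.01)
    assert d.ci_hi == pytest.approx(-4.93, abs=0.01)


@pytest.mark.parametrize("dn,dp,expected", [
    (-13.90, -1.08, 12.9),
    (-29.50, -3.29, 9.0),
    (-5.0, -5.0, 1.0),
])
def test_np_export_ratio(dn, dp, expected):
    assert dx.np_export_ratio(dn, dp) == expected


def test_np_export_ratio_undefined():
    with pytest.warns(UserWarning):
        assert np.isnan(dx.np_export_ratio(-5.0, 0.0))


def test_deposition_scenario():
    delta = dx.AnnualRate(-13.90, 4.575, -22.87, -4.93)
    sc = dx.deposition_scenario(delta, 11.0)
    assert sc.conservative_net_input == pytest.approx(6.07)
    assert sc.net_input == pytest.approx(-2.90)
    sc0 = dx.deposition_scenario(delta, 0.0)
    assert sc0.net_input == pytest.approx(delta.mean)
    # a grassland-scale net export balances even Europe's high deposition end
    grass = dx.AnnualRate.from_mean_se(-29.50, 0)
    assert dx.deposition_scenario(grass, 30.0).net_input == pytest.approx(0.50)


@pytest.mark.parametrize("removal,pool,expected", [(-10, 25, 0.40), (-10, 20, 0.50)])
def test_fraction_of_production(removal, pool, expected):
    assert dx.fraction_of_production(removal, pool) == pytest.approx(expected)


def test_fraction_of_production_domain():
    with pytest.raises(DomainError):
        dx.fraction_of_production(-10, 0)


def test_propagated_se_matches_monte_carlo():
    """Simulating period means as independent normals and summing: the
    empirical SD of annual totals matches sqrt(sum se^2) within 2%."""
    rng = np.random.default_rng(99)
    means = np.array([2.0, 1.0, 0.5, 1.5, 4.0])
    ses = np.array([0.4, 0.3, 0.1, 0.2, 0.8])
    sims = rng.normal(means, ses, size=(100_000, 5)).sum(axis=1)
    propagated = dx.annualize(
        [PeriodSummary(m, s, 8) for m, s in zip(means, ses)]).se
    assert abs(sims.std(ddof=1) - propagated) / propagated < 0.02


def test_annual_budget_table_internal_consistency(study_ds):
    fx = dx.flux_table(study_ds)
    bt = dx.annual_budget_table(fx).set_index(["habitat", "variable"])
    for hab in ("heathland", "grassland"):
        ti = bt.loc[(hab, "total_N_import")]
        ex = bt.loc[(hab, "N_export")]
        dn = bt.loc[(hab, "delta_N")]
        assert dn["mean"] == pytest.approx(ti["mean"] - ex["mean"])
        assert dn["se"] == pytest.approx(np.hypot(ti["se"], ex["se"]))
        assert dn["ci_hi"] == pytest.approx(dn["mean"] + Z95 * dn["se"])
        # faecal import cannot exceed total import
        assert bt.loc[(hab, "faecal_N_import"), "mean"] <= ti["mean"]


def test_scenario_table(study_ds):
    bt = dx.annual_budget_table(dx.flux_table(study_ds))
    sc = dx.scenario_table(bt, deposition_n=11.0, deposition_p=0.3)
    row = sc[(sc["habitat"] == "heathland") & (sc["nutrient"] == "N")].iloc[0]
    assert row["net_input"] == pytest.approx(11.0 + row["delta"])
    assert row["net_input"] < row["deposition"]  # delta is negative here
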