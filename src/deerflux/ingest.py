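"""Survey-design vocabulary, validated data container and table I/O.

The study layout this package ships as its default is a one-year dung and
vegetation survey in two protected open habitat types (dry heathland and
lowland hay meadow grassland), each sampled at four sites.  Every site holds
one burnt (``B``) and one untreated (``U``) vegetation plot; dung is recorded
on one plot adjoining the B plot and on two subplots (``left``/``right``) on
opposing sides of the U plot.  Six sampling dates bound five consecutive
sampling periods that together cover exactly one year.

All raw records travel in long-format delimiter-separated tables with one
header row; a missing value is an empty cell, never a zero.  :func:`read_survey`
validates every row against the declared design and keeps missing cells as
explicit ``NaN`` so that downstream stages can distinguish "not measured"
from "measured zero".
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

HABITATS = ("heathland", "grassland")
TREATMENTS = ("B", "U")
SUBPLOTS = ("left", "right")
NUTRIENTS = ("N", "P")
CONC_KINDS = ("plant", "faecal")

#: Default sampling dates (mid-month stand-ins for Apr, May, Jun, Aug, Oct
#: 2015 and Apr 2016; the months are what matters for period labels).
DEFAULT_DATES = (
    "2015-04-15",
    "2015-05-15",
    "2015-06-15",
    "2015-08-15",
    "2015-10-15",
    "2016-04-15",
)

#: Default plot area in square metres (15 m x 15 m).
DEFAULT_PLOT_AREA_M2 = 225.0


class ValidationError(ValueError):
    """A survey table violates the declared design or a value constraint."""


class ParseError(ValueError):
    """A survey file could not be parsed (malformed rows or columns)."""


def _month_abbr(date: _dt.date) -> str:
    return date.strftime("%b")


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered sampling dates and the consecutive periods they bound.

    Period ``i`` (1-based) runs from ``dates[i-1]`` to ``dates[i]``; its label
    is the month pair, e.g. ``"Apr-May"``.  Periods are non-overlapping and
    consecutive by construction; the default six dates span exactly one year.
    """

    dates: tuple[_dt.date, ...] = tuple(
        _dt.date.fromisoformat(d) for d in DEFAULT_DATES
    )

    def __post_init__(self) -> None:
        if len(self.dates) < 2:
            raise ValidationError("a schedule needs at least two dates")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValidationError("sampling dates must be strictly increasing")

    @property
    def n_periods(self) -> int:
        return len(self.dates) - 1

    @property
    def periods(self) -> tuple[tuple[_dt.date, _dt.date], ...]:
        return tuple(zip(self.dates, self.dates[1:]))

    @property
    def period_labels(self) -> tuple[str, ...]:
        return tuple(
            f"{_month_abbr(a)}-{_month_abbr(b)}" for a, b in self.periods
        )

    def period_bounds(self, period: int) -> tuple[_dt.date, _dt.date]:
        """Start and end date of 1-based ``period``."""
        if not 1 <= period <= self.n_periods:
            raise ValidationError(
                f"period {period} outside 1..{self.n_periods}"
            )
        return self.periods[period - 1]


@dataclass(frozen=True)
class StudyDesign:
    """The crossed habitat x site x treatment layout plus the schedule.

    The shipped default is the 2 habitats x 4 sites x 2 treatments layout with
    five periods; all of it is configurable so the pipeline generalises to
    other survey designs.
    """

    habitats: tuple[str, ...] = HABITATS
    sites: tuple[int, ...] = (1, 2, 3, 4)
    treatments: tuple[str, ...] = TREATMENTS
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)
    plot_area_m2: float = DEFAULT_PLOT_AREA_M2

    def __post_init__(self) -> None:
        if self.plot_area_m2 <= 0:
            raise ValidationError("plot_area_m2 must be positive")
        if len(set(self.habitats)) != len(self.habitats):
            raise ValidationError("duplicate habitat names")

    @property
    def n_vegetation_plots(self) -> int:
        return len(self.habitats) * len(self.sites) * len(self.treatments)

    @property
    def n_flux_rows(self) -> int:
        """Design size of the per-plot flux table (plots x periods).

        U-treatment dung subplots are averaged into a single U record, so each
        site contributes one B and one U observation per period.
        """
        return self.n_vegetation_plots * self.schedule.n_periods

    def plot_keys(self) -> list[tuple[str, int, str]]:
        return [
            (h, s, t)
            for h in self.habitats
            for s in self.sites
            for t in self.treatments
        ]

    def dung_plot_keys(self) -> list[tuple[str, int, str, str | None]]:
        """Dung recording units: one B plot and two U subplots per site."""
        keys: list[tuple[str, int, str, str | None]] = []
        for h in self.habitats:
            for s in self.sites:
                keys.append((h, s, "B", None))
                for sub in SUBPLOTS:
                    keys.append((h, s, "U", sub))
        return keys


# ---------------------------------------------------------------------------
# Table schemas: file name stem -> required columns
# ---------------------------------------------------------------------------

TABLE_COLUMNS: dict[str, list[str]] = {
    "dung_counts": ["habitat", "site", "treatment", "subplot", "period", "pg_obs"],
    "decay_trials": ["habitat", "site", "period", "n_placed", "n_lost"],
    "pellet_masses": ["habitat", "site", "date", "mass_g"],
    "concentrations": ["kind", "habitat", "site", "treatment", "date", "nutrient", "value_pct"],
    "forage": ["habitat", "site", "treatment", "period", "removal_kg_ha"],
}


@dataclass
class SurveyDataset:
    """Validated container of all raw field records.

    Attributes
    ----------
    dung_counts
        One row per dung plot (B, or U subplot) x period with the observed
        pellet-group count ``pg_obs``.
    decay_trials
        One row per site x period with the number of marked fresh pellet
        groups placed at the previous date and the number lost by the next
        (a group with fewer than six pellets retrieved counts as lost).
    pellet_masses
        One row per collected pellet group: site x date x dry mass (g).
    concentrations
        Long table of N/P concentrations (% dry mass): plant samples at plot
        level, faecal samples at site level (``treatment`` empty).
    forage
        Per vegetation plot x period forage removal (kg DM ha^-1), possibly
        missing (e.g. unburnt-calibration heathland plots).
    """

    design: StudyDesign
    dung_counts: pd.DataFrame
    decay_trials: pd.DataFrame
    pellet_masses: pd.DataFrame
    concentrations: pd.DataFrame
    forage: pd.DataFrame

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(
            design=self.design,
            **{k: getattr(self, k).copy() for k in TABLE_COLUMNS},
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _fail_rows(table: str, msg: str, bad: pd.DataFrame) -> None:
    rows = ", ".join(str(i) for i in bad.index[:10])
    raise ValidationError(f"{table}: {msg} (rows: {rows})")


def _check_members(df: pd.DataFrame, table: str, col: str,
                   allowed: Iterable, allow_missing: bool = False) -> None:
    allowed = set(allowed)
    vals = df[col]
    ok = vals.isin(allowed)
    if allow_missing:
        ok |= vals.isna()
    if not ok.all():
        _fail_rows(table, f"invalid {col} value(s) {sorted(set(vals[~ok].dropna()))!r}",
                   df[~ok])


def _check_counts(df: pd.DataFrame, table: str, col: str) -> None:
    v = pd.to_numeric(df[col], errors="coerce")
    bad = v.isna() & df[col].notna()
    if bad.any():
        _fail_rows(table, f"non-numeric {col}", df[bad])
    present = v.dropna()
    if ((present < 0) | (present != present.round())).any():
        _fail_rows(table, f"{col} must be a non-negative integer",
                   df[(v < 0) | (v != v.round())])


def validate_dataset(ds: SurveyDataset) -> SurveyDataset:
    """Validate every table against the design; raise :class:`ValidationError`.

    Missing values are legal wherever the schema allows them and are never
    altered; rows whose keys fall outside the declared design are rejected.
    """
    d = ds.design
    n_per = d.schedule.n_periods
    date_set = set(d.schedule.dates)

    dc = ds.dung_counts
    if dc.empty:
        raise ValidationError("dung_counts: table is empty")
    _check_members(dc, "dung_counts", "habitat", d.habitats)
    _check_members(dc, "dung_counts", "site", d.sites)
    _check_members(dc, "dung_counts", "treatment", d.treatments)
    _check_members(dc, "dung_counts", "subplot", SUBPLOTS, allow_missing=True)
    bad_sub = (dc["treatment"] == "U") & dc["subplot"].isna()
    if bad_sub.any():
        _fail_rows("dung_counts", "U-treatment rows need a subplot", dc[bad_sub])
    bad_sub = (dc["treatment"] == "B") & dc["subplot"].notna()
    if bad_sub.any():
        _fail_rows("dung_counts", "B-treatment rows must not have a subplot", dc[bad_sub])
    _check_members(dc, "dung_counts", "period", range(1, n_per + 1))
    _check_counts(dc, "dung_counts", "pg_obs")
    dup = dc.duplicated(["habitat", "site", "treatment", "subplot", "period"], keep=False)
    if dup.any():
        _fail_rows("dung_counts", "duplicate plot x period records", dc[dup])

    dt_ = ds.decay_trials
    _check_members(dt_, "decay_trials", "habitat", d.habitats)
    _check_members(dt_, "decay_trials", "site", d.sites)
    _check_members(dt_, "decay_trials", "period", range(1, n_per + 1))
    _check_counts(dt_, "decay_trials", "n_placed")
    _check_counts(dt_, "decay_trials", "n_lost")
    bad = dt_["n_lost"] > dt_["n_placed"]
    if bad.any():
        _fail_rows("decay_trials", "n_lost exceeds n_placed", dt_[bad])

    pm = ds.pellet_masses
    _check_members(pm, "pellet_masses", "habitat", d.habitats)
    _check_members(pm, "pellet_masses", "site", d.sites)
    _check_members(pm, "pellet_masses", "date", date_set)
    m = pd.to_numeric(pm["mass_g"], errors="coerce")
    if ((m <= 0) & pm["mass_g"].notna()).any():
        _fail_rows("pellet_masses", "mass_g must be positive", pm[m <= 0])

    cc = ds.concentrations
    _check_members(cc, "concentrations", "kind", CONC_KINDS)
    _check_members(cc, "concentrations", "habitat", d.habitats)
    _check_members(cc, "concentrations", "site", d.sites)
    _check_members(cc, "concentrations", "treatment", d.treatments, allow_missing=True)
    bad = (cc["kind"] == "plant") & cc["treatment"].isna()
    if bad.any():
        _fail_rows("concentrations", "plant rows are plot-level and need a treatment", cc[bad])
    bad = (cc["kind"] == "faecal") & cc["treatment"].notna()
    if bad.any():
        _fail_rows("concentrations", "faecal rows are site-level (no treatment)", cc[bad])
    _check_members(cc, "concentrations", "date", date_set)
    _check_members(cc, "concentrations", "nutrient", NUTRIENTS)
    v = pd.to_numeric(cc["value_pct"], errors="coerce")
    bad = cc["value_pct"].notna() & ~((v > 0) & (v < 100))
    if bad.any():
        _fail_rows("concentrations", "value_pct must lie in (0, 100) % of dry mass", cc[bad])

    fo = ds.forage
    _check_members(fo, "forage", "habitat", d.habitats)
    _check_members(fo, "forage", "site", d.sites)
    _check_members(fo, "forage", "treatment", d.treatments)
    _check_members(fo, "forage", "period", range(1, n_per + 1))

    return ds


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path, name: str, sep: str) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{name}: file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True,
                         na_values=[""], skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{name}: cannot parse {path}: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise ParseError(
            f"{name}: {path} lacks required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return _coerce_types(df[TABLE_COLUMNS[name]].copy(), name)


_NUMERIC_COLS = {
    "dung_counts": ["pg_obs"],
    "decay_trials": ["n_placed", "n_lost"],
    "pellet_masses": ["mass_g"],
    "concentrations": ["value_pct"],
    "forage": ["removal_kg_ha"],
}


def _coerce_types(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if "site" in df.columns:
        df["site"] = pd.to_numeric(df["site"], errors="raise").astype(int)
    if "period" in df.columns:
        df["period"] = pd.to_numeric(df["period"], errors="raise").astype(int)
    if "date" in df.columns:
        df["date"] = df["date"].map(
            lambda s: _dt.date.fromisoformat(s) if isinstance(s, str) else s
        )
    for col in _NUMERIC_COLS[name]:
        # exact float parsing (bit-for-bit file round-trips)
        def _to_float(s):
            if s is None or (isinstance(s, float) and np.isnan(s)):
                return np.nan
            try:
                return float(s)
            except ValueError:
                return np.nan
        df[col] = df[col].map(_to_float).astype(float)
    return df


def read_survey(paths: Mapping[str, str | Path] | str | Path,
                design: StudyDesign | None = None,
                sep: str = ",") -> SurveyDataset:
    """Read and validate the five survey tables.

    Parameters
    ----------
    paths
        Either a mapping ``{table name: file path}`` for the five tables in
        :data:`TABLE_COLUMNS`, a directory containing ``<table>.csv`` files,
        or a YAML config file (see :func:`read_config`).
    design
        Study design; defaults to the shipped 2x4x2 layout with five periods.
    sep
        Field delimiter (comma by default).
    """
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if p.is_dir():
            paths = {name: p / f"{name}.csv" for name in TABLE_COLUMNS}
        else:
            return read_config(p)
    design = design or StudyDesign()
    tables = {
        name: _read_table(Path(paths[name]), name, sep) for name in TABLE_COLUMNS
    }
    ds = SurveyDataset(design=design, **tables)
    return validate_dataset(ds)


def write_survey(ds: SurveyDataset, out_dir: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write the five tables as delimiter-separated text; empty cell = missing.

    The written files round-trip through :func:`read_survey` bit-for-bit on
    values, including missing markers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in TABLE_COLUMNS:
        df = getattr(ds, name).copy()
        if "date" in df.columns:
            df["date"] = df["date"].map(lambda d: d.isoformat())
        path = out / f"{name}.csv"
        df.to_csv(path, sep=sep, index=False, na_rep="")
        written[name] = path
    return written


def read_config(path: str | Path) -> SurveyDataset:
    """Read a YAML config declaring the design and the five table paths.

    Recognised keys: ``tables`` (mapping table name -> path, relative to the
    config file), ``plot_area_m2``, ``dates`` (list of ISO dates), ``sites``,
    ``habitats``, ``treatments``, ``sep``.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = {}
    if "dates" in cfg:
        kwargs["schedule"] = SamplingSchedule(
            tuple(_dt.date.fromisoformat(str(d)) for d in cfg["dates"])
        )
    for key in ("habitats", "treatments"):
        if key in cfg:
            kwargs[key] = tuple(cfg[key])
    if "sites" in cfg:
        kwargs["sites"] = tuple(int(s) for s in cfg["sites"])
    if "plot_area_m2" in cfg:
        kwargs["plot_area_m2"] = float(cfg["plot_area_m2"])
    design = StudyDesign(**kwargs)
    tables = cfg.get("tables", {})
    paths = {
        name: (path.parent / tables.get(name, f"{name}.csv"))
        for name in TABLE_COLUMNS
    }
    return read_survey(paths, design=design, sep=cfg.get("sep", ","))


# ---------------------------------------------------------------------------
# Missingness report
# ---------------------------------------------------------------------------

def missingness_report(ds: SurveyDataset) -> pd.DataFrame:
    """Count non-missing observations per variable and date (or period).

    Returns a table with columns ``variable``, ``when`` (ISO date or period
    label), and ``n_available``.  Read-only: the dataset is not modified.
    """
    rows: list[dict] = []
    labels = ds.design.schedule.period_labels

    def _per_period(df: pd.DataFrame, value_col: str, variable: str) -> None:
        for per in range(1, ds.design.schedule.n_periods + 1):
            sub = df[df["period"] == per]
            rows.append({
                "variable": variable,
                "when": labels[per - 1],
                "n_available": int(sub[value_col].notna().sum()),
            })

    _per_period(ds.dung_counts, "pg_obs", "dung_counts")
    _per_period(ds.decay_trials, "n_placed", "decay_trials")
    _per_period(ds.forage, "removal_kg_ha", "forage_removal")
    for date in ds.design.schedule.dates:
        sub = ds.pellet_masses[ds.pellet_masses["date"] == date]
        rows.append({
            "variable": "pellet_masses",
            "when": date.isoformat(),
            "n_available": int(sub["mass_g"].notna().sum()),
        })
    for kind in CONC_KINDS:
        for nutrient in NUTRIENTS:
            sub0 = ds.concentrations[
                (ds.concentrations["kind"] == kind)
                & (ds.concentrations["nutrient"] == nutrient)
            ]
            for date in ds.design.schedule.dates:
                sub = sub0[sub0["date"] == date]
                rows.append({
                    "variable": f"{kind}_{nutrient}",
                    "when": date.isoformat(),
                    "n_available": int(sub["value_pct"].notna().sum()),
                })
    return pd.DataFrame(rows, columns=["variable", "when", "n_available"])
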