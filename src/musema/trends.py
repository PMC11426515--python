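"""Trait-mean change over generations and MA-versus-control contrasts.

Per-generation change is an ordinary least-squares regression of trait
values on generation number (sex and natal litter size as additional fixed
effects for morphometric traits), with the slope expressed as a percent of
the experiment-wide trait mean and a CI of +/- 2 standard errors on the
same scale.

The contemporaneous MA-versus-control comparison assigns records to three
calendar time periods by birth date, fits a linear model with time period
(categorical), experiment (control as reference) and the morphometric
covariates, and expresses the MA-experiment effect as a percent of the
control mean.  Sharing the rearing environment by calendar time is what
lets this contrast isolate the genetic (mutational) deficit from the
environmental time trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class TrendEstimate:
    """Per-generation linear trend scaled to percent of the trait mean."""

    slope: float                 # trait units per generation
    se: float                    # standard error of the slope
    trait_mean: float
    percent_change_per_gen: float
    ci_low: float
    ci_high: float
    n_records: int

    def percent_change_total(self, n_generations: int) -> float:
        """Percent change over the experiment: per-generation percent times
        the number of modelled generations."""
        return self.percent_change_per_gen * n_generations


@dataclass
class PeriodWindows:
    """Inclusive birth-date windows of the contemporaneous comparison."""

    early: tuple[date, date] = (date(2022, 6, 29), date(2022, 9, 26))
    middle: tuple[date, date] = (date(2022, 9, 27), date(2022, 12, 29))
    late: tuple[date, date] = (date(2022, 12, 30), date(2023, 3, 1))

    def items(self):
        return (("early", self.early), ("middle", self.middle),
                ("late", self.late))

    def assign(self, d: date) -> str | None:
        for name, (lo, hi) in self.items():
            if lo <= d <= hi:
                return name
        return None

    @property
    def span(self) -> tuple[date, date]:
        return self.early[0], self.late[1]


def per_generation_change(data: pd.DataFrame, trait: str,
                          morphometric: bool = True) -> TrendEstimate:
    """OLS of trait on generation (numeric), percent-scaled.

    For morphometric traits sex and litter size are additional fixed
    effects; fitness traits (assigned to mothers only) use generation
    alone.
    """
    df = data.dropna(subset=[trait, "generation"]).copy()
    if df["generation"].nunique() < 2:
        raise ValueError("need >= 2 generations of data")
    cols = {"generation": df["generation"].to_numpy(dtype=float)}
    if morphometric:
        d = pd.get_dummies(df["sex"], drop_first=True, dtype=float)
        for c in d.columns:
            cols[f"sex[{c}]"] = d[c].to_numpy()
        cols["litter_size"] = df["litter_size"].to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame(cols, index=df.index))
    fit = sm.OLS(df[trait].astype(float), X).fit()
    slope = float(fit.params["generation"])
    se = float(fit.bse["generation"])
    mean = float(df[trait].mean())
    pct = 100.0 * slope / mean
    half = 2.0 * 100.0 * se / mean
    return TrendEstimate(slope=slope, se=se, trait_mean=mean,
                         percent_change_per_gen=pct,
                         ci_low=pct - half, ci_high=pct + half,
                         n_records=len(df))


def ma_vs_control_difference(data: pd.DataFrame, windows: PeriodWindows,
                             trait: str, morphometric: bool = True) -> dict:
    """Percent difference of MA lines below/above controls, with +/- 2 SE CI.

    ``data`` combines both experiments (column ``experiment`` in
    {"MA", "control"}) with ``birth_date``.  Records outside the
    comparison span are dropped; a record inside the span lacking a birth
    date is an error.  The MA effect is estimated with control as the
    reference level, subtracted from the control mean, and expressed as a
    percent of the control mean.
    """
    df = data.dropna(subset=[trait]).copy()
    no_date = df["birth_date"].isna()
    if no_date.any():
        raise ValueError(
            "records lack birth dates: "
            + ", ".join(map(str, df.loc[no_date, "individual_id"].head(20))))
    period = df["birth_date"].map(
        lambda d: windows.assign(d if isinstance(d, date) else d.date()))
    df = df[period.notna()].assign(period=period[period.notna()])
    for exp in ("MA", "control"):
        present = set(df.loc[df["experiment"] == exp, "period"])
        missing = {p for p, _ in windows.items()} - present
        if missing:
            raise ValueError(f"experiment {exp!r} absent from windows "
                             f"{sorted(missing)}")
    cols = {}
    d = pd.get_dummies(df["period"], drop_first=True, dtype=float)
    for c in d.columns:
        cols[f"period[{c}]"] = d[c].to_numpy()
    cols["experiment[MA]"] = (df["experiment"] == "MA").astype(float).to_numpy()
    if morphometric:
        ds = pd.get_dummies(df["sex"], drop_first=True, dtype=float)
        for c in ds.columns:
            cols[f"sex[{c}]"] = ds[c].to_numpy()
        cols["litter_size"] = df["litter_size"].to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame(cols, index=df.index))
    fit = sm.OLS(df[trait].astype(float), X).fit()
    effect = float(fit.params["experiment[MA]"])
    se = float(fit.bse["experiment[MA]"])
    control_mean = float(df.loc[df["experiment"] == "control", trait].mean())
    pct = 100.0 * effect / control_mean
    half = 2.0 * 100.0 * se / control_mean
    return {
        "ma_effect": effect,
        "se": se,
        "control_mean": control_mean,
        "percent_difference": pct,
        "ci_low": pct - half,
        "ci_high": pct + half,
        "n_records": len(df),
    }


def extrapolate_decline(percent_total: float, n_generations: int,
                        rate_ratio: float = 1.0,
                        horizon_generations: int = 1) -> float:
    """Linear extrapolation of a total percent change.

    Divides the total change by the number of generations it accrued over,
    scales by a mutation-rate ratio (e.g., human/mouse per-site rates) and
    multiplies by a horizon in generations.  Exactly linear in each
    argument.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    return percent_total / n_generations * rate_ratio * horizon_generations
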