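"""Per-generation trait trends, MA-vs-control contrasts, extrapolation."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import musema as m
from musema.simulate import SimConfig, TraitSpec, simulate_control_branch, \
    simulate_pedigree


def _trend_frame(slope, n_per_gen=30, gens=range(1, 11), noise=0.0, seed=0,
                 mean=10.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in gens:
        for k in range(n_per_gen):
            rows.append({
                "individual_id": f"g{g}k{k}", "generation": g,
                "sex": "male" if k % 2 == 0 else "female",
                "litter_size": 5,
                "y": mean + slope * g + rng.normal(0, noise),
            })
    return pd.DataFrame(rows)


def test_percent_arithmetic():
    df = _trend_frame(slope=0.05, gens=range(0, 21), noise=0.0)
    est = m.per_generation_change(df, "y", morphometric=True)
    # slope 0.05 on the realized mean
    assert est.slope == pytest.approx(0.05, abs=1e-10)
    assert est.percent_change_per_gen == pytest.approx(
        100 * 0.05 / df["y"].mean(), rel=1e-10)
    assert est.ci_low <= est.percent_change_per_gen <= est.ci_high


def test_exact_linear_trend_recovered_to_machine_precision():
    df = _trend_frame(slope=-0.123)
    est = m.per_generation_change(df, "y")
    assert est.slope == pytest.approx(-0.123, abs=1e-9)
    assert est.se == pytest.approx(0.0, abs=1e-9)


def test_ci_width_scales_with_sample_size():
    a = m.per_generation_change(_trend_frame(0.0, n_per_gen=20, noise=1.0,
                                             seed=1), "y")
    b = m.per_generation_change(_trend_frame(0.0, n_per_gen=320, noise=1.0,
                                             seed=2), "y")
    assert (b.ci_high - b.ci_low) < 0.5 * (a.ci_high - a.ci_low)


def test_zero_slope_ci_covers_zero_most_of_the_time():
    hits = 0
    n = 40
    for s in range(n):
        est = m.per_generation_change(
            _trend_frame(0.0, noise=1.0, seed=100 + s), "y")
        hits += est.ci_low <= 0.0 <= est.ci_high
    assert hits >= int(0.85 * n)


def test_constant_generation_errors():
    df = _trend_frame(0.0, gens=[5])
    with pytest.raises(ValueError):
        m.per_generation_change(df, "y")


# ---------------------------------------------------------------------------
# Windows and MA-vs-control
# ---------------------------------------------------------------------------

def test_window_boundaries_inclusive():
    w = m.PeriodWindows()
    assert w.assign(date(2022, 6, 29)) == "early"
    assert w.assign(date(2022, 9, 26)) == "early"
    assert w.assign(date(2022, 9, 27)) == "middle"
    assert w.assign(date(2022, 12, 29)) == "middle"
    assert w.assign(date(2022, 12, 30)) == "late"
    assert w.assign(date(2023, 3, 1)) == "late"
    assert w.assign(date(2023, 3, 2)) is None
    assert w.assign(date(2022, 6, 28)) is None


def _contrast_frame(ma_shift=0.0, window_shift=(0.0, 0.0, 0.0), noise=0.3,
                    seed=0, n=60):
    rng = np.random.default_rng(seed)
    w = m.PeriodWindows()
    rows = []
    for wi, (name, (lo, _hi)) in enumerate(w.items()):
        for exp in ("MA", "control"):
            for k in range(n):
                rows.append({
                    "individual_id": f"{name}{exp}{k}",
                    "experiment": exp,
                    "birth_date": lo + timedelta(days=int(rng.integers(0, 60))),
                    "sex": "male" if k % 2 == 0 else "female",
                    "litter_size": 5,
                    "y": (10.0 + window_shift[wi]
                          + (ma_shift if exp == "MA" else 0.0)
                          + rng.normal(0, noise)),
                })
    return pd.DataFrame(rows)


def test_null_experiment_effect_near_zero():
    res = m.ma_vs_control_difference(_contrast_frame(0.0, seed=1),
                                     m.PeriodWindows(), "y")
    assert abs(res["percent_difference"]) < 1.0
    assert res["ci_low"] <= 0.0 <= res["ci_high"]


def test_window_constant_shifts_cancel_exactly():
    a = m.ma_vs_control_difference(_contrast_frame(-0.5, seed=2),
                                   m.PeriodWindows(), "y")
    b = m.ma_vs_control_difference(
        _contrast_frame(-0.5, window_shift=(3.0, -2.0, 7.0), seed=2),
        m.PeriodWindows(), "y")
    assert a["ma_effect"] == pytest.approx(b["ma_effect"], abs=1e-9)


def test_missing_birth_date_lists_ids():
    df = _contrast_frame(0.0)
    df.loc[3, "birth_date"] = None
    with pytest.raises(ValueError, match=str(df.loc[3, "individual_id"])):
        m.ma_vs_control_difference(df, m.PeriodWindows(), "y")


def test_known_deficit_recovered():
    shift = -0.2    # -2% of mean 10
    res = m.ma_vs_control_difference(
        _contrast_frame(shift, window_shift=(1.0, 0.5, 0.0), seed=3, n=200),
        m.PeriodWindows(), "y")
    assert res["ci_low"] <= -2.0 <= res["ci_high"]
    assert res["percent_difference"] == pytest.approx(-2.0, abs=0.5)


def test_end_to_end_control_branch_contrast():
    """Simulated cryopreserved-control experiment: the configured genetic
    deficit is recovered by the window contrast (averaged over replicate
    experiments, since line-level random effects make one draw noisy)
    while a shared time trend alone produces none."""
    traits = {"trait": TraitSpec(mean=10.0, sex_effect=0.5,
                                 trend_per_gen=-0.1)}
    cfg = SimConfig(n_lines=10, n_generations=21, burnin=0, litter_mean=4.5,
                    seed=21, v_m=0.0, v_a=0.0, v_litter=0.05,
                    v_maternal=0.05, v_e=0.3, traits=traits,
                    n_control_lines=8, ma_deficit_percent=-2.0)
    diffs, diffs0, trends = [], [], []
    for s in range(5):
        ped = simulate_pedigree(replace(cfg, seed=21 + s))
        combined, _ = simulate_control_branch(ped, replace(cfg, seed=21 + s))
        res = m.ma_vs_control_difference(combined, m.PeriodWindows(), "trait")
        diffs.append(res["percent_difference"])
        ma = combined[combined["experiment"] == "MA"]
        trends.append(m.per_generation_change(ma, "trait")
                      .percent_change_per_gen)
        # trend-only world: same seed, no deficit
        cfg0 = replace(cfg, ma_deficit_percent=0.0, seed=21 + s)
        ped0 = simulate_pedigree(cfg0)
        combined0, _ = simulate_control_branch(ped0, cfg0)
        diffs0.append(m.ma_vs_control_difference(
            combined0, m.PeriodWindows(), "trait")["percent_difference"])
    assert np.mean(diffs) == pytest.approx(-2.0, abs=1.5)
    assert np.mean(diffs0) == pytest.approx(0.0, abs=1.5)
    # deficit recovery: the paired difference removes the shared
    # line-level noise almost exactly
    assert np.mean(np.array(diffs) - np.array(diffs0)) == \
        pytest.approx(-2.0, abs=0.1)
    # per-generation regression on MA data alone still shows the trend
    assert np.mean(trends) < -0.5


# ---------------------------------------------------------------------------
# Extrapolation arithmetic
# ---------------------------------------------------------------------------

def test_extrapolation_linearity():
    base = m.extrapolate_decline(4.0, 8)
    assert m.extrapolate_decline(8.0, 8) == pytest.approx(2 * base)
    assert m.extrapolate_decline(4.0, 16) == pytest.approx(base / 2)
    assert m.extrapolate_decline(4.0, 8, rate_ratio=2.0) == \
        pytest.approx(2 * base)
    assert m.extrapolate_decline(4.0, 8, horizon_generations=3) == \
        pytest.approx(3 * base)


def test_extrapolation_requires_generations():
    with pytest.raises(ValueError):
        m.extrapolate_decline(1.0, 0)
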