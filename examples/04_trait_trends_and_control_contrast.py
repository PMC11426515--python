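"""Separate environmental trends from genetic change using the
cryopreserved control.

Simulates an MA experiment with a shared environmental time trend plus a
built-in 2% genetic deficit of the MA lines, then shows that the
per-generation regression mixes both signals while the contemporaneous
MA-vs-control window contrast isolates the genetic deficit.  Ends with the
linear extrapolation arithmetic used for the human projection.
"""

import musema as m
from musema.simulate import SimConfig, TraitSpec, simulate_pedigree, \
    simulate_control_branch

traits = {"trait": TraitSpec(mean=10.0, sex_effect=0.5, trend_per_gen=-0.1)}
cfg = SimConfig(n_lines=10, n_generations=21, burnin=0, litter_mean=4.5,
                seed=8, v_m=0.0, v_a=0.0, v_litter=0.05, v_maternal=0.05,
                v_e=0.3, traits=traits, n_control_lines=8,
                ma_deficit_percent=-2.0)
ped = simulate_pedigree(cfg)
combined, _ = simulate_control_branch(ped, cfg)

ma = combined[combined["experiment"] == "MA"]
trend = m.per_generation_change(ma, "trait")
print(f"per-generation change (MA lines alone): "
      f"{trend.percent_change_per_gen:.2f}% per generation "
      f"[{trend.ci_low:.2f}, {trend.ci_high:.2f}]")
print("  -> mixes the environmental trend with any genetic change")

res = m.ma_vs_control_difference(combined, m.PeriodWindows(), "trait")
print(f"MA vs control in shared calendar windows: "
      f"{res['percent_difference']:.2f}% [{res['ci_low']:.2f}, "
      f"{res['ci_high']:.2f}]  (built-in genetic deficit: -2%)")
print("  -> the shared environment cancels; the contrast isolates the "
      "mutational deficit")
print("  (with only 10 MA and 8 control lines, single-experiment "
      "estimates scatter by ~1-2 points around the truth)")

per_gen = m.extrapolate_decline(3.6, 16)
print(f"\nextrapolation arithmetic: a 3.6% deficit accrued over 16 "
      f"generations is {per_gen:.3f}% per generation;")
print(f"doubling for the human/mouse mutation-rate ratio and projecting "
      f"8 generations: "
      f"{m.extrapolate_decline(3.6, 16, 2.0, 8):.1f}% (about 3%).")
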