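"""Project adult smoking prevalence under the seven policy scenarios.

Calibrates the synthetic baseline to the packaged status-quo anchors, runs
every scenario from 2022 to 2050, and prints the male prevalence table.
Each row is a policy package; columns are calendar years; entries are
adult (age >= 19) current-smoking prevalence in percent.
"""
import smokesim as ss
from smokesim.calibration import calibrate
from smokesim.io import format_table, render_scenario_table

result = calibrate(settings={"budget": 700, "restarts": 1})
print(
    f"calibration: loss={result.loss:.3f} (%p)^2, "
    f"max anchor deviation {result.max_abs_residual():.2f} %p\n"
)

runs = [
    ss.run_scenario(result.baseline, ss.build_scenario(name))
    for name in ss.SCENARIO_NAMES
]
years = (2022, 2025, 2030, 2035, 2040, 2045, 2050)
print("Male adult smoking prevalence (%) by scenario:")
print(format_table(render_scenario_table(runs, years, sex="male")))

combined = runs[-1]
print(
    f"\nUnder the combined endgame package the overall prevalence reaches "
    f"{combined.value(2050, 'total'):.1f}% in 2050 "
    f"({combined.value(2050, 'male'):.1f}% male, "
    f"{combined.value(2050, 'female'):.1f}% female): only this package "
    f"approaches the <5% endgame threshold."
)
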