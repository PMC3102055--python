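"""Occupational-activity trends on the anchored synthetic series.

Generates the noiseless 1960–2008 employment drift (moderate-intensity
share 48% -> 20%, manufacturing 30% -> 12%), computes yearly mean METs and
daily occupational energy expenditure, and tests the secular trends.
"""

from metshift import (
    Gender,
    Intensity,
    activity_trend,
    generate_employment_series,
    trend_test,
)

series = generate_employment_series(noise_sd=0.0, seed=0)
rows = activity_trend(series)
first, last = rows[0], rows[-1]

print(f"years {first.year}-{last.year}")
print(f"mean occupational METs: {first.mean_met:.2f} -> {last.mean_met:.2f}")
for cat in Intensity:
    t = trend_test({r.year: r.category_prevalence[cat] for r in rows})
    print(
        f"{cat.value:>9} share: {first.category_prevalence[cat]:.2f} -> "
        f"{last.category_prevalence[cat]:.2f}  (slope {t.slope:+.4f}/yr, p {t.p_value:.3g})"
    )
for g in Gender:
    decline = first.daily_ee_kcal[g] - last.daily_ee_kcal[g]
    print(
        f"{g.value:>9}: daily EE {first.daily_ee_kcal[g]:.0f} -> "
        f"{last.daily_ee_kcal[g]:.0f} kcal/workday (decline {decline:.0f})"
    )
print(
    "\nBoth declines exceed 100 kcal/day — the shift out of moderate-intensity"
    " work alone removes a meal's worth of daily expenditure."
)
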