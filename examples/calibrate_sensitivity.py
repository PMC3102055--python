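"""Calibration of the kg-per-kcal steady-state sensitivity.

Expenditure is reduced by 50, 100 and 150 kcal/day in turn, the model is
integrated to steady state, and the three weight-change ratios are
averaged. In the linear model the ratios coincide at 1/gamma.
"""

from metshift import EnergyBalanceParams, Gender, kg_per_kcal_ratio, simulate_weight

for gender in Gender:
    params = EnergyBalanceParams.default(gender)
    for inc in (50.0, 100.0, 150.0):
        res = simulate_weight(params, -inc)
        print(
            f"{gender.value:>5}: -{inc:3.0f} kcal/d -> +{res.delta_weight_kg:5.2f} kg "
            f"({res.delta_weight_kg / inc:.4f} kg per kcal/d, "
            f"settled in {res.days_to_tolerance / 365:.1f} y)"
        )
    ratio = kg_per_kcal_ratio(params)
    print(f"{gender.value:>5}: averaged sensitivity {ratio:.3f} kg per kcal/day\n")
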