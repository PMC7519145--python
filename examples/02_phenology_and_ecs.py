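"""From daily weather to growth stages to environmental covariates.

A winter-wheat season is simulated from generated daily weather: emergence at
150 °C-days, stem elongation (GS30) under photoperiod x vernalization control,
heading (GS55) under photoperiod control, then fixed thermal-time offsets to
anthesis, milk and maturity. The per-phase weather summaries are the ECs that
feed the environmental kernel Omega = WW'/q.
"""

from gxesim import (
    CultivarPhenologyParams,
    ECSchema,
    compute_ecs,
    generate_weather,
    simulate_growth_stages,
)

w = generate_weather(latitude=48.0, year=2012, seed=7, location="Boigneville-like")
cp = CultivarPhenologyParams(gdd_pv=220.0, gdd_p=280.0)
gs = simulate_growth_stages(w, cp, sowing_date="2011-10-15")

print("growth-stage calendar (date, cumulative base-0 °C-days since sowing):")
for stage in ("GS00", "GS10", "GS30", "GS39", "GS55", "GS65", "GS75", "GS92"):
    print(f"  {stage}: {gs.dates[stage].date()}  {gs.tt_cum[stage]:7.1f}")
print(f"phyllotherm: {gs.phyll:.1f} °C-days/leaf (bounded to [66, 120])")

schema = ECSchema()
row = compute_ecs(w, gs, schema)
print(f"\n{len(row)} environmental covariates over {len(schema.phases)} phases; a few:")
for name in ("GS30_GS39:tmean_mean", "GS55_GS65:days_tmax_gt25", "cycle:rain_sum",
             "GS39_GS55:water_balance"):
    print(f"  {name} = {row[name]:.1f}")
# Heading lands in late May and maturity in July, as for French winter wheat;
# the EC row is one environment's coordinates in the q-dimensional weather space.
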