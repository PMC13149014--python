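"""Full pipeline: counterfactual simulation and per-day effect estimates.

Fits the pretreatment model, simulates 1000 counterfactual trajectories
for distribution day + 7, and compares observed rates to the simulated
distribution through 95% quantile credible intervals.
"""

import itsim

params = itsim.default_params("mortality")
series = itsim.generate_series(params, seed=1)
config = itsim.AnalysisConfig(seed=1, lag_order=1, n_sims=1000)

result = itsim.analyze(series, params.calendar, config)
print(result.table.round(6).to_string(index=False))

sig = [e.day for e in result.effects if e.significant]
print(f"\nsignificant days: {sig or 'none'}")
print("mean_diff is observed minus expected deaths per 10 000 residents,")
print("pooled across the 11 distribution events; implied_count_diff scales")
print("it to statewide daily deaths. On this null series every 95% interval")
print("covers zero: the payment-day effect is indistinguishable from noise.")
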