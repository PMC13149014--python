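"""Fit the autoregressive negative-binomial pretreatment model.

Builds the pooled 30-day pretreatment design (lagged rates, day-of-week
dummies, within-window trend, year fixed effects, log-population offset),
selects the lag order by stepwise AIC, and prints fit diagnostics.
"""

import itsim
from itsim.design import build_pretreatment_design
from itsim.model import fit_nb

params = itsim.default_params("mortality")
series = itsim.generate_series(params, seed=1)
config = itsim.AnalysisConfig(seed=1, lag_order="auto", max_lag=7)

selection = itsim.select_lag_order(series, params.calendar, config)
print(f"stepwise AIC selected lag order D = {selection.order}")
print("AIC by order:", {d: round(a, 1) for d, a in selection.aic_by_order.items()})

design = build_pretreatment_design(series, params.calendar, config, selection.order)
model = fit_nb(design)
print(f"\nrows: {model.n_obs} (11 years x 30 days), dispersion theta = {model.theta:.2f}")
print(model.summary_frame().round(4).to_string())
print(f"\nLjung-Box Q = {selection.diagnostics.ljung_box_stat:.2f}, "
      f"p = {selection.diagnostics.ljung_box_pvalue:.3f} "
      "(a small p hints at residual autocorrelation beyond the fitted lags;")
print("read it descriptively — on fitted residuals the test runs hot, see docs/methods.md)")

# The generating process uses lag-rate coefficient 1.0 and theta = 12; the
# lag estimate is attenuated at 30-day windows (short-panel bias, see
# docs/methods.md) while the calendar effects are recovered directly.
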