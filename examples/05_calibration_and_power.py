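"""Interval calibration and spike-detection power on synthetic replicates.

The validation loop behind the package: under the null the 95% interval
should miss ~5% of days; a planted treatment-day spike should be detected
with power growing in its size. (Scaled down to 30 replicates here; the
acceptance script runs 200.)
"""

import itsim
from itsim.calibration import null_calibration, power_curve

params = itsim.default_params("mortality")
config = itsim.AnalysisConfig(seed=1, lag_order=1, n_sims=500)

report = null_calibration(params, config, n_replicates=30, seed=5)
print("null calibration (30 replicates, days 0-7):")
print(report.to_frame().round(3).to_string(index=False))
print(f"overall coverage {100 * report.overall_coverage:.1f}% "
      f"(nominal 95%)\n")

curve = power_curve(params, config, multipliers=(1.5, 2.0),
                    n_replicates=30, seed=5)
print("power to detect a planted day-0 spike:")
print(curve.to_string(index=False))
print("a x2 spike (~11 extra deaths statewide) is detected nearly always;")
print("smaller spikes fade into the day-to-day noise.")
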