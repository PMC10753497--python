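"""Fit the degradation rate of each collagen condition and form their ratio.

Scans the ECM degradation constant for the high-density (cleft 0.10) and
low-density (cleft 0.26) assay conditions and picks, for each, the value
whose 100-step invasion summary best matches the measured targets: 80% /
60% of emigrating cells in the interface and a low:high interface cell
ratio of 0.4. The delta grid here is restricted to the informative range so
the example runs in about a minute; the full default grid gives the same
optimum.
"""

import numpy as np

from cleftsim.scanfit import fit_interface_conditions

deltas = np.round(np.arange(0.0, 0.0601, 0.005), 10)
fit = fit_interface_conditions(delta_values=deltas)

print("high-density condition:")
print(f"  fitted delta      : {fit.high.delta}")
print(f"  interface fraction: {fit.high.interface_fraction:.3f} (target 0.80)")
print("low-density condition:")
print(f"  fitted delta      : {fit.low.delta}")
print(f"  interface fraction: {fit.low.interface_fraction:.3f} (target 0.60)")
print(f"  interface mass    : {fit.low.interface_mass:.0f} "
      f"(target {0.4 * fit.high.interface_mass:.0f})")
print(f"\ndegradation-rate ratio high/low: {fit.ratio}")
print("\nCells must degrade collagen ~2.5x faster in the high-density assay")
print("to produce the observed invasion pattern — dense matrix forces more")
print("proteolysis per cell, a digest-on-demand behaviour.")
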