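"""Run the cellular automaton for the high-density collagen assay.

Simulates 100 timesteps (~48 h) of a tumor spheroid sitting on a low-density
cleft between two dense collagen lattices, then reduces the final state to
the invasion summary.
"""

import cleftsim as cs

params = cs.high_density_params(delta=0.025)  # fitted degradation rate
result = cs.run(params, log=lambda s, c, m: print(
    f"  step {s:3d}: cell mass {c:8.1f}  ecm mass {m:8.1f}"))
summary = cs.summarize_invasion(result.final, params)

print(f"\ninterface mass : {summary.interface_mass:8.1f}")
print(f"bulk 3D mass   : {summary.bulk_mass:8.1f}")
print(f"interface frac : {summary.interface_fraction:8.3f}")
print("\nThe interface fraction is the share of emigrated cell mass that sits")
print("in the cleft plane rather than in the 3D gels; ~0.8 matches the")
print("high-density assay, where four of five emigrating cells follow the cleft.")
print("\nRadial profile (cell mass per 50 um shell beyond the rim):")
print(summary.radial_profile.to_string(index=False))
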