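"""Full pipeline on a synthetic tumor microregion.

Generates a tumor-like microvascular network (heterogeneous diameters and
flows, long diffusion distances), solves oxygen → prodrug → effector
transport for the base Class II hypoxia-activated prodrug, and reports
hypoxia statistics, cell kill with and without 15 Gy radiation, and the
transvascular drug/effector budget.
"""

import numpy as np

import hapsim as hs

net, dom = hs.generate_tumor_like(seed=1, box=(300.0, 250.0, 100.0),
                                  n_vessels=5)
print(f"network: {len(net.segments)} vessels, "
      f"Q/V = {hs.perfusion_per_volume(net):.0f} nl/min/mm3")
d = hs.distance_to_nearest_vessel(net, dom).active_values()
print(f"distance to nearest vessel: median {np.median(d):.0f} um, "
      f"max {d.max():.0f} um, {(d > 50).mean():.0%} of tissue beyond 50 um")

o2 = hs.solve_oxygen(net, dom, hs.OxygenParameters.tumor())
print(f"hypoxic fraction (<4 uM O2): {hs.hypoxic_fraction(o2, 4.0):.1%}; "
      f"severe (<0.13 uM): {hs.hypoxic_fraction(o2, 0.13):.2%}")

psol = hs.solve_prodrug(net, dom, o2, hs.ProdrugParameters())
esol = hs.solve_effector(net, dom, o2, psol, hs.EffectorParameters())
print(f"prodrug extracted from plasma: "
      f"{hs.net_transvascular_per_volume(esol, 'prodrug'):.1f} pmol/mm3")
print(f"effector washed out to plasma: "
      f"{hs.net_transvascular_per_volume(esol, 'effector'):.1f} pmol/mm3")

kill = hs.compute_kill(esol, o2, a=0.200, radiation=hs.RadiationParameters())
print(f"log cell kill: drug alone {kill.kill_drug:.2f}, "
      f"15 Gy alone {kill.kill_rad:.2f}, combined {kill.kill_combined:.2f}")
print(f"drug kill additional to radiation: {kill.additional_kill:.2f} logs")
print("\nAdditional kill > drug-alone kill shows the prodrug preferentially")
print("eliminates the radioresistant hypoxic subpopulation.")
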