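"""Effector washout into the circulation and the systemic exposure bound.

Computes per-volume effector release for modulations of the main kinetic
parameters, then scales a literature worked example (per-volume amounts for
a reference dinitrobenzamide-mustard prodrug system) to a whole 600 mm³
tumor and expresses the worst-case elevation of systemic effector exposure.
"""

import hapsim as hs

net, dom = hs.generate_tumor_like(seed=1, box=(300.0, 250.0, 100.0),
                                  n_vessels=5)
o2 = hs.solve_oxygen(net, dom, hs.OxygenParameters.tumor())
pp, ep = hs.ProdrugParameters(), hs.EffectorParameters()
ps = hs.solve_prodrug(net, dom, o2, pp)

print("effector washout (pmol/mm3) under parameter modulation:")
for label, pp_v, ep_v in [
        ("base model", pp, ep),
        ("kmetP,max x10", hs.ProdrugParameters(kmetP_max=0.1), ep),
        ("kmetE x10", pp, hs.EffectorParameters(kmetE=0.1)),
        ("ktE x10", pp, hs.EffectorParameters(ktE=0.1))]:
    ps_v = ps if pp_v is pp else hs.solve_prodrug(net, dom, o2, pp_v)
    es = hs.solve_effector(net, dom, o2, ps_v, ep_v)
    print(f"  {label:14s} {hs.net_transvascular_per_volume(es, 'effector'):8.2f}")

print("\nworst-case systemic exposure for a 600 mm3 tumor (worked example):")
per_volume = {"H": 3.37, "M": 11.77}       # pmol/mm3 released
CL = {"H": 44.0, "M": 20.0}                # l/h/kg
plasma = {"H": 1.30, "M": 0.71}            # measured free plasma AUC, uM.h
released = {}
for s in per_volume:
    amount = hs.scale_release(per_volume[s], 600.0)
    released[s] = hs.release_to_plasma_auc(amount, CL[s], 0.025)
    print(f"  species {s}: {amount:6.2f} nmol -> {released[s]:.4f} uM.h")
pct = hs.percent_plasma_elevation(released, plasma)
print(f"  percent elevation of systemic effector AUC: {pct:.1f}%")
print("\nEven if everything released in 1 h entered plasma at once, systemic")
print("exposure rises by under one percent for this tumor burden.")
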