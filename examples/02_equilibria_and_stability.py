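"""Equilibria of the visit system and their local stability.

Evaluates the closed-form equilibria, the existence conditions H1-H3
and the stability classification at the nationally fitted parameters.
"""

from hospflow import (
    REFERENCE_PARAMS,
    all_equilibria,
    classify_all,
    existence_conditions,
    stability_conditions,
)

params = REFERENCE_PARAMS

print("existence conditions:", existence_conditions(params))
print("stability conditions:", stability_conditions(params))
print()
for rep in all_equilibria(params):
    if rep.exists:
        x, y, z = rep.point
        print(f"{rep.label}: ({x:9.1f}, {y:9.1f}, {z:9.1f})  exists")
    else:
        print(f"{rep.label}: does not exist (condition violated)")
print()
for rep in classify_all(params):
    eigs = ", ".join(f"{e:+.4f}" for e in rep.eigenvalues)
    print(f"{rep.label}: {rep.classification:9s}  eigenvalues [{eigs}]")

print()
print("H1 fails (r_t < c_t: third-tier growth below churn), so the")
print("TLH-only equilibrium E2 cannot exist; the fully occupied")
print("equilibrium E4 is the unique attractor (H7 holds).")
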