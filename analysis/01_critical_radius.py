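#!/usr/bin/env python
"""Gibbs-Thomson critical radii for real and TIP4P water.

Tabulates the critical ice-embryo radius over a range of supercoolings
for both parameter sets and both geometries, and prints the two headline
numbers: the 518 A spherical embryo for real water at 1 K supercooling
(~1.8e7 molecules -- why brute-force simulation of homogeneous growth is
hopeless) and the 46 A cylindrical radius for TIP4P at 5 K (the curvature
an adsorbed AFP must force on the model ice front to halt it).
"""

from pathlib import Path

import pandas as pd

from afpice.thermo import REAL_WATER, TIP4P, critical_radius

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for params in (REAL_WATER, TIP4P):
    for geometry in ("spherical", "cylindrical"):
        for dT in (0.5, 1.0, 2.0, 5.0, 10.0, 20.0):
            res = critical_radius(params, dT, geometry)
            rows.append(
                {
                    "model": params.name,
                    "geometry": geometry,
                    "supercooling_K": dT,
                    "R_angstrom": res.R_angstrom,
                    "volume_A3": res.volume,
                    "n_waters": res.n_waters,
                }
            )
df = pd.DataFrame(rows)
df.to_csv(OUT / "critical_radius.csv", index=False)

sphere = critical_radius(REAL_WATER, 1.0, "spherical")
cyl = critical_radius(TIP4P, 5.0, "cylindrical")
print(f"wrote {OUT / 'critical_radius.csv'} ({len(df)} rows)")
print(
    f"real water, 1 K, sphere:  R = {sphere.R_angstrom:.0f} A, "
    f"V = {sphere.volume:.3g} A^3, {sphere.n_waters:.2g} molecules"
)
print(f"TIP4P, 5 K, cylinder:     R = {cyl.R_angstrom:.1f} A")
print(
    "finding: a critical embryo at 1 K supercooling needs ~18 million waters; "
    "growth must instead be seeded, and a ~46 A cylindrical curvature is enough "
    "to stall TIP4P ice at 5 K below its melting point."
)
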