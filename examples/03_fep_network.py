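"""Free-energy network diagnostics on a synthetic five-ligand panel.

Generates per-leg edges from additive node free energies plus noise, then
reports hysteresis, cycle closure and reference-anchored relative pKd values.
"""

import numpy as np

from macrodissect.fep_network import (
    build_network,
    cycle_closure,
    edge_hysteresis,
    relative_dpkd,
    restraint_sensitivity,
)
from macrodissect.synthetic_data import NetworkSpec, make_fep_network

node_dg = {"5": 0.0, "7": 2.7, "9": 1.4, "11": -0.7, "12": -0.6}  # kcal/mol vs ligand 5
edges = [("5", "7"), ("7", "9"), ("9", "5"), ("5", "11"), ("11", "12"), ("12", "5")]

tables = {}
for fc in (0.1, 1.0, 10.0):  # restraint force constants, kcal/mol/A^2
    spec = NetworkSpec(node_dG=node_dg, edges=edges, noise_sigma=0.15,
                       force_constant=fc, seed=int(fc * 10))
    fep_edges = make_fep_network(spec)
    net = build_network(fep_edges, reference="5")
    hyst = [h for e in fep_edges if (h := edge_hysteresis(e)) is not None]
    closure = cycle_closure(net)
    tables[fc] = relative_dpkd(net)
    print(f"fc={fc:>4}: RMS hysteresis {np.sqrt(np.mean(np.square(hyst))):.3f} kcal/mol, "
          f"RMS cycle closure {closure['rms_closure_kcal_mol']:.3f} kcal/mol")

print("\ndpKd vs reference ligand 5 (per restraint level):")
for fc, table in tables.items():
    print(f"  fc={fc:>4}: " + ", ".join(f"{lig}:{v:+.2f}" for lig, v in sorted(table.items())))

sens = restraint_sensitivity(tables, flag_threshold=0.5)
print("\nspread across restraint levels (flag if > 0.5 pKd):")
print(sens.to_string(index=False))
# similar dpKd across restraint levels indicates the estimates reflect the
# direct interaction/solvation term, not the restraint strength.
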