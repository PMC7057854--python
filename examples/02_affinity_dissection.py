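"""Dissecting an affinity difference into direct and conformational terms.

Uses the published bioactive-population occupancies of the Et/Me (40%) and
H/H (6%) macrocycles together with a restrained-FEP direct-interaction
estimate of ~2 pKd units.
"""

from macrodissect.thermo import apparent_pkd, bei, conformational_dpkd, dissect

# conformational term from free-ligand populations
dpkd_conf = conformational_dpkd(0.40, 0.06)
print(f"conformational dpKd (40% vs 6% bioactive): {dpkd_conf:.3f} -> ~{round(dpkd_conf, 1)}")

# combine with the direct interaction/solvation term from restrained FEP
result = dissect(direct=2.0, conformational=dpkd_conf, ligand_pair=("11", "7"))
print(f"total dpKd: {result.dpkd_total:.2f}")
print(f"fraction conformational: {result.fraction_conformational:.2f} (~ one third)")

# the population penalty on a single ligand's apparent affinity
print(f"apparent pKd of a 7.0 binder at 6% occupancy: {apparent_pkd(7.0, 0.06):.2f}")

# size-normalised potency
print(f"BEI of a pKd 6.06 ligand at 1358 g/mol: {bei(6.06, 1358.0):.2f}")
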