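# macrodissect

Tools for dissecting the binding affinity of large, flexible macrocyclic
ligands into a **direct-interaction** term and a **conformational** term, and
for modelling their lipophilicity from ensemble-averaged surface areas.

## The problem

Macrocyclic peptides bind flat protein surfaces that small molecules cannot,
but they remain highly flexible in solution: only a fraction *p* of the free
ligand's conformers resemble the bound ("bioactive") conformation.  That
fraction carries directly into the apparent binding constant,

```
Kd_app = Kd / p          <=>   pKd_app = pKd + log10(p)
```

where `Kd` is the binding constant of the conformationally locked compound.
Between two ligands A and B, the conformational contribution to their
affinity difference is

```
ΔpKd_conf = log10(p_A / p_B)
```

Relative free-energy (FEP) calculations run with the ligand restrained to
the bound conformation converge well but capture only the direct
interaction/solvation term; free-ligand enhanced-sampling MD supplies *p*.
Adding the two dissects an observed structure–affinity trend into physically
distinct contributions.  The same free-ligand ensembles yield *dynamic*
polar and nonpolar surface areas (PSA/NPSA), which model the measured
octanol/water distribution coefficient as
`logD = a·NPSA + b·PSA + c`.

`macrodissect` implements the full downstream analysis: ensemble I/O and
RMSD population analysis with block-averaged uncertainties, free-energy
network diagnostics (hysteresis, cycle closure, least-squares node
estimates, restraint sensitivity), Shrake–Rupley SASA with polar/nonpolar
partition, the affinity algebra, the logD regression — plus seeded
synthetic-data generators so everything runs and is validated without an MD
engine.

## Worked example

```python
from macrodissect.thermo import conformational_dpkd, dissect

dpkd_conf = conformational_dpkd(0.40, 0.06)   # Et/Me at 40% vs H/H at 6%
result = dissect(direct=2.0, conformational=dpkd_conf, ligand_pair=("11", "7"))
print(round(dpkd_conf, 3), round(result.dpkd_total, 2),
      round(result.fraction_conformational, 2))
```

prints `0.824 2.82 0.29`: a 40% vs 6% bioactive occupancy is worth ~0.8 pKd
units, and combined with a ~2 pKd direct term the conformational preference
accounts for roughly one third of the total affinity gain.

Running the population stage on a synthetic bimodal ensemble
(`python examples/01_population_analysis.py`):

```
frames: 2500, RMSD range 0.33-3.71 A
p1 (RMSD <= 2.6 A): 0.300 +/- 0.020 (1 sigma over 5 blocks)
ground truth bioactive fraction: 0.300
```

The occupancy of the bioactive population (frames within 2.6 Å RMSD of the
bound reference) is recovered with its 1σ uncertainty estimated over five
contiguous trajectory blocks.  The `examples/` directory holds one short
script per capability (populations, dissection, network diagnostics,
surface/logD modelling, the full pipeline); a thin CLI
(`macrodissect simulate|populations|fep|dissect|lipo|report`) drives the
same stages from a YAML config.

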