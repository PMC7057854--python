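# Methods

## Conformational dissection model

The package assumes a two-state picture of the free ligand: a *bioactive*
population (population 1) whose conformers overlay the protein-bound
reference, and a non-bioactive population (population 2) comprising
everything else.  Binding proceeds only from population 1, so with
occupancy `p` the apparent dissociation constant of the flexible ligand is
`Kd_app = Kd / p`, i.e. `pKd_app = pKd + log10 p`, where `Kd` refers to the
hypothetical conformationally locked compound.  The conformational
contribution to a *pairwise* affinity difference is then
`ΔpKd_conf = log10(p_A / p_B)` — independent of the locked `Kd` as long as
the two ligands share a binding mode.

The direct interaction/solvation term comes from relative free-energy
calculations run with the ligand (and protein backbone) restrained to the
bound conformation; restraining suppresses exactly the conformational
equilibrium the population term reintroduces, which is what makes the two
terms additive.  No restraint-free-energy debiasing is attempted: restraint
force constants are treated as metadata labels, and the
`restraint_sensitivity` report quantifies how much the node estimates move
across levels instead.

Free energies convert to affinity units as
`ΔpKd = -ΔΔG / (ln 10 · R · T)` with `R = 1.9872e-3 kcal/(mol·K)` and
`T = 298.15 K` by default (configurable).

## Population analysis

Per-frame RMSD against the bound-state reference is computed by Kabsch
superposition (SVD with sign correction; proper rotations only) over a
configurable atom selection.  The default selection for the bundled toy
systems is the macrocycle backbone heavy atoms plus the crosslink carbons;
free-ligand ensembles are fit on the ligand itself since no protein is
present.  Dihedrals follow the IUPAC sign convention and are invariant
under atom-order reversal.

The RMSD distribution is histogrammed at 0.1 Å bin width (left-closed bins
from 0).  Population 1 is `RMSD <= threshold` with the threshold a config
value defaulting to 2.6 Å; frames exactly at the threshold count as
population 1.  A helper locates the histogram minimum inside a user-given
window as an aid for choosing the threshold, but automatic selection is
never applied silently.

Uncertainties use block averaging: the trajectory is split into 5
contiguous, order-preserving blocks (sizes differing by at most one frame)
and the 1σ spread of per-block occupancies (sample standard deviation,
ddof = 1) is reported.  With a single block the uncertainty is reported as
absent, never as zero.  Block-to-block distribution drift is quantified as
the pairwise L1 distance between normalized per-block histograms on shared
bins; the maximum pairwise distance is the convergence score.

## Free-energy network

Each alchemical edge carries one ΔΔG per leg (complex, solvent);
`ΔΔG_bind = ΔΔG_complex − ΔΔG_solvent`.  Hysteresis is defined as
forward + backward ΔΔG of a leg (zero when converged); cycle-closure errors
are signed sums around a cycle basis of the undirected network.  Node free
energies relative to the reference ligand solve the overdetermined edge
system by ordinary least squares with the reference eliminated (pinned at
zero); for trees this reduces to exact path sums, and for redundant
networks it has the usual Gauss–Markov variance advantage over any single
path, which the tests verify by simulation.

## Surface areas and lipophilicity

SASA uses the Shrake–Rupley construction with a deterministic golden-spiral
point lattice — no random numbers, so results are bit-for-bit reproducible
at fixed `n_points` (default 960; probe radius 1.4 Å, water).  A sample
point on the solvent-expanded sphere `r_i + probe` is accessible iff it
lies strictly outside every other expanded sphere; exactly coincident
equal-radius atoms therefore each keep their shared surface, a documented
degenerate behaviour.  Accuracy is validated against the closed-form
two-sphere spherical-cap area and against an independent reference
implementation (biotite) on random fixtures.

Atoms are classed polar (N, O, S, and H attached to them) or nonpolar
(C, P, H on carbon); the ruleset is swappable for stricter PSA definitions.
Hydrogen attachment uses bond records when present, else the nearest heavy
atom in the first frame.  Van der Waals radii default to the Bondi set,
overridable per element.  PSA/NPSA are sums of per-atom SASA by class; the
all-atom convention (hydrogens included) is the default, and heavy-atom-only
analyses can be expressed through the ruleset.  Ensemble ("dynamic") PSA and
NPSA are arithmetic means over frames, with 1σ over frames or over
contiguous blocks.

logD is modelled as `logD = a·NPSA + b·PSA + c`, fit by ordinary least
squares on whatever descriptor scale the caller supplies; no hidden
normalisation is applied and the scale is recorded in the model metadata.
A constant response yields zero slopes and an absent fit correlation;
collinear descriptors raise.  Group-contribution XlogP values are consumed
as an input column for comparison only.

## Competition binding

`ki_from_ic50` defaults to the classical Cheng–Prusoff correction
`Ki = IC50 / (1 + [tracer]/Kd_tracer)`.  For fluorescence-polarization
competition assays where the protein is not in trace amounts, an `fp` mode
implements the exact-concentration variant
`Ki = IC50 / ([L]50/Kd + [P]0/Kd + 1)`, deriving the free tracer at 50%
inhibition and free protein at 0% inhibition from the totals via the
one-site binding quadratic; the free inhibitor at 50% inhibition is
approximated by the IC50 itself.  Both modes are exposed because the
literature uses both; the default is the classical form and the choice is
always explicit in code.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* each analysis stage
assumes, not molecular physics:

- `make_toy_macrocycle` builds an idealised ring of pseudo-residues
  (N, Cα, C, O, amide H; ~3.8 Å Cα spacing, slight pucker) with a
  two-carbon crosslink chord and named masks.  It is a geometry fixture,
  not a force-field structure.
- `make_bimodal_ensemble` emits native frames (reference + isotropic
  Gaussian jitter, σ = 0.25 Å per coordinate by default → RMSD mode
  ≈ 0.4 Å) and decoy frames in which the crosslink-bearing half of the ring
  is flipped 150–210° about the anchor axis and displaced 4 Å (RMSD mode
  ≈ 3.2 Å), mimicking the crosslink leaving its bound-state position.  The
  generator warns if the two RMSD modes are closer than four pooled σ.
  Default ensemble length is 2500 frames, mirroring a five-block trajectory
  layout.  Real ensembles have autocorrelated frames and many metastable
  states; passing tests therefore demonstrate correct bookkeeping and
  statistics, not MD convergence.
- `make_fep_network` draws each leg's ΔΔG as an additive node difference
  plus `N(0, σ)`, with backward values as minus the true leg value plus an
  independent `N(0, σ)` draw, making forward/backward hysteresis the sum of
  two independent normals (RMS σ√2).
- `make_lipo_dataset` samples descriptors uniformly (PSA 4.5–5.5, NPSA
  8–10 in scaled units) and generates logD from the coefficient set
  (0.27, −0.82, 2.22) plus noise, so the regression's recovery can be
  checked exactly.

All generators take one seed, use a single `numpy` Generator per
invocation, and are bit-for-bit reproducible.

## Numerical conventions

- Coordinates in Å throughout; atom indices 0-based in memory, 1-based in
  PDB serials; PDB coordinates printed at 3 decimals, XYZ at 6.
- Kabsch requires ≥ 3 non-collinear selection atoms (second singular value
  ≥ 1e-8 of the first) and resolves reflection cases toward a proper
  rotation.
- Dihedral degenerate geometry (coincident consecutive points, collinear
  triples) raises instead of returning a value.
- Reports are written with sorted JSON keys, fixed float formatting and no
  timestamps, so reruns under one config and seed are byte-identical.

## Problem sizes

The default synthetic study uses five ligands at bioactive occupancies
6/16/30/40/30 %, 2500 frames per ensemble, three restraint levels with
σ = 0.15 kcal/mol edge noise, and SASA evaluated on every 25th frame at 960
sphere points — sizes chosen so a complete pipeline run takes seconds on a
single core while leaving the statistical checks (binomial recovery bands,
block-σ consistency, network variance comparisons) well resolved.

## Known limitations

- The two-state population model ignores intermediate conformations and
  binding-competent sub-states; ligands without clean bimodality need a
  different decomposition.
- Least-squares node estimation weights all edges equally; per-edge
  uncertainties, if available, are not yet used as weights.
- The pairwise-distance SASA implementation is O(n²) per frame — fine for
  ligand-sized systems (tens to hundreds of atoms), not intended for whole
  proteins.
- Binary trajectory formats (DCD/XTC) are out of scope; convert to
  multi-model PDB or XYZ upstream.
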