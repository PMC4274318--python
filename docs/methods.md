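# Methods

This note documents the models implemented in `spindock`, the defaults
and why they were chosen, the numerical decisions that are not obvious
from the code, and what the synthetic benchmarks do and do not
demonstrate.

## Coordinate substrate

Structures are fixed-column PDB ATOM records with a strict dialect: a
terminal `END` line, no tabs, residue names in columns 18–21 (four
characters, so the spin-ensemble residue `SPIN` fits), and a segment
identifier in columns 73–76 that supersedes the chain character for all
selections.  Four-character atom names (`N001`…`N190`) occupy columns
13–16 exactly; shorter names follow the usual convention of starting at
column 14.  HETATM records are dropped on read by default (retained with
a flag); alternate locations and insertion codes are rejected with a
clear error rather than silently flattened — the workflow never produces
them.  Multi-model records (`NUMMDL`/`MODEL`/`ENDMDL`) and `TER` cards
are ignored, so an NMR-style multi-model file is flattened into one atom
list.

The selection language supports `segid`, `chain`, `resname`, `resid`
(single or inclusive `a:b` range), `name` with shell globs, and
`and`/`or`/`not` with parentheses.  Evaluation is vectorised and always
returns atoms in structure order.

## Spin-label ensembles

**R1 (MTSL on a single cysteine).**  The label is rebuilt at the site
from idealised internal coordinates for the Cys–S–S–CH2–pyrroline linker
(bond lengths 1.81/2.04/1.81/1.50 Å, tetrahedral-to-trigonal angles, a
planar five-membered nitroxide ring with the N–O bond in plane; methyl
groups omitted because the steric envelope is dominated by the ring and
linker heavy atoms).  The five rotatable dihedrals are sampled uniformly
on [0°, 360°); each trial conformer is rejected if any of its heavy atoms
approaches a protein heavy atom closer than a scaled sum of van der Waals
radii.  The two named clash modes map to scale factors on the radius sum:
`tight` = 0.90, `loose` = 0.75.  The labelled residue itself is excluded
from the clash set entirely (the mutation replaces its side chain, and
gauche χ1 conformers legitimately pass within ~3 Å of its own backbone),
as are `SPIN` pseudo-atoms from any previously placed ensemble — an
ensemble is a population, not physical matter.  Sampling stops when
`max_conformers` (default 200) survive or the trial budget
(`thoroughness`, default 5000) is exhausted; zero survivors raise an
error that advises raising the thoroughness or loosening the clash
cutoff.

**Rx2 (bis-reactive label bridging two cysteines).**  The pseudo-cyclic
side chain cannot be enumerated by a rotamer search, and no published
internal geometry was available to reproduce, so the ensemble is
generated by constrained geometric sampling: nitroxide positions are
drawn from the intersection of two spherical shells centred on the two
anchor CB atoms, with shell radii sampled uniformly from the reachable
arm-length band (5.0–8.0 Å, the span of a CB–S–S–CH2–ring arm), using
the standard two-sphere circle construction with uniform azimuth, then
clash-filtered like R1.  Anchors further apart than a configurable reach
(default 12 Å) are rejected.  This sampler is a deliberate, documented
simplification: it reproduces the two defining properties of a bridging
label — both attachment constraints hold for every conformer, and the
ensemble is markedly narrower than an R1 cloud at the same site — but it
is not a conformational-energy-weighted ensemble.

**Extraction.**  The restraint endpoint is the N1 nitroxide-nitrogen
position.  The first min(n, 190) conformers (sampling order under the
seed) yield an ensemble emitted as one `SPIN` residue, atoms named
`N%03d`; 190 is the per-residue atom cap of the downstream dialect.
Which conformers survive the cap is therefore order-dependent, exactly
like a head-truncation of a conformer file.

All sampling is reproducible under a fixed seed and rigidly equivariant:
labelling a rotated structure yields the rotated ensemble.

## Distance restraints

The effective distance between two ensembles under R⁻³ averaging is
`(mean over cross pairs of r⁻³)^(−1/3)`; the mean (not the sum) is used
so that a singleton-vs-singleton restraint degenerates to the plain
distance.  R⁻⁶ and centroid averaging are provided for completeness.

The square-well energy of a restraint with target d and bounds
(−minus, +plus) is zero inside the well and otherwise

    E = scale · min(ceiling, sqconstant · v^sqexponent),

with v the violation.  Two conventions deserve note:

* **The ceiling caps the unscaled well term.**  With ceiling 50 and
  scale 10 a per-restraint energy of 86.26 (violation 2.937 Å) is
  reportable — the cap binds only at `scale × ceiling = 500`, i.e. at
  violations beyond `√(ceiling/sqconstant) ≈ 7.07 Å`.
* **The reported delta is signed as (violated bound − r_eff)**, so an
  overlong distance prints a negative delta.

A hard cap would make badly violated restraints force-free: at a 100 Å
body separation every restraint would sit on the flat capped plateau and
rigid-body minimisation could never start.  The *minimisation objective*
therefore continues linearly beyond the cap with the slope at the
crossing (C¹-continuous), while every *reported* energy — breakdown rows,
summaries, totals — is the capped value.  The far-field pull per
restraint is then constant (`2·scale·sqconstant·v_c ≈ 141 kcal·mol⁻¹·Å⁻¹`
at the defaults).

Summaries report the RMS of the signed deltas over **all** rows (a
violated-only RMS is easy to recover since deltas are per-row) and count
a row as violated when |delta| > 0, mirroring the classic printout.

## Symmetry (NCS) restraints

An equivalence group is a list of copies — ordered atom selections of
equal cardinality.  Copies are superposed (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`, with an explicit
degeneracy check for collinear sets) onto a running average, and the pass
is repeated to a fixed point; the energy is

    E = Σ_copies weight · Σ_atoms |z_i − mean_i|² .

At the fixed point each copy is optimally superposed onto the final mean
and the mean is self-consistent, so by the envelope theorem the gradient
reduces to `2·weight·(z − mean)` rotated back into each copy's frame —
the implicit dependence of the rotations and the mean on the coordinates
contributes nothing.  This makes the analytic gradient exact, which the
test suite verifies against finite differences.  The energy is invariant
under any global rigid motion of a whole copy.  For two copies the
functional form collapses to `weight/2 ×` the squared superposition
misfit, which is the closed-form oracle used in the tests.  `sigb` is
parsed for interface fidelity but unused — no B factors are refined.

Because this penalty only requires *some* rigid correspondence between
the copies, a two-copy group whose copies are built from both bodies
(e.g. A+D vs C+B) constrains the relative pose to an involution (a C2
arrangement) rather than to one specific C2 axis; the distance restraints
select among those.  This is why symmetry restraints alone never suffice
and why the fixture supplies several restraints (see below).

## Non-bonded terms

A deliberately small per-element table supplies vdW radii, LJ well depths
and crude name-based backbone partial charges (C 1.90 Å/0.10; N 1.65/0.17;
O 1.55/0.15; S 2.00/0.25; H 1.10/0.03; default 1.80/0.10; charges
N −0.47, C +0.51, O −0.51, CA +0.07).  There is no bonded force field —
the bodies are rigid — so pairs within the same segment and within one
residue of each other are excluded from all non-bonded sums (they are
covalent 1-2/1-3/1-4 neighbours).  `SPIN` atoms are excluded from
non-bonded terms entirely: scoring contacts against a whole conformer
population would overestimate any single label's interaction many-fold.

Two evaluation modes, switched by `repel`:

* **Soft repulsion** (`repel > 0`):
  `E = k Σ max(0, (repel·(r_i+r_j))² − d²)²` with k = 4.0
  kcal·mol⁻¹·Å⁻⁴.  At `repel = 1e-9` the term is numerically zero for any
  physically separated atoms — bodies are ghosts; at 0.7 it restores
  excluded volume.  The term is non-negative, zero beyond scaled contact,
  monotone in distance and in `repel`.
* **Physical terms** (`repel = 0`): 12-6 Lennard-Jones with
  `r_min = r_i + r_j` and geometric-mean well depth, switched off
  smoothly over the 6.0–6.5 Å window, plus Coulomb electrostatics
  (332.06 kcal·Å·mol⁻¹·e⁻²) with shift-function truncation
  `(1 − (r/ctofnb)²)²`, zero beyond 6.5 Å.  Pair lists are built with a
  7.5 Å cutoff (scipy cKDTree).

Because of the united-heavy-atom treatment, absolute VDW/ELEC magnitudes
are not comparable with a full-force-field calculation; only their
qualitative staging behaviour (huge when interpenetrating at `repel` 0.7,
modest and often attractive after refinement) carries meaning.

## Rigid-body minimisation

Each rigid group is addressed by a selection (protein segments plus the
spin ensembles that ride on them).  Poses are applied as exact rotation
matrices about the group centroid plus translations, so internal geometry
is preserved to floating-point precision; the test suite checks sampled
intra-body distances to 1e-9 Å across whole trajectories.

The pose gradient of a group is the summed atomic force (translation) and
the torque about the centroid (rotation).  The default minimiser is
gradient descent with a backtracking line search: the rotational
component of the descent direction is the torque divided by the group's
mean squared atom radius (so rotation and translation steps live on
comparable scales), the first trial step is sized so the predicted linear
decrease equals `drop` (default 10 kcal·mol⁻¹), accepted steps must
strictly decrease the stage objective, the step grows ×2 after success
and halves on failure, and the stage stops at `nstep` iterations, a
zero-gradient point, or five consecutive improvements below 1e-6.  A
derivative-free Powell minimiser over the stacked (rotation-vector,
translation) parameters is available as a fallback; it never accepts an
uphill result.

The staged protocol is: (1) restraints only, `repel = 1e-9`, 100 steps;
(2) restraints + NCS, `repel = 1e-9`, 200 steps; (3) + soft repulsion at
`repel = 0.7`, 100 steps; (4) torsion refinement with `repel = 0`
(LJ + electrostatics).  Intermediate structures are written as
`RES/noe.pdb`, `RES/noencs.pdb`, `RES/noencsvdw.pdb` and
`RES/noencsvdwdynint.pdb`.  During rigid stages only inter-body
non-bonded pairs are evaluated; the torsion stage adds per-segment
self-interactions over the flexible interface residues with
electrostatics weight 0 (intra-body electrostatics would otherwise
dominate the refinement).

## Torsion refinement

Side chains of residues inside the configured flexible interface ranges
rotate about their χ axes; backbone atoms (and CB) never move, PRO is
wholly rigid, and the ring moieties of PHE/HIS/TYR/TRP move only as rigid
units — a χ rotation transforms the whole distal set rigidly, so ring
internal geometry is preserved exactly.  The optimiser is coordinate
descent: for each residue and χ in turn, a coarse 15° scan followed by a
3° local scan picks the best rotation, evaluated on the non-bonded energy
of the moving atoms against everything outside their own residue
(inter-body pairs with full weights, intra-body with electrostatics
zero).  Sweeps repeat until no χ improves by more than 1e-6 or the
evaluation budgets are exhausted (`nstep` = 2000 total trial evaluations,
`maxe` = 1000 per sweep, `depred` seeds the breakdown stage).  This is
minimisation in torsion space, not thermostatted dynamics: the use case
is energy minimisation, and a minimiser is the direct implementation of
that intent.

## Synthetic benchmark

The fixture generator builds idealised α-helical chains (φ = −57°,
ψ = −47°, NeRF construction with standard bond geometry) — poly-alanine
with PHE/LEU/TYR at a third, half and two-thirds of the chain so torsion
refinement has bulky side chains to move.  Two antiparallel chains form a
dimer; the planted tetramer duplicates the dimer, applies a 180° rotation
about z plus an in-plane offset (an exact C2 when the offset has no z
component), and then separates the copy by (0, 100, 0) Å to create the
docking start — the copy already carries the planted *orientation*, as it
would when two crystallographic dimers are superposed and translated
apart before docking.  Default offsets (x ∈ [42, 44] Å, y ∈ [4, 7] Å,
drawn per seed) put the ground-truth interface in contact (minimum
inter-body distances of roughly 2.5–6 Å) without interpenetration.

Labels are placed at four sites per body (residues 6 and 18 of one chain,
12 and 20 of the other); ten restraints are derived from the ground-truth
R⁻³ distances of mirrored site pairs with bounds ±max(noise, 0.1) Å.
Ten restraints from four non-collinear sites per body are deliberate:
cross-ensemble distances are invariant under reflection of one body, and
with too few restraints a wrong C2 arrangement can satisfy both the
distance and the symmetry restraints — three sites and six restraints
were observed to admit exactly such a spurious solution.  The two NCS
groups are ordered concatenations consistent with the planted chain
mapping (A+D vs C+B, and B+C vs D+A); by the relabelling symmetry of the
two-copy energy the two groups evaluate identically on any pose.

Under these conditions the four-stage protocol recovers the planted
relative transform to about 1° and 0.6 Å (tested over 20 seeds at a
≥90% success criterion of 2 Å / 5°, with each seed redrawing the planted
offset, the label ensembles and the restraint noise).  The residual
~0.6 Å bias reflects the ±0.1 Å restraint wells and the finite label
ensembles, not a minimiser failure.

What passing these benchmarks shows: the energy terms and their gradients
are mutually consistent, rigid geometry is preserved, symmetric solutions
are found from a 100 Å separation, and the pipeline is deterministic
under seeds.  What it does not show: performance on real proteins —
the fixtures have no backbone flexibility, no hydrogens, toy partial
charges, and restraint noise far below experimental PELDOR distance
uncertainties.  Recovering a published assembly additionally requires the
deposited coordinates and a full force field, which are outside the test
scope.

## Numerical choices and degenerate inputs

* Rotations are applied as matrices from rotation vectors
  (`scipy.spatial.transform.Rotation`); orthonormality of user-supplied
  matrices is checked to 1e-8 and improper rotations rejected.
* Kabsch superposition rejects point sets whose second singular value is
  below 1e-8 of the first (collinear/degenerate).
* Coincident atoms across restraint ensembles (r = 0) raise rather than
  returning an infinite average.
* Pair lists are rebuilt at every energy evaluation; with `repel > 0` the
  build cutoff shrinks to the largest scaled contact distance.
* `e14fac`, `wmin` and `sigb` are parsed and stored for config fidelity
  but unused: there are no 1-4 pairs across rigid bodies, no pair-list
  diagnostics, and no B-factor refinement.
* The line search halves at most 50 times before declaring convergence;
  a non-finite starting energy is an error, not a silent reset.

## Known limitations

* No bonded force field: BOND/ANGL/DIHE/IMPR always report 0.000.
* The Rx2 sampler is geometric, not energetic (see above).
* Conformer populations are unweighted (no rotamer-library weighting).
* The torsion stage handles χ1/χ2 of F/Y/W/H/L; longer side chains
  (K, R, E, …) would need additional χ definitions in `_CHI_MOVING`.
* One restraint class per run (a single parameter set applies to all
  restraints).
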