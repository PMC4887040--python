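# Methods

`enzymatch` places an idealized active site — a transition-state (TS) model
plus a multi-residue catalytic motif with geometric constraints — onto
protein scaffolds by continuous loop closure, prunes and ranks the resulting
matches, and evaluates them by rotamer-based side-chain repacking. This note
documents the model, its assumptions, the numerical choices, and what the
synthetic test bed does and does not demonstrate.

## Active-site model

A motif couples a TS model (a small-molecule fragment defined by a serial
z-matrix with partial charges and optional rotatable torsions) to residue
*roles* of three classes: catalytic residues, residues stabilizing the
catalytic residues, and residues binding the TS. A *minimal* motif restricts
to the catalytic roles; a *complex* motif keeps all three classes. Roles
interact through their side chains or through backbone amide groups
(oxyanion-hole style donors), and each role carries geometric constraints —
distances (Å), angles (deg) and improper dihedrals (deg), each with an
optimal value and a tolerance.

For kinematics, the constraints attached to a role are compiled into a
six-degree-of-freedom *attachment block* between a residue atom triple
(A1, A2, A3) and a partner triple (B1, B2, B3) on the TS or on another,
earlier-placed role: one distance (A1–B1), two angles (A2-A1-B1, A1-B1-B2)
and up to three dihedrals. Dihedrals omitted from the motif file are free
torsions. This is the standard matcher parameterisation of a theozyme
constraint and is exactly sufficient to place one rigid group relative to
another.

Covalent attack geometry is expressed by making the nucleophile-derived atom
part of the TS model (the forming bond belongs to the reaction center): for
a serine nucleophile the TS carries the shared oxygen, the serine attaches
via a ~1.4 Å CB–O pseudo-bond, and the grafted serine omits its own OG (and
dependent hydroxyl hydrogen). The catalytic histidine is modeled with both
ring nitrogens protonated (imidazolium-like): in the covalent-intermediate
context the base has abstracted the nucleophile proton and donates hydrogen
bonds on both sides. Acceptor-histidine tautomers are not modeled; this is a
deliberate simplification appropriate for the catalytic context and noted as
a limitation.

## Matching by loop closure

For a candidate assignment of roles to scaffold sites, a *main loop* threads:
start-anchor backbone (N, CA, C of the first site) → the first role's side
chain → the attachment pseudo-bond into the TS → the TS internal frame (plus
its rotatable torsions) → the attachment pseudo-bond out of the TS → the
second role's side chain rebuilt in reverse → a computed backbone whose
deviation from the second site's real N/CA/C is the closure objective. Every
other role contributes a *side loop* built outward from already-placed atoms
to its own site's backbone. Anchors are rigid; bond lengths and angles never
change during closure — only torsions move.

Numerical choices:

* **Constraint distances are frozen at their optima** during kinematics (they
  act as pseudo-bond lengths); constraint angles enter as fixed NeRF bond
  angles at the optimum and constraint dihedrals become *bounded* torsion
  variables (optimum ± tolerance). Distance/angle tolerance slack is
  therefore not explored during closure — an approximation; the final match
  check measures all constraints explicitly.
* **Closure solver.** The primary solver minimizes the weighted squared
  deviation of the computed terminal N/CA/C from the anchor (weights 0.7 /
  1.0 / 0.7) by damped Gauss–Newton steps — a quasi-Newton scheme whose
  Hessian approximation is JᵀJ — with analytic torsion jacobians (rigid
  rotation about each torsion axis; validity is verified structurally at
  chain build time, with a finite-difference fallback) and projection onto
  bounded-torsion ranges. It is batched over the multistart.
* **Acceptance of a closed loop** requires the terminal CA within the closure
  tolerance (default 0.1 Å) and the flanking N and C atoms within twice the
  tolerance — otherwise the backbone frame, not just the CA position, would
  be wrong.
* **Extended CCD baseline.** A one-torsion-at-a-time solver using the classic
  closed-form rotation that best aligns the three terminal atoms; it shares
  the acceptance contract and serves as the comparison baseline.
* **Multistart.** Free sp3-like torsions enumerate a 120° grid, sp2-like
  torsions a 180° grid, bounded torsions seed at their optimum; grids larger
  than the cap (default 128) are subsampled reproducibly.

## Pruning

Four stages keep enumeration tractable:

1. **Maximum reach.** Before closure, the loop's maximum start-to-terminal CA
   distance is estimated by running the closure optimizer against a phantom
   target 1,000 Å away along the anchor direction, from the multistart plus
   the most extended random conformations, followed by a cyclic 1-D polish
   (the constrained maximum usually sits on a torsion bound, where
   Gauss–Newton steps stall). The result is inflated by a 0.2% safety factor
   to cover optimizer slack and cached per residue-type pair (it is rigid-
   motion invariant). Site pairs farther apart than reach + margin (0.5 Å)
   are pruned. The same bound prunes side-loop sites.
2. **Deduplication.** Converged loops within 0.5 Å no-fit RMSD of a kept loop
   are dropped (greedy, in input order; the engine orders candidates by
   closure deviation first so the best representative of each cluster
   survives).
3. **Immediate constraint checks** on freshly closed loops against already-
   placed atoms.
4. **Linear repulsion thresholds.** e(r) = k·max(0, c(Ri+Rj) − r)/(c(Ri+Rj))
   with k = 10 PEU per fully overlapping pair and clash onset c = 0.85,
   summed over heavy-atom pairs. Thresholds: 150 PEU (closed main loop vs
   backbone), 30 (side loop vs backbone), 200 (whole match vs template),
   50 (whole match vs backbone), where *backbone* means main-chain atoms of
   candidate-site residues and *template* all atoms of non-candidate
   residues. The thresholds are calibrated so planted ground-truth matches
   always pass (verified by the test suite). PEU ("package energy units") is
   this model's own scale; absolute values are not comparable across energy
   functions.

Matches are ranked ascending by
`rms(normalized constraint deviations) + total repulsion / 100 PEU`,
normalizing 1 Å of distance deviation like 10° of angular deviation (both
weights configurable); ties break on lower repulsion, then lexicographic
site ids. The ranking functional is this package's own choice — constraint
quality is what separates native-like from spurious matches.

TS placement accuracy is reported as **no-fit RMSD** over TS heavy atoms in
the scaffold frame (a match must put the TS where the reference has it; a
fitted RMSD would forgive rigid displacement). The fitted (Kabsch) value is
also available.

## Repacking

Residues with any heavy atom within 7.0 Å of the TS (prolines excluded) are
repacked with the TS fixed. Each site's rotamers come from a compact
backbone-independent chi-grid library (shipped as plain text; the loader
accepts any library in the same format) *augmented with the input side-chain
conformation* — standard practice for recapitulation, and necessary because
a coarse chi grid cannot reproduce arbitrary input torsions. Ser/Thr/Tyr/Cys
hydroxyl hydrogens are expanded on a 120° torsion grid at fixed heavy-atom
geometry. Residues covalently attached to the TS are held fixed (their
conformation is set by the bond), with 1-2 through 1-4 interactions across
the junction excluded from scoring.

The energy model is a documented surrogate: linearized-repulsion van der
Waals with a capped r⁻⁶ attractive tail, a directional 10–12 hydrogen-bond
term (ideal H···acceptor 1.9 Å, reward 2.5 PEU, gated on the D-H···A angle),
and screened Coulomb electrostatics with a distance-dependent dielectric
(ε = 4r), all capped so every table entry is finite. Polar-hydrogen/acceptor
pairs are owned by the hydrogen-bond term and excluded from van der Waals.

Dead-end elimination uses the Goldstein criterion iterated to a fixed point;
eliminated rotamers provably cannot occur in the global minimum-energy
conformation (GMEC). The GMEC is then found exactly: exhaustively for up to
10⁶ combinations, otherwise by mixed-integer linear programming (HiGHS via
scipy) with binary site-rotamer variables and continuous pair variables tied
by flow constraints.

Hydrogen bonds are detected geometrically: donor-heavy to acceptor distance
≤ 3.3 Å (closed interval) and D-H···A angle ≥ 120°, acceptors being oxygens
and nitrogens without attached hydrogens. The criterion is configurable; the
default is chosen from typical donor–acceptor distances (2.5–3.2 Å) in
hydrolase active sites. The binding energy is E(complex) − E(protein) −
E(TS) at the repacked conformation under rigid separation, which for a
pairwise model equals the protein–TS interaction energy.

## Scaffold-library screening

The library filter keeps X-ray structures with resolution strictly below
3.0 Å, 300–800 residues, mutual sequence identity below 95% (via precomputed
identity clusters — computing alignments is out of scope), a catalytic-site
annotation, and an expression flag. Screening runs matching on every
scaffold, selecting candidate sites within 15 Å of the CA centroid of the
scaffold's annotated catalytic residues, and replaces visual TS-in-pocket
inspection by a burial proxy: a match passes when ≥ 60% of TS heavy atoms
have ≥ 8 protein heavy atoms within 6 Å (all thresholds configurable).
Scaffolds are screened independently (optionally in parallel) with a
deterministic merge.

## Synthetic fixtures

The generator builds the study conditions for all desk-scale validation: a
rigid 6-atom tetrahedral-intermediate mimic (sp3 center, oxyanion acceptor,
nucleophile oxygen, truncated leaving group), a Ser-His-Asp triad plus two
backbone oxyanion donors and one backbone Asp stabilizer, and (by default)
six poly-alanine decoy residues scattered 7.5–12.5 Å from the TS without
clashes. The planted site is constructed by running the matching kinematics
*forward* — free torsions drawn from the multistart grid, bounded torsions
at their constraint optima — so the computed backbones become the scaffold
anchors and the ground truth satisfies every constraint exactly. One global
rigid transform de-aligns the fixture from the axes; regeneration from a
seed is bit-identical.

What the fixtures do **not** emulate: real protein connectivity and
Ramachandran statistics, crystallographic noise on anchor positions,
alternate conformations, solvent, or the density of competing polar groups
in a real pocket. Passing the planted-recovery criteria therefore
demonstrates the correctness of the kinematics, pruning, ranking and
repacking machinery under exactly satisfiable geometry — not matching
performance on crystallographic scaffolds, which additionally depends on
motif tolerances curated per system.

## Problem sizes and defaults

Defaults used by the validation suite and the reproduction script, chosen as
a desk-scale workload: 20 planted fixtures (≈ 14 residues each) for recovery
statistics, 100 paired perturbation-recovery trials (±20° torsion noise) for
the closure contract, 100 random ≤4-site × ≤6-rotamer instances for the
DEE/GMEC oracle, 6 fixtures for hydrogen-bond recovery, and 1,000 random
conformations per loop on 3 fixtures for the reach bound. Key tunables:
candidate radius 15 Å, design radius 7 Å, closure tolerance 0.1 Å, torsion
grid 120°, multistart cap 128, dedup RMSD 0.5 Å, reach margin 0.5 Å,
repulsion thresholds 150/30/200/50 PEU, ranking weights 1 and 1.

## Known limitations

* Metal coordination is not modeled; motifs requiring metal sites are out of
  scope.
* The energy function is a calibrated surrogate; its absolute energies (PEU)
  are not transferable, only orderings and signs within this model.
* Bond angles and anchor backbones are rigid during closure; constraint
  distance/angle tolerances are not explored kinematically (see above).
* The shipped example motifs (PNPA and cephalexin triads) use surrogate
  tolerances (±0.3 Å / ±15°) and idealized TS fragment geometry; per-scaffold
  match counts on real libraries are sensitive to these choices.
* Sequence design (choosing new identities for pocket residues) is outside
  the package's scope: matching assigns motif identities, repacking only
  repacks existing/assigned ones.
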