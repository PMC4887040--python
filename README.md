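# enzymatch

Active-site matching and side-chain repacking for computational enzyme
design.

`enzymatch` is for protein designers who want to graft a *complex active-site
model* — a transition-state (TS) model plus a multi-residue catalytic motif
(e.g. a Ser-His-Asp triad with an oxyanion hole) — onto existing protein
scaffolds. It answers three questions:

1. **Matching** — at which scaffold sites can the motif be realized so that
   every catalytic geometric constraint (distances, angles, improper
   dihedrals, each with an optimum ± tolerance) is satisfied, and where does
   the TS end up?
2. **Ranking** — which of the surviving matches is most native-like?
3. **Evaluation** — with the TS fixed at the matched pose, does rotamer-based
   repacking of the surrounding shell reproduce the intended hydrogen-bond
   network and a favourable binding energy?

## Method in brief

A motif role is attached to its partner (the TS or another role) through a
six-degree-of-freedom constraint block between atom triples
(A₃,A₂,A₁)·(B₁,B₂,B₃): one distance d(A₁,B₁), two angles θ(A₂A₁B₁),
θ(A₁B₁B₂), and up to three dihedrals. Matching builds a kinematic *main
loop*,

    anchor₁ (N,CA,C) → side chain₁ → TS → side chain₂ (reversed) → anchor₂,

whose free variables are side-chain χ angles, TS rotatable torsions, and the
constraint dihedrals bounded to optimum ± tolerance; constraint distances act
as pseudo-bonds frozen at their optima. Closure minimizes the terminal
backbone deviation ‖x_computed − x_anchor‖² by damped Gauss–Newton (a
quasi-Newton scheme with Hessian ≈ JᵀJ and analytic torsion jacobians) over a
deterministic multistart; an extended-CCD solver is provided as the baseline.
Remaining roles close *side loops* from already-placed atoms onto their own
anchors. Four pruning stages (maximum loop reach, RMSD deduplication,
immediate constraint checks, linear repulsion thresholds of 150/30/200/50
PEU) keep enumeration tractable, and matches are ranked by normalized
constraint deviation plus repulsion.

Repacking fixes the TS, repacks all residues within 7 Å (prolines excluded)
from a backbone-independent rotamer library with hydroxyl-hydrogen expansion,
solves the global minimum-energy conformation exactly by dead-end
elimination + exhaustive/MILP search, and reports recovered hydrogen bonds
(donor–acceptor ≤ 3.3 Å, D-H···A ≥ 120°) and the binding energy
E(complex) − E(protein) − E(TS).

See `docs/methods.md` for the full model description, assumptions and
limitations.

## Worked example

Generate a synthetic scaffold with a planted catalytic site, then match the
triad motif onto it:

```python
from enzymatch import MatchConfig, match_scaffold, ts_rmsd_vs_reference
from enzymatch.fixtures import generate_fixture

fx = generate_fixture(seed=3)          # toy scaffold + planted Ser-His-Asp site
matches = match_scaffold(
    fx.scaffold, fx.motif, MatchConfig(seed=0),
    reference_residues=fx.catalytic_site_ids,
)
top = matches[0]
print(len(matches), top.assignment_labels())
print(round(top.rank_score, 4),
      round(ts_rmsd_vs_reference(top, fx.truth.ts_pose), 3))
```

Output:

```
1 {'SER1': 'A4', 'HIS2': 'A9', 'ASP3': 'A1', 'ALA4': 'A5', 'ALA5': 'A7', 'ALA6': 'A10'}
0.3075 0.0
```

One match survives all constraints and pruning stages; its role→site
assignment is exactly the planted one, and the matched TS sits on the planted
pose (no-fit RMSD 0.0 Å). The rank score is the match's repulsion/deviation
ranking functional (lower is better).

Repacking the shell around the matched TS:

```python
from enzymatch.repacking import covalent_exclusions, hbond_recovery, repack_active_site

excl = covalent_exclusions(fx.motif, fx.truth.assignment, fx.scaffold)
result = repack_active_site(
    fx.scaffold, fx.motif.ts, fx.truth.ts_pose,
    fixed_sites=[fx.truth.assignment["SER1"]],   # covalently attached nucleophile
    excluded_pairs=excl,
)
pred = [(h.donor_id, h.acceptor_id) for h in result.hydrogen_bonds]
frac, matched, missed = hbond_recovery(pred, fx.truth.hydrogen_bonds)
print(round(frac, 3), round(result.binding_energy, 2))
```

Output:

```
1.0 -1.88
```

All planted hydrogen bonds (two backbone donors to the oxyanion, the backbone
donor to the Asp, His-ND1→Asp and His-NE2→nucleophile-O) are recovered and
the protein–TS interaction is favourable (negative, in package energy units).

## Command line

```bash
enzymatch simulate --seed 7 --n 3 --out fixtures/          # planted fixtures
enzymatch match --scaffold scaffold.pdb --motif pnpa_classic \
    --catalytic A:57,A:102,A:195 --out matches.json --dump-pdb out/
enzymatch screen --library scaffolds/ --motif cephalexin_flexible \
    --out report.json --jobs 4
```

Three example motifs ship with the package (`pnpa_classic`,
`cephalexin_classic`, `cephalexin_flexible`): classic and flexible
catalytic-triad models for ester/amide hydrolysis, written in the package's
YAML motif format (see `src/enzymatch/motifs/`).

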