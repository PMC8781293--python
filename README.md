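# quasidock

Two-step **quasi-docking** of a flexible ligand in a rigid protein:
a library and command-line tool for enumerating the low-energy minima of a
protein–ligand complex with a fast force field and re-ranking them with a
slower quantum-chemical (or surrogate) energy model.

## The problem

Classical docking rests on the *docking paradigm*: the bound ligand pose
coincides with the global minimum (GM) of the complex's energy surface.
Scoring that surface quantum-chemically for every trial pose is out of
reach, so quasi-docking splits the job:

1. **Search (stage 1).** Throw the flexible ligand into the binding-site
   sphere at random — uniform rigid rotations/translations plus uniform
   torsion angles — reject clashing starts, and minimize the complex energy
   with L-BFGS over all ligand Cartesian coordinates. Unique minima
   (heavy-atom RMSD deduplication, no superposition) are collected into a
   fixed-capacity pool (default 8192) until the search *saturates*: further
   sampling reveals no minimum below any stored one.
2. **Re-rank (stage 2).** Recompute every pool minimum's energy as a
   *single point* (no geometry change — the `1SCF` contract) with a
   semiempirical QM method (PM7 or PM6-D3H4X, COSMO implicit water,
   ε = 78.4, via an external MOPAC-dialect program) or with a built-in
   surrogate potential. Rank 1 — the lowest stage-2 energy — is the
   predicted binding mode.

Evaluation against a crystallographic pose uses the heavy-atom RMSD in the
common receptor frame, corrected for ligand graph symmetry, and the
**INN** (Index Near Native): the rank of the lowest-energy minimum with
RMSD < 2 Å to the native pose. INN = 1 means the paradigm holds. The
binding enthalpy is estimated from GM energies alone:

```
ΔH_bind = E₁(PL) − E₁(P) − E₁(L)
```

with E₁(PL) the solvent single point at the vacuum-relaxed complex GM,
E₁(P) the receptor in its fixed docking conformation, and E₁(L) the best
unbound-ligand conformer.

## Worked example

The package ships a toy-complex generator whose stage-1 landscape has a
known number of basins (verified by an independent grid-enumeration
oracle), so every stage can be checked end to end:

```bash
quasidock fixtures --pockets 2 --seed 3 --out toy
quasidock search  --receptor toy/receptor.pdb --ligand toy/ligand.sdf \
                  --site-center 0,0,0 --site-radius 6 \
                  --model toy --toy-spec toy/toyspec.yaml \
                  --n-starts 60 --seed 7 --out toy/run
quasidock rescore  --pool toy/run/pool.sdf --ligand toy/ligand.sdf \
                   --receptor toy/receptor.pdb --method surrogate \
                   --surrogate-preset reranking --out toy/run
quasidock evaluate --pool toy/run/pool_ranked.sdf --ligand toy/ligand.sdf \
                   --native toy/native.sdf --out toy/run
```

which prints

```
fixtures: 2-pocket toy complex with 2 enumerated minima -> toy
search: 2 unique minima from 60 starts -> toy/run/pool.sdf
rescore: 2 ranked -> toy/run/pool_ranked.sdf
paradigm failed: INN=2, GM RMSD=9.60 A (cutoff 2.0 A)
```

Both basins are found (60 starts dedupe to 2 unique minima, matching the
oracle to < 1e-9 kcal/mol). The `reranking` surrogate deliberately prefers
the second pocket, so the re-ranked GM is *not* the stage-1 native basin:
INN = 2, GM RMSD 9.6 Å — the evaluation correctly reports a paradigm
failure. Rescoring with the stage-1-agreeing surrogate (`default` preset)
gives `paradigm fulfilled: INN=1` instead. This is exactly the distinction
the second stage exists to expose.

The packaged evaluation tables (25 complexes, two stage-2 methods) are
summarized with:

```bash
quasidock evaluate --reference-tables --out tables
# pm6d3h4x_cosmo: 11 paradigm failures / 25
# pm7_cosmo: 6 paradigm failures / 25
# pm6d3h4x_cosmo: R = 0.40 over 10 pairs
# pm7_cosmo: R = 0.74 over 12 pairs
```

## Library layout

| module | contents |
|---|---|
| `quasidock.core` | domain types (`LigandTopology`, `Pose`, `MinimumRecord`), the `EnergyModel` contract, finite-difference gradient fallback |
| `quasidock.sampling` | start-pose generator: uniform SO(3)/ball placement, torsion randomization, vdW clash screening |
| `quasidock.optimize` | L-BFGS local minimization over ligand Cartesians |
| `quasidock.pool` | fixed-capacity unique-minima pool + saturation diagnostics |
| `quasidock.rescoring` | stage-2 re-ranking, MOPAC-dialect I/O, surrogate model |
| `quasidock.analysis` | RMSD (plain/symmetry-corrected), INN, paradigm verdicts, enthalpy protocol, correlations, table summaries |
| `quasidock.models` | MMFF94 energy model via RDKit behind the contract |
| `quasidock.fixtures` | toy complexes with enumerable minima, oracles, packaged tables |
| `quasidock.runtime` / `quasidock.cli` | run orchestration and the `quasidock` command |

See `docs/methods.md` for the model details, numerical choices and
limitations.
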