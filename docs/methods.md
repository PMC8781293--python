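# Methods

## Model and procedure

quasidock implements two-step quantum-assisted docking for a flexible
ligand in a rigid receptor. The assumptions are explicit:

* **Rigid receptor.** Protein coordinates never change; its internal
  energy is an additive constant to every pose, so models that score only
  receptor–ligand interactions (the surrogate) and models that report
  total energies (force fields, QM heats of formation) rank poses
  identically. `EnergyModel.receptor_energy` exposes the constant where
  the enthalpy protocol needs it.
* **Docking paradigm.** The bound pose is taken to be the global minimum
  of the complex energy. Stage 1 is therefore responsible for *complete*
  enumeration of candidate minima (saturation), stage 2 only for ranking
  them; stage 2 never moves atoms (single-point `1SCF` contract).
* **Enthalpy from minima.** ΔH_bind = E₁(PL) − E₁(P) − E₁(L) neglects
  higher minima and vibrational contributions; each E₁ is a global-minimum
  energy of its species under the stage-2 method + solvent.

## Stage 1: multi-start search

Start poses compose three independent draws: torsion angles uniform on
[0°, 360°) per rotatable bond (applied to the smaller side of the split
bond graph; ties broken toward the side containing the lower atom index),
a rotation uniform over SO(3) (normalized Gaussian quaternion), and a
ligand-center position uniform over the site ball (direction × r^(1/3)
radius). A start is rejected when any receptor–ligand pair, or any
ligand–ligand pair at ≥ 1-4 bond separation, is closer than
`clash_scale` × (sum of Bondi vdW radii). Parameters:

| parameter | default | units | why |
|---|---|---|---|
| `site_radius` | 8 | Å | sphere covering the active site; the only placement restriction |
| `clash_scale` | 0.5 | — | permissive: soft overlaps are left to the optimizer |
| `grad_tol` | 1e-5 | kcal/mol/Å | see "numerical choices" |
| `max_iter` | 2000 | — | L-BFGS cap; rarely reached on smooth fields |
| pool `capacity` | 8192 | — | hard targets may need several× more; plain config value |
| `uniqueness_rmsd` | 0.5 | Å | separates basins without splitting optimizer jitter; well below the 2 Å success cutoff |

Local minimization is scipy L-BFGS-B over all 3·N ligand Cartesians with
the model's analytic gradient, or a central-difference fallback (h = 1e-4 Å)
when a backend provides none. The returned energy is never above the start
energy; non-converged results remain pool-eligible but carry a flag.

The pool keeps records strictly sorted by stage-1 energy. A candidate
within `uniqueness_rmsd` (heavy-atom RMSD, identity mapping, no
superposition) of a stored record is a duplicate; the lower-energy
representative of the basin is kept. When full, a candidate below the pool
maximum evicts the highest record. Saturation over a window of w
candidates means no insertion improved on the then-current pool maximum in
that window.

**Reproducibility contract.** Start *i* draws from a generator seeded
`(master_seed, i)`. The pose stream is therefore a pure function of config
+ seed, independent of how many worker processes execute the starts, and
reruns produce byte-identical pool artifacts.

## Stage 2: re-ranking

Every pool record receives one single-point energy from the stage-2
backend; ranks are 1..N ascending, ties broken by stage-1 energy then
insertion order. Failed jobs are flagged and excluded; more than 10%
failures aborts the run. Backends:

* **External semiempirical program** (optional runtime dependency): the
  writer emits a MOPAC-dialect deck — method token (`PM7` or
  `PM6-D3H4X`), `1SCF`, `MOZYME`, `CHARGE=n`, and `EPS=78.4` for COSMO
  water — with receptor atoms first, ligand atoms last. The parser
  returns the *last* `FINAL HEAT OF FORMATION` (kcal/mol) in the output
  and raises on truncation or failure markers. The exact keyword set
  beyond these tokens is a pinned assumption of this package, not a fact
  about the original computations. COSMO2 is deliberately not offered.
* **Surrogate** (always available): soft Lennard-Jones plus screened
  Coulomb over receptor–ligand pairs, depth from per-element tables
  (geometric-mean combination), soft core δ so contact energies stay
  finite. It shares nothing with the stage-1 field, so re-ranking under it
  genuinely permutes stage-1 order — the property the pipeline tests need.

## Evaluation

RMSD is over heavy atoms in the common receptor frame; no superposition.
Symmetry correction minimizes RMSD over all element- and
bond-order-preserving automorphisms of the heavy-atom graph (networkx
VF2; enumeration capped at 10,000 with an explicit-mapping escape hatch).
INN is the smallest rank with RMSD strictly below 2 Å (a boundary value
counts as failure); symmetric homodimer binding sites are handled by an
optional second native reference, taking the smaller RMSD per minimum.
Correlation between measured and calculated enthalpies is sample Pearson,
dropping incomplete pairs; the packaged evaluation tables carry exclusion
lists (no measured value; positive measured enthalpy, i.e. entropy-driven
binding; distorted pyranose rings) as metadata rather than code.

The enthalpy protocol: E₁(PL) relaxes ligand atoms in the rigid receptor
under the *vacuum* stage-2 model from the docked GM, then takes one
solvent single point; E₁(P) is the receptor's solvent single point in its
fixed docking conformation; E₁(L) relaxes each unbound-ligand conformer
under vacuum, single-points with solvent, and takes the minimum.

## Synthetic fixtures and what they do (not) show

The toy receptor is K disjoint "pockets", each a rigidly rotated copy of
the ligand's equilibrium geometry; anchor *i* of a pocket attracts ligand
atom *i* (index-paired, not element-paired) through a Lorentzian well
−depth/(1 + r²/σ²) with σ = 1.2 Å. Pocket depths decrease strictly
(6.0, 5.6, 5.2, … kcal/mol), so the landscape has exactly K basins with
known ordering and long-range tails that leave no flat spots inside the
site sphere. Intramolecular terms are harmonic bonds (300 kcal/mol/Ų) and
1-3 distances (150), plus a Fourier torsion potential; the bundled
double-well chain uses V(φ) = 0.6 cos φ + cos 3φ — an anti well at exactly
−1.6 kcal/mol and a degenerate gauche pair. Anchors carry a different
element per pocket so the surrogate can be parameterized to invert the
stage-1 ordering (the `reranking` preset weights oxygen contacts above
nitrogen, making pocket 1 the surrogate GM of the standard two-pocket
complex).

The **minima oracle** never touches the production search: rigid template
copies are scored on a translation grid (1.5 Å step) × the 24 chiral
octahedral orientations, the best spatially-thinned candidates are refined
in full Cartesians with nonlinear conjugate gradients, and refined points
are deduplicated by RMSD. Construction fails loudly if the enumerated
basin count differs from K. The torsional landscape has its own oracle: a
1° dihedral scan with bounded scalar polish.

What passing these tests shows: the sampler covers the site, the optimizer
descends to genuine minima, the pool deduplicates and truncates exactly,
re-ranking and INN interact as designed, and the whole chain is
deterministic under a seed. What they do **not** show: behaviour on real
force fields with thousands of receptor atoms, rugged landscapes with
10³–10⁴ basins, QM rescoring noise, receptor flexibility, or protonation
effects — all properties of real systems the smooth toy field does not
emulate.

## Numerical choices

* **Optimizer tolerance.** The projected-gradient infinity norm must fall
  below `grad_tol`. The default is 1e-5 kcal/mol/Å, deliberately tighter
  than typical minimization practice: on toy landscapes a looser 1e-3
  allowed L-BFGS to stop inside near-flat saddle regions (a terminal atom
  swinging freely about a bond axis produces an intra-energy-invariant
  circle whose far side is a saddle with gradient < 1e-3), and such
  pseudo-minima contaminated the pool. At 1e-5 the optimizer walks off
  these saddles; the cost is a moderate iteration increase.
* **Duplicate resolution** keeps the lower-energy representative; the
  nearest stored record (not the first below threshold) is the merge
  target.
* **Tie-breaks.** Rank ties (possible at truncated printed precision)
  break by stage-1 energy then insertion order; torsion moving-side ties
  break by lower minimum atom index.
* **Degenerate inputs.** Zero-atom ligands, disconnected bond graphs,
  ring or non-single central torsion bonds, non-finite coordinates and
  unknown elements are rejected at construction with named errors;
  non-finite energies during line search abort that start only.
* **Dihedral sign convention.** Rotating the d-side of torsion a-b-c-d by
  +δ about the b→c axis decreases the dihedral; the torsion setter
  accounts for which side moves.

## Problem sizes

Oracle-equivalence checks run 50·K random starts per repeat, 20 seeded
repeats for K ∈ {2, 5, 10} (≈ 6 min on one CPU); the pool oracle streams
10,000 candidates in 10 arrival orders; the symmetry-RMSD oracle compares
100 random pose pairs against an O(n!) permutation enumeration on a
six-ring. These sizes were chosen to make each property's failure modes
visible (missed basins, order dependence, wrong automorphism set) while
staying desk-scale.

## Known limitations

* The MMFF94 backend types systems through RDKit; receptors with
  nonstandard residues or missing hydrogens fail typing (with a clear
  error) and need out-of-band preparation. Full-complex MMFF94 runs are
  supported by the contract but untested beyond small systems.
* The external QM path is exercised against a synthetic output fixture;
  dialect drift in future program versions would surface as parse errors,
  not silent misreads (the parser anchors on the heat-of-formation line).
* Total formal charge round-trips through SDF on the first atom; per-atom
  charges are not tracked.
* The pool's RMSD deduplication is identity-mapped by design; symmetric
  ligands may occupy two pool slots per physical basin, which matches the
  search program's behaviour this package models and is corrected at
  analysis time.
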