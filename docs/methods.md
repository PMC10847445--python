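# Methods

## Scope and model

`plscore` implements an end-point scoring workflow for ranking ligands of
a protein target. "End-point" means a single representative structure of
the bound state (and one locally relaxed structure of the free ligand) is
used — no configurational sampling — so some contributions are neglected
and error cancellation is relied upon. Consequently the score is a
ranking quantity within one target series, never an absolute binding free
energy.

The score is the sum of five terms (kcal/mol):

| term | meaning | computed from |
|---|---|---|
| ΔE_int | gas-phase interaction energy | E(PL) − E(P) − E(L), fixed complex geometry |
| ΔΔG_solv | desolvation penalty | G_solv(PL) − G_solv(P) − G_solv(L) |
| ΔG_conf(L) | ligand strain | G(bound pose) − G(relaxed pose), gas + solvation |
| ΔG_H+ | proton-transfer correction | Henderson–Hasselbalch-weighted reaction free energy |
| −TΔS | entropy penalty | 1 kcal/mol × rotatable bonds (default) |

The stored `total` is the exact floating-point sum of the five stored
components, so ablation of any term moves the total by exactly that
component.

## Active-site model

The receptor is truncated to all residues having at least one atom
within a cutoff (default 10 Å; trimmed variants 6 Å, or 5 Å for very
large ligands) of the union of all overlaid ligand poses of the series.
Whole residues are the selection unit. Each cut peptide bond is
terminated by a neutral cap restoring valence: -NH-CH₃ (NME) on the
C-terminal side of a kept segment, -CH=O (FOR) on the N-terminal side.
Cap heavy atoms reuse the backbone coordinates of the removed neighbor
(N/CA for the methylamide, C/O for the formyl), which perturbs the
geometry the least; hydrogens are added at 1.09 Å (C–H) / 1.01 Å (N–H)
with planar/tetrahedral geometry. The cap-placement rule is this
package's stated convention, and atom counts include cap hydrogens.

Charged residues exposed at the truncation boundary are kept, not
neutralized (they are screened by the solvent model); a report lists
charged residues farther than a configurable distance (default 8 Å)
from the ligands. Cysteines disulfide-bonded (S–S < 2.5 Å) to a
selected cysteine are pulled into the selection to avoid cutting the
bridge. Structural waters, metal ions and cofactors are retained only by
explicit whitelist — deciding which waters define a binding mode is
judgment the package does not automate. Metal-ion formal charges come
from a fixed table (Zn/Ca/Mg +2, Na/K +1, Cl −1), overridable.

The pocket net charge is the integer sum of residue charges (table
lookup: Asp/Glu −1, Lys/Arg +1, protonated His +1) plus ion and cofactor
charges; caps are neutral. An unknown residue name with no table entry
and no per-atom formal charges is an error, never a silent zero.

## Energy backends

A backend maps (atoms, coordinates, net charge, solvated flag) to a
gas-phase energy and a solvation free energy, deterministically.

**External engine.** `render_engine_input` emits a MOPAC-style deck:
method keyword, `1SCF` for single points, `CHARGE=n`, `MOZYME` above a
configurable atom-count threshold (default 300, since localized-orbital
SCF is what makes thousand-atom pockets tractable), and `EPS=ε`
(default 78.4) for solvated runs. `parse_engine_output` extracts the
final heat of formation, an optional solvation-energy line, and the
convergence state; a (gas, solvated) single-point pair yields g_solv by
difference. Rendering is bit-stable.

**Classical test backend.** A self-contained surrogate so the entire
pipeline is runnable and testable without any engine — it is *not* a
physical substitute for a quantum-chemical treatment:

- gas phase: 12-6 Lennard-Jones (Lorentz–Berthelot combination, per-element
  σ/ε table) + Coulomb point charges (332.0636 kcal·Å/mol/e²), optionally
  + the dispersion term below;
- solvation: a Born-like polar term −166.0318·(1−1/ε)·q²/b with an
  effective radius b = a·(1 + 0.2·n) that grows with the local atom
  density n (Gaussian counter, width 3.5 Å), so burying a charge raises
  its solvation energy and complex formation yields a positive polar
  desolvation penalty; plus a surface term −γ·A·exp(−n/n₀)
  (γ = 0.010 kcal/mol/Å², n₀ = 6) giving a small positive penalty for
  burying neutral surface;
- analytic gradients for all terms, verified against central finite
  differences.

All terms are pairwise or local-density functions, hence
size-consistent: two fragments 100 Å apart have exactly additive
energies and |ΔE_int| < 1e-6 kcal/mol.

**Dispersion.** Pairwise −s6·C6/(r⁶+f₀⁶) − s8·C8/(r⁸+f₀⁸) with
Becke–Johnson damping f₀ = a1·√(C8/C6) + a2, finite at contact.
Defaults s6 = 1 (fixed), s8 = 0.9220, a1 = 0.3419, a2 = 5.2955 bohr.
Internally atomic units (1 Ha = 627.509 kcal/mol, 1 Å = 1.8897259886
bohr). The coefficient table is static per element pair: the built-in
set (H, C, N, O, F, S, Cl, Br, I, Zn) uses free-atom-like C6 values with
geometric-mean pair combination and C8 = 3·C6·√(Q_A·Q_B); the
coordination-number interpolation of the full D3 scheme is deliberately
omitted, and user tables load from TSV.

**Relaxation.** `relax` is a line-searched quasi-Newton (L-BFGS-B)
minimization over unfrozen atoms; convergence when the largest per-atom
gradient norm ≤ tol (default 0.1 kcal/mol/Å, max 2000 steps), frozen
atoms returned bit-identical, energy non-increasing across accepted
steps. Ligand strain relaxes the free ligand in solvent from the bound
pose; with a deterministic optimizer the strain is non-negative up to
the gradient tolerance.

## Proton-transfer term

Applied only when the ligand's protonation changes upon binding; the
bound-form protonation variant is used in ΔE_int, ΔΔG_solv and
ΔG_conf(L), and ΔG_H+ pays for converting the solution-dominant species:

- uptake (ligand protonated on binding): ΔG_H+ = f · ΔG(L + H₂O → LH⁺ + OH⁻)
- release (ligand deprotonated on binding): ΔG_H+ = (1−f) · ΔG(LH + H₂O → L⁻ + H₃O⁺)

with f = 10^(pH−pKa)/(1+10^(pH−pKa)) the deprotonated solution fraction.
The release weighting is read as (1−f)·ΔG_rxn — the printed form of the
source expression is ambiguous about precedence, and symmetry with the
uptake case (both weight by the fraction of the species that must
convert) fixes the interpretation; this is a documented choice. Ligand
species free energies are backend values at relaxed free-ligand
geometries (which geometry to use is unstated in the source; relaxed is
this package's documented choice). The H₂O/OH⁻/H₃O⁺ free energies
combine a computed gas-phase enthalpy with an *experimental* solvation
free energy and must be supplied in configuration — no defaults are
invented; fixtures declare clearly non-physical placeholder values.
There is no default assay pH: a protonation change without a pH is an
error.

## Rotatable bonds and entropy

No single community definition of "rotatable bond" exists, so the
package documents its own: an acyclic single (non-aromatic) bond between
two heavy atoms, each having at least one further heavy neighbor, with
amide C–N bonds excluded (a carbonyl is recognized by bond order 2 or a
C–O distance ≤ 1.28 Å); the amide exclusion is configurable. Ring
membership is graph-based (an edge is in a ring iff it is not a bridge).
The default entropy model charges 1.0 kcal/mol per rotatable bond;
descriptor-based estimators can be plugged in by callable.

## Conformer and receptor selection

When a crystal structure provides several ligand conformers, every one
is scored as a complex (gas + solvation total) and the lowest-energy one
is kept; ties keep the first in input order. Whether selection should
use the full score or the complex energy is open in the source; the
complex total energy is used here, documented. Candidate receptor
structures are ranked by their closest atom–atom approach to the union
of overlaid ligands — the largest minimum distance wins (it best
accommodates all poses); approaches below 1 Å are flagged as clashes.

## Benchmark evaluation

ΔG = R·T·ln(Ki_eff/1 M), R = 1.98720e-3 kcal/mol/K, default
T = 298.15 K (the temperature only rescales ΔG globally and cannot
change R²). Kd and Ki are treated as equivalent (competitive
inhibition); IC50 approximates Ki as IC50/2 under
substrate-concentration ≈ Michaelis-constant conditions — a linear map,
so correlations are unchanged. Series enter the benchmark only with
pKi range > 1.5 and ≥ 10 ligands; exclusions are reported with reasons.
Per-target R² is the squared sample Pearson correlation (n ≥ 3 and
nonzero variance required); the aggregate is the unweighted mean over
targets, with population SD (the source's ± convention is unstated;
population SD is this package's documented choice) and the minimum.

## Synthetic data

The generators are pure functions of (seed, config) using numpy's PCG64;
identical outputs across runs and platforms at the serialization level.

- **Toy pocket**: a helical polypeptide (60°/residue, radius 5.5 Å,
  rise 1.5 Å — widened so an axial ligand channel stays clash-free)
  with planted Asp/Lys charges, 1–10 single-atom waters, and an off-axis
  Zn²⁺; the planted pocket charge is exactly the composition sum.
- **Toy ligands**: heavy-atom chains with explicit bond topology; a
  chain of L atoms has exactly L−3 rotatable bonds, formal charges −1..+2
  are planted on terminal N/O atoms, and atoms sit near the
  Lennard-Jones minimum spacing because the classical backend has no
  bonded terms.
- **Toy series**: poses are scored with the classical backend and the
  "true" affinity is generated by a known linear law
  ΔG = 0.03·score − 9 + N(0, noise_sd), back-converted to Ki (every
  third ligand reported as IC50 at 2·Ki); ~1 in 5 records is flagged
  modeled, every fourth carries a protonation change. The dataset
  envelope mirrors the reference benchmark (charges −1..+2, rotatable
  bonds 0..25, ≥10 ligands, pKi range > 1.5).
- **Statistical benchmark**: ten targets × 500 ligands with scores
  N(−35, 1.5²) and noise chosen for a planted population ρ² = 0.69; the
  per-target analytic expectation uses the realized signal variance,
  var(signal)/(var(signal)+σ_n²).

What passing tests show — and do not show. The synthetic systems
exercise every contract of the pipeline (selection, capping, charge
bookkeeping, term assembly, conformer choice, correlation recovery) but
none of the physics of real protein–ligand complexes: no real
electrostatics or dispersion balance, no explicit hydrogens on the toy
systems, no experimental noise structure. Correlations recovered on
synthetic data validate the *machinery*, not predictive accuracy on real
targets, which depends entirely on the quality of the external energy
backend and input geometries.

Statistical note: the sampling SD of R² at ρ² = 0.69, n = 500 is
≈ 0.023 (delta method), so per-target recovery is checked within three
standard errors while the across-target mean (SD ≈ 0.007 over ten
targets) is held to ±0.02.

## Problem sizes and numerical choices

Tests and the acceptance script run on toy pockets of ~12 residues
(~10² atoms), ligand series of 10–16, pairwise-oracle clusters of ≤10³
atoms, and the ten-target × 500-ligand statistical benchmark — sizes
chosen so the whole suite completes in seconds while every code path is
exercised at realistic shapes. Other defaults: bond-perception tolerance
1.3 × covalent-radius sum with hydrogens bonded only to their nearest
heavy atom; PDB altloc policy "A" (exceptions are configuration);
element inference from PDB columns 77–78 with fallback to atom-name
letters, failure being an error; superposition requires ≥3 non-collinear
pairs and returns a proper rotation; batch scoring caches backend calls
keyed by (elements, rounded coordinates, charge, flag) for resumability.

## Known limitations

- No quantum-chemical backend is bundled; the classical surrogate's
  absolute energetics are meaningless outside of contract testing.
- No protonation-state assignment, pKa prediction, missing-atom
  reconstruction, docking/pose generation, or crystallographic symmetry
  handling; inputs are assumed prepared.
- The dispersion table omits coordination-number dependence and ships a
  minimal element set.
- Counterpoise-like corrections to ΔE_int are not applied (plain
  supermolecular difference).
- Water/cofactor retention is manual whitelisting by design.
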