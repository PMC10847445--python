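# plscore

End-point protein–ligand binding-affinity scoring for structure-based
drug design: build a truncated, capped active-site model around a series
of overlaid ligand poses, decompose the binding free energy into five
physically defined terms, and benchmark the resulting ranking against
experimental affinities.

## The score

For one protein–ligand complex the score (kcal/mol; more negative =
better predicted binding) is

```
score = ΔE_int + ΔΔG_solv + ΔG_conf(L) + ΔG_H+ − TΔS
```

- **ΔE_int** — gas-phase interaction energy, `E(PL) − E(P) − E(L)` at the
  fixed complex geometry.
- **ΔΔG_solv** — desolvation penalty, `G_solv(PL) − G_solv(P) − G_solv(L)`.
- **ΔG_conf(L)** — ligand strain: energy of the bound conformation minus
  the locally relaxed solution conformation.
- **ΔG_H+** — proton-transfer correction, applied only when the ligand's
  protonation changes upon binding. The reaction free energy
  (`L + H₂O → LH⁺ + OH⁻` for uptake, `LH + H₂O → L⁻ + H₃O⁺` for release)
  is weighted by the Henderson–Hasselbalch solution fraction
  `f = 10^(pH−pKa) / (1 + 10^(pH−pKa))` of the species that must convert
  (`f` for uptake, `1 − f` for release).
- **−TΔS** — ligand conformational-entropy penalty, by default
  1 kcal/mol per rotatable bond (a descriptor-based plugin hook is
  provided).

Energies come from a pluggable backend. The intended production backend
is an external semiempirical engine driven through a MOPAC-style text
interface (`render_engine_input` / `parse_engine_output`, with a MOZYME
keyword above a configurable atom count and an `EPS` solvent keyword); a
self-contained classical backend (Lennard-Jones + Coulomb + Born-like
solvation, analytic gradients) ships so the whole pipeline runs and is
tested with no external software. A pairwise dispersion correction with
Becke–Johnson damping is included, with damping parameters
s8 = 0.9220, a1 = 0.3419, a2 = 5.2955 (s6 = 1).

The score ranks ligands of one target; it is not an absolute binding
free energy. Ranking quality is measured per target by the squared
Pearson correlation R² between score totals and experimental
ΔG = R·T·ln(Ki/1 M) (Kd and Ki treated as equivalent; IC50/2 used as a
Ki surrogate), and summarized across targets by the unweighted mean ± SD
and minimum.

## Worked example

Score a deterministic synthetic ligand series in a toy helical pocket
(ionizable residues, two structural waters, a Zn²⁺ cation) and evaluate
the correlation against affinities generated with a known linear law:

```python
from plscore.fixtures import FixtureConfig, make_toy_series
from plscore.energy import CachingBackend, make_test_backend
from plscore.scorer import score_series
from plscore.bench import evaluate

backend = CachingBackend(make_test_backend())
cfg = FixtureConfig(seed=1, n_ligands=10, rotbond_range=(0, 6), noise_sd=1.0)
records, series, truth = make_toy_series(cfg, backend=backend)
table = score_series(backend, records)
print(table[["id", "dE_int", "ddG_solv", "dG_conf", "dG_Hplus", "TdS", "total"]]
      .round(2).to_string(index=False))
print(evaluate(table, [series]).to_markdown())
```

prints

```
    id  dE_int  ddG_solv  dG_conf  dG_Hplus  TdS  total
LIG000   -2.51     13.40     0.00      0.00  5.0  15.89
LIG001   -1.23      1.39     0.00      5.52  0.0   5.67
LIG002  130.08     61.12    56.91      0.00  2.0 250.11
LIG003  -49.33     15.35     4.98      0.00  3.0 -26.01
LIG004   77.22     28.22     4.76      0.00  2.0 112.19
LIG005  107.23     12.71     4.95     10.24  5.0 140.13
LIG006  -38.46      7.81     4.92      0.00  6.0 -19.73
LIG007  -38.58      8.56     5.12      0.00  6.0 -18.90
LIG008   -2.50      7.82     0.00      0.00  3.0   8.32
LIG009   67.87     25.42     4.77      0.19  1.0  99.25

Average R² = 0.81 ± 0.00; minimum 0.81 (TOY01). 10 complexes over 1 targets (8 crystal, 2 modeled).
```

Each row decomposes one complex: e.g. LIG003 binds favorably
(ΔE_int = −49.3) at a desolvation cost of +15.4 and a strain of +5.0,
paying 3 kcal/mol of entropy for its three rotatable bonds. Ligands
carrying +1/+2 formal charges clash electrostatically with this
positively charged toy pocket (large positive totals) — exactly the
spread the correlation is computed over. The R² of 0.81 reflects the
1 kcal/mol noise planted on the generated affinities.

The same flow is available from the shell:

```
plscore fixtures --seed 3 --out fx/
plscore score --manifest fx/manifest.yaml --out scores.csv
plscore evaluate --manifest fx/manifest.yaml --scores scores.csv --out report/
```

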