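# anisofit

Equilibrium binding analysis for tetrameric DNA-binding transcriptional
sensors of the RcnR/CsoR (DUF156) family — the repressors whose operator
binding is allosterically weakened by an effector (a metal ion, or
formaldehyde for FrmR-type sensors), derepressing the downstream genes.

The package covers the quantitative workflow around fluorescence
anisotropy titrations of an operator probe:

1. **Equilibrium speciation** (`anisofit.speciation`) — declare a binding
   scheme as components (with total concentrations) and complexes (with
   overall dissociation constants) and solve the coupled mass balances
   for all free and bound species.
2. **Titration simulation and K_DNA fitting** (`anisofit.titration`) —
   the standard mechanism for these sensors is *two non-dissociable
   tetramers binding one operator with equal stepwise affinity*:

   T + D ⇌ TD (K₁ = K_DNA),  T + TD ⇌ T₂D (K₂ = K_DNA),

   with the anisotropy change linear in bound tetramers,
   Δr = Δr_max·(½[TD] + [T₂D])/D_tot.  `AnisotropyTitrationModel.fit()`
   estimates K_DNA (and optionally Δr_max) by least squares with
   log-spaced multistarts, and flags non-saturating titrations as lower
   bounds ("K ≥ value") instead of pretending to a point estimate.
   Stoichiometric titrations (probe ≫ K) yield the binding stoichiometry
   from the rising-phase/plateau breakpoint (8 monomer equivalents per
   DNA for two tetramers).
3. **Allosteric coupling free energy** (`anisofit.coupling`) —
   ΔG_C = RT·ln(K_effector/K_apo), averaged over all pairwise
   permutations of replicate apo and effector-bound K values; positive
   ΔG_C means the effector weakens DNA binding.
4. **Cytosolic competition model** (`anisofit.cellmodel`) — partitioning
   of formaldehyde between a trace sensor (tens of nM) and the bulk
   glutathione pool (mM), treating adduct formation as a reversible
   equilibrium.  Answers: how modified is the sensor at the formaldehyde
   level where the GSH pool just begins to form
   S-(hydroxymethyl)glutathione?
5. **Synthetic data** (`anisofit.synthetic`) — seeded replicate
   titrations with additive Gaussian noise, for closed-loop validation
   of the fitter.

## Worked example

```python
from anisofit import (AnisotropyTitrationModel, NoiseSpec, gen_titration,
                      coupling_energy, CytosolCompetitionModel, FRMR_PARAMS)

# three replicate titrations of a 10 nM probe, true K = 9.9e-8 M,
# 5% Gaussian noise, fixed seed
reps = gen_titration(true_k=9.9e-8, probe_total=1e-8,
                     noise=NoiseSpec(sd=0.005, seed=3, n_replicates=3))
print(AnisotropyTitrationModel(reps).fit().summary())
```

```
Anisotropy titration fit
------------------------
K_DNA:           9.637e-08 M (SD 1.48e-08)
delta_r_max:     0.0989
SSE:             1.6064e-03
saturation at last point: 88.7%
converged:       True
lower bound:     False
n replicates:    3
per-replicate K (M): 1.122e-07, 8.280e-08, 9.410e-08
```

The mean fitted K (9.6 ± 1.5 × 10⁻⁸ M) recovers the generating value
within the replicate scatter, and the titration saturates (88.7% at the
final point), so the estimate is a genuine point value, not a bound.

```python
# coupling energy from a Ni(II)-loaded vs apo sensor (K in M);
# the effector K is itself a detection-limited bound, so the energy is too
print(coupling_energy([1.5e-7], [5.9e-6], effector_is_lower_bound=True).summary())
```

```
Allosteric coupling free energy
-------------------------------
dG_C:        >= +2.18 +/- 0.00 kcal/mol
n pairs:     1
temperature: 298.15 K
per-pair dG_C (kcal/mol): +2.175
```

```python
print(CytosolCompetitionModel(FRMR_PARAMS).summary())
```

```
Cytosolic competition model (FrmR)
---------------------------------------
k_sensor:         1.00e-05 M
k_gsh (S-HMG):    1.77e-03 M
GSH total:        1.20e-03 M
sensor tetramer:  1.61e-08 M (9.7 copies/cell at 1e-15 L)
sensor sites:     6.44e-08 M (4/tetramer)
at f_gsh = 4%: total F = 1.218e-04 M, sensor modified = 88.1%
```

Despite GSH being five orders of magnitude more abundant, the sensor's
~200-fold tighter effective formaldehyde affinity means it is 88%
modified at the point where only 4% of the GSH pool carries
formaldehyde — the sensor fires as its downstream enzyme's substrate
begins to accumulate.

The same operations are available from the shell:

```bash
anisofit generate --true-k-m 9.9e-8 --seed 3 --out-dir data/
anisofit fit data/titration_rep*.csv --out fit.yaml
anisofit couple --apo 1.5e-7 --effector 5.9e-6 --effector-lower-bound
anisofit cellmodel --sensor frmr --out curve.csv
```

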