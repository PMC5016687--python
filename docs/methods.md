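# Methods

## Equilibrium speciation

A binding scheme is a set of components with analytic (total)
concentrations and complexes with overall dissociation constants, so
that `[complex] = Π_i [free_i]^ν_i / K`.  The solver finds the free
concentrations closing every mass balance

    total_i = free_i + Σ_c ν_ic [c].

Unknowns are the logarithms of the free concentrations (positivity by
construction), initialised at `free = total`, solved with a hybrid
Powell root find on residuals scaled by `max(total, ε)` with
ε = 10⁻³⁰ M (so relative residuals stay defined at zero totals).  If
the root find stalls, a damped successive-substitution pass
(`free_i ← total_i·free_i/(free_i + bound_i)`, geometric damping)
re-centres the iterate and the root find is retried.  Components with
zero totals, and any complex containing one, are eliminated before
solving.  Default tolerance: worst relative mass-balance violation
≤ 10⁻⁹; failure raises an error naming the worst component rather than
returning an unconverged state.

### The two-tetramer scheme

These sensors are homotetramers that are fully assembled at every
concentration used experimentally.  We therefore treat the tetramer as
an elementary component — monomer totals are divided by four — rather
than modelling a 4M ⇌ T assembly step.  An overall single-step assembly
constant would carry units of M³, and a numerically literal "very small
dissociation constant" of 10⁻²⁰ in those units would, counter to
intent, leave a non-negligible free-monomer pool at sub-micromolar
protein (the fourth root is unforgiving).  The optional
`explicit_assembly=True` mode keeps the monomer as the component and
adds the assembly complex with an overall constant of 10⁻⁶⁰ M³
(equivalent to compounding stepwise constants of the 10⁻²⁰ scale), which
makes assembly quantitative; tests assert it reproduces the reduced
scheme to 10⁻⁶ relative.  The reduced form is the default and the one
used everywhere else in the package.

"Equal affinity" means equal stepwise macroscopic constants
K₁ = K₂ = K_DNA with no statistical-factor corrections, so the doubly
bound complex has overall constant K_DNA².

For speed, titration curves use a scalar reduction of the same mass
balances: the probe balance is eliminated in closed form,
`d = D_tot/(1 + t/K + (t/K)²)`, leaving one monotone equation in the
free tetramer t solved by Brent bracketing on [0, T_tot].  Equivalence
with the general solver is property-tested.

## Anisotropy response model

The anisotropy change is taken linear in the number of bound tetramers:
the singly bound complex contributes weight 0.5 and the doubly bound
1.0 of the saturating response Δr_max (the molar-response convention of
standard mechanism-fitting software).  Original per-species responses
for this mechanism are not documented, so the weights are configurable;
with the defaults, Δr/Δr_max equals the fractional occupancy of binding
sites, and half-site occupancy gives exactly half the saturating
response.

Δr_max defaults to 0.1 anisotropy units in simulations — a typical
magnitude for a ~30-bp labelled probe bound by two ~45 kDa tetramers.

## Fitting K_DNA

The fit minimises Σ(Δr_obs − Δr_model)² on untransformed residuals
(constant noise assumed, matching the generator).  Because the model is
linear in Δr_max, the amplitude is profiled out in closed form at every
trial K (or held at a user-supplied fixed value — the practice for
non-saturating effector titrations, where the average fitted Δr_max from
apo-protein experiments is reused).  The remaining one-dimensional
objective in log₁₀K is minimised by bounded Brent search in overlapping
windows around 7 log-spaced starts spanning the K bounds (default
[10⁻¹², 10⁻³] M), and the best local optimum is reported.  Noise-free
recovery is ≤ 10⁻⁴ relative across K ∈ [10⁻⁹, 10⁻⁶] M (grid-tested).

**Lower-bound convention.**  When the best fit's site occupancy at the
final titration point is below 80% of saturation, or the estimate runs
into the upper K bound, only a bound on K is identifiable and the result
is flagged and displayed as "≥ K".  Data with no detectable signal
(profiled amplitude below the 0.01 noise floor) return K at the upper
bound with the flag set, not an exception.  The 80% threshold is
configurable.

**Replicates** are fit independently and summarised as mean ± SD
(ddof = 1) of the per-replicate K estimates.

## Stoichiometric breakpoint

For titrations at probe ≫ K the curve rises quasi-linearly and then
plateaus at saturation.  The plateau is the mean of the final 20% of
points, required to vary less than a noise floor (default 5% of the
maximum signal; otherwise an error advises titrating further).  A
least-squares line through the rising phase (points below 50% of the
plateau) intersects the plateau at the equivalence point, reported in
monomer equivalents per DNA.  With infinitely tight binding the
procedure returns exactly 8.0 for the two-tetramer scheme (4.0 for a
single-site scheme); at the finite affinities and 2.5 µM probe used for
stoichiometry determinations it returns ≈ 8.1, inside the ±0.5
window a practitioner would quote.

## Coupling free energy

ΔG_C = RT·ln(K_effector/K_apo) with R = 1.987 × 10⁻³ kcal mol⁻¹ K⁻¹,
default T = 298.15 K (the 25 °C assay condition).  Every (apo,
effector) replicate pair contributes one equally weighted value; the
default averages in the energy domain (mean of per-pair ΔG).  The
alternative — averaging the K_C ratios first, then taking the log — is
available as `average="ratio"`; by Jensen's inequality it is never
smaller, and for the replicate scatter typical of these experiments the
two differ by far less than the reported SD.  SD uses ddof = 1 (0 for a
single pair).  If either input K is a detection-limited bound, the
energy is reported as a bound ("≥"), never as an exact number.

## Cytosolic competition model

Free formaldehyde F partitions between the sensor's effector sites
(effective dissociation constant `k_sensor`; 10⁻⁵ M for the
formaldehyde sensor, 10⁻⁴ M — a tighter limit — for the related metal
sensor) and the glutathione pool (GSH + F ⇌ S-HMG, K = 1.77 × 10⁻³ M).
Covalent adduct formation is modelled as a reversible equilibrium with
these effective constants; no kinetic irreversibility.  At each total
formaldehyde the single-unknown balance

    F_tot = F + GSH_tot·F/(k_gsh + F) + sites_tot·F/(k_sensor + F)

is solved by Brent bracketing on [0, F_tot] (the left side is strictly
increasing in F).  Defaults: GSH_tot = 1.2 mM (anaerobic growth, all
reduced), sensor tetramer 1.61 × 10⁻⁸ M with 4 sites per tetramer, cell
volume 1 fl.  The sensor pool is numerically negligible against
millimolar GSH: deleting it moves free F by at most
(sites_tot/k_sensor)/(1 + GSH_tot/k_gsh) ≈ 0.4% relative, which is why
the sites-per-tetramer choice (1 vs 4) is immaterial to the curves.

The curve's abscissa is **total** formaldehyde (free + all bound); free
formaldehyde is reported alongside, since for occupancy questions either
axis can be wanted.  The inverse query — the total formaldehyde at which
the S-HMG fraction of GSH reaches a target — has a closed-form free
concentration `F = target/(1−target)·k_gsh` with the bound pools added
back.  A useful identity for checking any implementation: at any shared
free F, the occupancy odds ratio (sensor vs GSH) equals
k_gsh/k_sensor exactly (177 for the formaldehyde sensor, 17.7 for the
metal sensor).

Copies-per-cell conversions use N_A = 6.02214 × 10²³ mol⁻¹;
16.1 nM of tetramer in 1 fl is 9.7 copies.

## Synthetic data

The generator reproduces the two experimental designs: trace probe
(10 nM, 20 points, 0–2 µM added monomer) for K determination, and
stoichiometric (2.5 µM probe, 0–30 µM monomer) for stoichiometry.
Noise is additive i.i.d. Gaussian on Δr with constant SD (default 0.005,
i.e. 5% of the default Δr_max), matching the fitter's least-squares
assumption — a deliberate self-consistency, not a claim about
instruments.  Real titrations additionally show slow drift, titrant
dilution effects, and occupancy-dependent noise, none of which are
emulated; closed-loop recovery tests therefore demonstrate correctness
of the estimator under its own assumptions, not robustness to every
instrumental artefact.  One seeded generator drains all replicates, so a
dataset is a pure function of (parameters, seed).  Closed-loop
calibration at the trace-probe design (5% noise, 3 replicates, 200
seeds) recovers K within 0.1 log₁₀ units in ≥ 95% of runs.

## Problem sizes

Property tests run on schemes of 1–3 components and 1–3 complexes with
totals ≤ 10⁻⁴ M; curve-level checks use the 20–61-point schedules above;
the Monte-Carlo recovery check uses 200 seeds × 3 replicates.  These
sizes fully exercise the numerics while keeping the default test run
under a minute of solver work.

## Known limitations

- No kinetics: everything is equilibrium; time courses and
  irreversible chemistry are out of scope.
- Cooperative (K₁ ≠ K₂) binding is not a fitting default; the scheme
  machinery supports it, the fitter does not expose it.
- No error propagation from fit covariance into ΔG_C; replicate scatter
  is the only uncertainty source reported.
- Fluorescence intensity changes, photobleaching, and G-factor
  corrections are not modelled — the observable is the anisotropy
  change alone.
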