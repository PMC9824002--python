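# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions.

## Hansen solubility parameters (group_contribution)

The Hoftyzer–Van Krevelen scheme treats each partial cohesion parameter as
a group-additive quantity over a molecule's structural fragments:

    δd = Σ Nᵢ Fdᵢ / V        (dispersion)
    δp = √(Σ Nᵢ Fpᵢ²) / V    (polar)
    δh = √(Σ Nᵢ Ehᵢ / V)     (hydrogen bonding)
    δt = √(δd² + δp² + δh²)

with Fdᵢ, Fpᵢ in J^1/2 cm^3/2 mol^−1/2, Ehᵢ in J mol^−1, V in cm³ mol^−1,
and all δ in MPa^1/2 (numerically identical to J^1/2 cm^−3/2). The shipped
group table (`data/hvk_groups.csv`) carries the standard Van Krevelen
attraction constants and Fedors volume increments for eleven common
groups; it is versioned package data so a different dialect can be swapped
in without code changes.

**Molar volume.** The default V is the Fedors sum Σ Nᵢ Vᵢ with a caller
override. Plain Fedors additivity (no ring/branch corrections) markedly
underestimates fused polycyclics, so the bundled luteolin/PVP fixtures pin
back-solved volumes — V = ΣNᵢFdᵢ/δd = 190.82 cm³/mol for luteolin and
89.63 cm³/mol for the PVP repeat unit — chosen so the published partial
parameters regenerate exactly at their printed precision. A side effect
worth knowing: luteolin's δp computes to 6.96 MPa^1/2 at full precision;
tables that print it as 7.00 are seeing rounding interplay, and
recombining *printed* partials can disagree with the full-precision δt in
the last digit (28.66 vs 28.65).

**Greenhalgh rule.** Δδt < 2 MPa^1/2 suggests a glassy solid solution,
< 7 miscibility, > 10 immiscibility. The literature rule is silent on
[7, 10]; the package labels that interval `borderline` rather than
silently assigning either neighbour. PVP is treated per repeat unit, the
standard convention for polymer group contributions.

**Rounding.** All internal math is full precision; comparisons to printed
values use round-half-up at the printed number of decimals.

## Flory–Huggins χ from melting-point depression (flory_huggins)

A crystalline drug's melting point drops in the presence of a miscible
polymer. In FH lattice theory,

    1/Tm,mix − 1/Tm,pure = (−R/ΔHfus)[ln Φd + (1 − 1/m)Φp + χΦp²],

so y = (1/Tm,mix − 1/Tm,pure)(ΔHfus/−R) − ln Φd − (1 − 1/m)Φp against
x = Φp² is a line of slope χ, treating χ as temperature-independent at low
polymer fractions. The fit is unweighted OLS; χ is read from the slope
only, the intercept is reported as a diagnostic (ideal systems give 0).
The caller chooses which points enter the fit (default: all), and ``m`` —
the polymer-to-drug molar-volume ratio — is supplied by the caller; for a
high-molecular-weight polymer such as PVP K90 it is effectively large and
(1 − 1/m) ≈ 1, so results are insensitive to its exact value.

The mixing free energy uses the standard per-site FH form
ΔG/RT = Φd ln Φd + (Φp/m) ln Φp + χΦdΦp, which is strictly negative on
(0, 1) whenever χ ≤ 0 and m ≥ 1. No spinodal/binodal construction and no
χ(T) dependence are attempted.

Temperatures are kelvin internally; the Celsius ingestion path converts
exactly once at construction. The luteolin fixture uses ΔHfus =
187.5 J/g × 286.24 g/mol ≈ 53.67 kJ/mol and Tm,pure = 616.35 K.

## DSC and TGA (thermal_analysis)

Glass-forming ability follows the heat–cool–heat classification: a
cooling-side crystallization exotherm ⇒ class I (and it dominates whatever
the reheat shows); otherwise a reheating exotherm ⇒ class II; otherwise
class III. The classifier requires a melting endotherm in the first
heating — without proof the melt was reached the protocol is not
assessable. Inputs are picked event lists: peak picking from raw heat-flow
traces is instrument-specific, and a simple prominence-based finder is
included only as a labelled heuristic.

Single-Tg verdicts merge glass transitions closer than a tolerance
(default 2 °C, on the order of DSC repeatability) and report
`miscible_single_tg`, `phase_separated`, or `indeterminate` (no Tg).

TGA summaries: the initial (water) loss is 100 minus the interpolated
weight at an early cutoff (default 120 °C, safely above free-water
evaporation); the decomposition onset is the interpolated crossing where
cumulative loss beyond that plateau exceeds a threshold (default 2 %).

## Trajectory analysis (trajectory_analysis)

**RDF.** g(r) between selections A and B is the frame-averaged histogram
of minimum-image pair distances normalized by the shell volume 4πr²dr
(bin centers at (i + ½)dr, default dr = 0.05 Å) and the unordered-pair
density (N_A·N_B − N_AB)/V, where N_AB counts atoms in both selections;
with A = B this reduces to the textbook same-species N(N − 1)
normalization and an ideal gas gives g = 1. Boxes are orthorhombic with
periodic minimum-image convention, and r_max is capped at half the
shortest edge, where the convention is valid.

**Hydrogen bonds.** Geometric criteria: H···acceptor distance ≤ 2.5 Å and
donor–H···acceptor angle ≥ 90°, both inclusive. The angle is evaluated at
the hydrogen vertex — the natural reading of a D–H···A geometry — and an
acceptor is never matched against its own covalent donor. Contact-strength
bands (≤ 2.5 strong, 2.5–3.2 moderate, 3.2–4.0 weak, > 4.0 none) are
stated for donor–acceptor separations; hydrogen–acceptor inputs are banded
with the same cutoffs but tagged with their kind so the two geometries are
never conflated.

**Tg from v(T).** The cooling curve is split at every admissible index
(≥ 3 points per side), each side fitted by OLS, and the split with minimal
total SSE wins; Tg is the intersection abscissa. The estimate is flagged
degenerate when the slopes are near-parallel or the intersection falls
outside the data range — degenerate fits are reported, not silently
dropped, and downstream recovery statistics average only the
non-degenerate estimates (an invalid fit is a detection failure, not an
estimate). The estimator is invariant to scan direction.

## Dissolution metrics (dissolution_analysis)

For a concentration–time profile: c_max and its earliest time t_max,
trapezoidal AUC over the observed window, supersaturation ratio c_max/Cs
against the crystalline equilibrium solubility, retention = final
concentration / c_max (defined 0 for an all-zero profile), and
fold-vs-reference = c_max/c_max(ref). Precipitation-inhibitor ranking
orders by retention, then AUC, then sample id, after linear resampling
onto the profiles' common time window; exact ties are flagged. Retention
and AUC as an inhibition score are this package's explicit
operationalization of the qualitative "maintains higher drug levels"
comparison; no mechanistic (Noyes–Whitney) modelling or f2 similarity is
attempted.

## Synthetic generators (synthetic_data)

All generators are pure functions of their arguments including the seed
(NumPy `default_rng`; no global state), with Gaussian noise models
throughout.

- *Melting depression*: inverts the FH depression relation exactly at a
  chosen true χ, then adds Tm noise (instrument-scale default 0.5 K in the
  tests). Round-tripping through `fit_chi` recovers χ to 1e-6 noiselessly.
- *H-bond configurations*: donor–H–acceptor triples on a 10 Å cubic grid
  so cross-triple contacts cannot approach the 2.5 Å criterion; planted
  triples are collinear with H···A ∈ [1.6, 2.3] Å, decoys violate distance
  (2.8 Å) or angle (60°) with ≥ 0.2 Å / ≥ 10° margins; a brute-force
  enumeration re-verifies the planted count at generation time.
- *v–T curves*: continuous two-slope cooling curves; defaults emulate a
  15-step cooling protocol over 803–203 K with glassy/rubbery
  expansivities 2×10⁻⁴ / 6×10⁻⁴ cm³ g⁻¹ K⁻¹ around v(Tg) = 0.85 cm³/g —
  typical polymer-melt magnitudes. Under 1 % relative noise individual
  15-point replicates scatter by tens of kelvin; the Monte-Carlo tests
  check the *mean* over 200 replicates (within 5 K), which is the
  meaningful accuracy statement at this grid size.
- *Dissolution*: c(t) = c_inf(1 − e^(−k_rise t))e^(−k_precip t), truncated
  at zero; a crystalline mimic is c_inf = Cs with no decay.

What the generators do **not** emulate: real peak shapes or baselines
(DSC/TGA), chemistry beyond role labels (no force fields, no excluded
volume), non-Gaussian instrument noise, and the specific g(r) peak heights
of any real trajectory. Passing tests therefore demonstrate correctness of
the estimators under their stated statistical assumptions, not agreement
with any particular instrument or simulation engine.

## Problem sizes and determinism

Default verification sizes — 500 χ replicates, 200 Tg replicates, 20
ideal-gas frames of 1000 particles, 21 planted H-bond configurations —
were chosen to make sampling error comfortably smaller than the tested
tolerances while keeping the whole suite interactive (seconds). Every
stochastic path takes an explicit seed; the pipeline report is
byte-reproducible for a fixed config apart from its timestamp.
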