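# Methods

## Electron bookkeeping

The degree of reduction of a compound counts the electrons transferred on
complete oxidation to the reference states CO₂, H₂O and NH₃: +4 per carbon,
+1 per hydrogen, −2 per oxygen, −3 per nitrogen (+6 per sulfur when present;
phosphorus is redox-inert and weighted 0, with a warning). Dividing by the
carbon count gives electrons per carbon, the currency of reducing-equivalent
recoveries. This convention is the unique weight set that reproduces the
whole family of coefficients used for the balance substrates (valine 4.8,
glutamate 3.6, aspartate/glycine 3.0, threonine/alanine/ribose/glucose 4.0,
succinate 3.5, formate 2.0). Casamino Acids, an acid casein hydrolysate, has
no single formula; it is modeled as a pseudo-compound with a fixed 4.2 e⁻/C
and an assumed mean-residue basis of 4 carbons and 100 g/mol. That basis is
a flagged assumption (the carbon-per-mole basis behind "10 mM Casamino
Acids" is not derivable), which is why the registry tags it as a mixture
rather than asserting a formula.

Unit conversions assume the standard microcosm make-up: 1 g fresh gut
content in a 10-ml slurry (so 100 µmol gFW⁻¹ = 10 mM) with a dry-mass
fraction of 0.45 (so ÷0.45 converts to per g dry weight). The cytoplasm
concentration helper treats cytoplasm as density 1 g/ml — the only
assumption under which 20% dry matter, 50% protein and a 100 g/mol mean
residue give the ~1 M polymeric-amino-acid figure (and 20% RNA × 40% ribose
× 150.13 g/mol gives ~0.1 M ribose).

## Gas partitioning

Total vessel CO₂ is headspace (ideal gas: n = xPV_head/RT) + dissolved
(Henry: n = K_H·x·P·V_liq) + bicarbonate (Henderson–Hasselbalch:
CO₂(aq)·10^(pH−pKa₁)); H₂ omits the bicarbonate term. Defaults: K_H(CO₂) =
3.39×10⁻² and K_H(H₂) = 7.8×10⁻⁴ mol L⁻¹ atm⁻¹ and pKa₁ = 6.35, all at
25 °C; the gas-law temperature defaults to 298.15 K for consistency with
those constants even though incubation was at ambient 21–24 °C (a ~1%
effect on the headspace term, configurable). The 60 kPa N₂ pressurization
is read as an overpressure, so the default absolute pressure is 161.325 kPa;
a vessel at exactly 1 atm is a one-argument change. Carbonate is neglected:
at pH ≤ 7.5 CO₃²⁻ is <1% of dissolved inorganic carbon. All three terms are
linear in the mixing ratio, so the partitioning commutes with control
subtraction downstream.

## Recovery accounting

Net product formation is computed on replicate means, matching how the
balance tables report one value per treatment; per-replicate deltas are
retained for the collective-product significance test (Welch's t with
Satterthwaite degrees of freedom, implemented from the closed form). A
product whose control-corrected net is ≤ 0 is "no net increase": it carries
0 in all arithmetic and renders as "—"; the signed value stays in the audit
column. Recovery of product p from substrate s is
100·net_p·C_p/(dose·C_s) for carbon and the analogous electron ratio; H₂
rows have no carbon cell and CO₂ rows no electron cell ("NA"), and totals
sum the applicable cells. The dose denominator is either the amount
provided or the measured disappearance of the substrate ("consumed" basis);
disappearance is the default interpretation of a consumed basis, and noisy
negative estimates clamp to 0 with a warning rather than producing a
negative denominator. Reports round to 2 significant figures; all internal
arithmetic is full precision. Recoveries are invariant under any consistent
unit rescaling of dose and products.

## Responder screening

The net increase of relative abundance follows three steps per molecule
stratum (DNA and RNA are never averaged): (i) mean relative abundances
where the three replicates were sequenced separately, single values where
they were pooled; (ii) time correction, end minus start of incubation, for
treatment and control; (iii) treatment delta minus the control delta, with
negative control deltas treated as 0. The procedure leaves a genuinely open
edge: a negative treatment delta can make the final value negative, and the
source procedure does not say what was done then. Here reports and
threshold screens clamp at 0 while the signed value is kept in the result
object, so the choice is auditable rather than silent. Nets are expressed
in percentage points; families are screened at ≥4 points in at least one
treatment × molecule, phylotypes at ≥2 (both inclusive). Family-level nets
are computed by summing abundances to the family *before* the net-increase
arithmetic (the subtraction is linear, so the alternative sum-after order
differs only when clamping interacts with mixed-sign members; it is
available via `order="sum-after"`).

Group phylotypes merge stimulated phylotypes whose representative sequences
are ≥97% identical: greedy clustering with seeds ordered by descending
maximal net increase (ties by id), each sequence joining the first seed
within threshold. Identity is matches / alignment length under a global
alignment with free end gaps, match 1 / mismatch 0 / linear gap −1 — no
specific aligner is canonical for this definition, so it is pinned here and
configurable via a `PairwiseAligner` instance.

Diversity: Shannon uses the natural log (the base is not canonical; config
knob provided), Chao1 defaults to the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)) so it stays defined without doubletons (classic
form by flag), rarefaction is the analytic hypergeometric expectation
E[S_d] = Σ(1 − C(N−n_i, d)/C(N, d)) evaluated in log-gamma space, and
Bray–Curtis is 1 − 2Σmin/Σ(a+b).

## Synthetic data

The microcosm generator plants a carbon- and electron-balanced
stoichiometry (the default: 1 glutamate → 1 acetate + 0.5 butyrate + 1 CO₂,
carbon 2+2+1 = 5 and electrons 8+10+0 = 18, an exact rewrite of C₅/18 e⁻)
and rejects imbalanced yield sets at construction, which is what makes
noiseless recovery totals 100% a theorem rather than a fit. Products
accumulate along a logistic curve over a 30-h grid; the control shares the
background product drift exactly, so control subtraction recovers the
planted yields. Noise is multiplicative log-normal on each observation
(mean-preserving, chromatographic-peak-like; additive Gaussian by flag).
Default conditions mirror the study design: 100 µmol gFW⁻¹ dose (10 mM),
three replicates, 6-h sampling grid, 5% noise where noise is wanted.

The community generator draws a 40-taxon background from a symmetric
Dirichlet (concentration 0.5 — a long-tailed, soil-like composition; a
modeling choice, not a claim about the study's data) and lays out samples
as the sequencing design did: control strata and the end-point RNA stratum
as three replicates, the remaining supplemented strata as single pooled
libraries. At the end of incubation a responder is spiked to baseline +
boost (percentage points) with the non-responders renormalized into the
remaining mass, so the planted net increase is exact at zero noise and
background taxa show the small compensating negatives a composition must.
Default boosts are 6 and 10 points, of the magnitude of the strong
family-level responses the screen is meant to find; per-taxon, per-sample
abundance noise is a truncated Gaussian of SD 0.25 percentage points
followed by renormalization. What this generator does *not* emulate:
sequencing-depth-dependent (multinomial) noise, taxon correlations,
cross-contamination, or compositional drift in the control beyond noise —
so a perfect screen on synthetic tables demonstrates the arithmetic and the
thresholds, not robustness to real library effects.

The sequence generator mutates a random ancestor; the divergence plan lists
each record's target identity to the ancestor. Mutated positions are nested
across records and characters at shared positions are chosen pairwise
distinct, so the realized identity between any two records is
min(plan_i, plan_j) up to the 1/length rounding of the substitution count.
Over a 4-letter alphabet at most three mutated records can share a
position, so deeper simultaneous divergence plans are rejected as
unsatisfiable; larger test sets are built as several independent families.

## Numerical and interface choices

- Endpoint arithmetic only: no interpolation or imputation between the 0-h
  and 30-h points beyond what the endpoints define.
- Degenerate Welch inputs (both variances zero) return p = 1 for equal
  means and p = 0 with a warning otherwise.
- Abundance tables validate column sums to 1 within 1e-9 (1e-6 on file
  read, with an opt-in renormalize policy); compositional closure of the
  time-corrected deltas then holds to 1e-9 by construction.
- Problem sizes in the test suite (40-taxon communities, 200- and 100-seed
  Monte-Carlo sweeps, ≤20-sequence clustering sets at 250 nt) are chosen so
  each property is exercised across its randomness while the whole suite
  stays interactive-fast.
- Reports are byte-deterministic given identical inputs and config, and
  carry a provenance header (version, config hash, seed, input checksums).

## Known limitations

- The recovery pipeline assumes products are measured as amounts per g
  fresh weight with gas totals already partitioned; it does not model
  kinetics, pathway flux, or transient intermediate turnover.
- The Casamino Acids carbon basis is assumed, so absolute recoveries for
  mixture substrates inherit that uncertainty (their relative comparisons
  do not).
- Ammonium handling is a generic linear standard-curve calibration;
  the colorimetric chemistry itself is out of scope.
- NMDS ordination, LEfSe effect sizes, phylogenetic trees and raw-read
  processing are deliberately out of scope; Bray–Curtis matrices are
  provided as the input an ordination would consume.
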