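# Methods

This note records the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions used throughout.

## Residue numbering and constructs

All residue numbers are full-length (UniProt-style) 1-based numbers
with inclusive ranges, everywhere. Expression constructs carry an
artificial N-terminal prefix (e.g. the Gly-Ala-Met scar of a TEV
cleavage site) numbered consecutively so the first native residue keeps
its full-length number: a GAM prefix before native residue 21 is
numbered 18–20. Theoretical masses are average (isotope-abundance)
masses of the intact unmodified chain — free termini, reduced
cysteines, no isotope-labelling shift — which is the convention behind
the "theoretical kDa" printed for unlabelled constructs; display
rounding is 2 decimals in kDa. The residue-mass table is written out in
`constructs.py` (20 values plus water) so the test suite can cross-check
it against Biopython's independent implementation rather than depend on
it.

## Secondary chemical shifts

The combined value is SCS = (δCα_obs − δCα_coil) − (δCβ_obs − δCβ_coil).
Helix formation moves Cα downfield and Cβ upfield, so the difference
amplifies both effects into one trace; for glycine and residues without
an assigned Cβ the combined value is ΔδCα alone. The bundled coil
reference is the Wishart et al. (1995) GGXAGG set (neutral pH, 25 °C),
selectable by `rc_table_id`; other tables can be registered at run
time. No sequence-neighbour corrections are applied by default — the
calling rules tolerate the ~0.1–0.3 ppm they would change, and keeping
the reference a pure per-residue-type lookup makes the computation
reproducible from the table alone.

Element calling uses strict inequalities (> +1 ppm, < −1 ppm; values
exactly at the threshold do not count), minimum lengths of 3 (helix)
and 4 (strand) consecutive residues, and residues missing from the
profile break runs. The 1 ppm threshold applies to the combined value,
not to Cα and Cβ separately — the combined trace is the quantity
plotted and thresholded in practice.

## Heteronuclear NOE and rigid core

hetNOE = I_sat/I_ref per amide. Classification: < 0.5 flexible, > 0.65
rigid; the band [0.5, 0.65] is labelled "intermediate" rather than
forced into either class, since the thresholds themselves say nothing
about it. Ratio errors propagate per-list noise floors as
σ_ratio = |ratio|·√((σ_sat/I_sat)² + (σ_ref/I_ref)²); spectral software
suites each use their own internal error model, so the noise floors are
caller-supplied and default to zero.

The rigid core is the longest stretch of rigid residues in which
interruptions (non-rigid or unobserved) of at most `max_gap = 3`
consecutive residues are tolerated, and which starts and ends on rigid
residues. A 3-residue tolerance bridges the short mobile loops that
occur inside otherwise rigid helix–loop–helix domains while still
splitting cores separated by genuinely flexible linkers.

## Titration CSPs

CSP = √((ΔδN/5)² + ΔδH²), with the ¹⁵N scaling fixed at exactly 1/5.
CSPs are computed apo → endpoint (highest molar ratio); intermediate
points serve trajectory checks only, because in fast exchange all
points lie on the same line and the endpoint has the best
signal-to-perturbation ratio.

Significance thresholds over the CSP profile: `mean`, `two_sd` (2σ) and
`mean_plus_two_sd` (default). σ is the population SD — the profile is
the complete population of observed residues, not a sample from a
larger one. Selection is strict (> threshold), and a zero-variance
profile marks nothing: uniform perturbation supports no outlier claim.
All three modes are first-class and recorded in reports because
figure-legend conventions in the literature are ambiguous about whether
"2× standard deviation" includes the mean.

Trajectory similarity is the per-residue cosine between (ΔδH, ΔδN/5)
vectors; 1.0 means the same binding mode with possibly different
extent. Variant comparison sums variant CSPs over the wild-type
significant residues: extent ratio < 0.1 → abolished; [0.1, 0.7) with
summary cosine > 0.8 → reduced; ≥ 0.7 with cosine > 0.8 → wild-type
like; otherwise nonspecific (shifts without a conserved direction,
e.g. surface-charge effects of a partially unfolded variant).

Fold assessment: folded iff amide ¹H range > 1.5 ppm AND ¹H SD >
0.35 ppm (both configurable). A collapsed HSQC piles amides into the
7.9–8.5 ppm random-coil window; both metrics are reported regardless of
verdict.

Peak matching is by residue identity for assigned lists; a greedy
nearest-neighbour mode (distance-bounded, ties by smallest distance
then lowest residue number) supports unassigned endpoints such as
mutant or pH-shifted spectra. Pairs moving farther than the tolerance
(default 0.15 ppm combined scale) are flagged "jumps" but kept.

## ¹⁵N relaxation and correlation time

Decay curves I(t) = I₀·exp(−Rt) are fitted by Levenberg–Marquardt least
squares (scipy `curve_fit`) with log-linear start values; delays are
milliseconds, rates s⁻¹. Fit quality is 1 − SSR/SST; rate errors come
from the fit covariance. Fitted rates ≤ 1e-6 s⁻¹ (no observable decay)
are flagged and excluded downstream.

τc from R2/R1, two algebraic readings:

* default `threehalves`: τc = (1/(2πν_N))·√((3/2)(R2/R1) − 7/6)
* `classical`: τc = (1/(4πν_N))·√(6(R2/R1) − 7)

Both are implemented because the printed forms of this estimator vary
across the literature and the two differ by < 8% in the slow-tumbling
range (R2/R1 ≳ 4) where the estimator is meaningful. ν_N is derived
from the spectrometer proton frequency via |γ(¹⁵N)/γ(¹H)| = 0.10136767.
At the root boundary the estimate is 0; below it (extreme narrowing)
the estimator is invalid and raises. The acceptance tests measure the
estimator against the spectral-density oracle: recovery is within 10%
at 5.3 ns/600 MHz and improves with τc, but the `threehalves` reading
overestimates strongly below ~3 ns (it is a slow-tumbling
linearization), so short correlation times should use the `classical`
reading or a full spectral-density fit, which is out of scope here.

Domain averages are the plain mean ± SD over included residues —
residues classified rigid when a hetNOE profile is supplied (flexible
termini tumble faster than the domain and bias τc low), else all
residues with valid rates. A 10%-per-tail trimmed mean is available for
exchange-contaminated profiles but is not the default. R1ρ may stand in
for R2 (partially exchange-free); the report then says "R1rho-based".

Apparent MW = τc / 0.6 ns·kDa⁻¹, the standard rule of thumb for
globular proteins near 298 K, exposed as a configurable constant. The
exchange diagnostic flags a profile when SD/mean of R2 exceeds 0.5.

## SEC calibration

Kav = (Ve − V0)/(Vc − V0); ordinary least squares of Kav on log10(MW)
(log base 10 is the conventional choice); sample MWs by inverting the
line, with a warning when extrapolating beyond the standards range.
Oligomer classification by apparent/theoretical mass ratio: < 1.4
monomer, ≥ 1.75 dimer or larger, between them an intermediate class
covering exchanging monomer–dimer mixtures and non-globular retention.
The thresholds are deliberately asymmetric around √2 and 2 because
elongated or breathing monomers commonly read 10–30% heavy on a SEC
column without being dimers. Peak elution volumes are inputs;
chromatogram peak-picking is out of scope.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) using numpy's
`default_rng`; each attaches the ground truth it planted.

* **Titrations** — single-site binding, bound fraction from the exact
  quadratic isotherm, observed peak = population-weighted average of
  free and bound positions (textbook fast-exchange limit). Noise is
  Gaussian per axis, with the ¹⁵N jitter scaled ×5 so noise is
  isotropic in combined-CSP space. Defaults emulate the study
  conditions of a small-domain DNA titration: 0.5 mM protein, ratios
  0, 0.5, 1, 1.85, 4, 6, micromolar-range Kd (0.05 mM), ≤ 10% of
  residues planted as binders. Not modelled: intermediate/slow
  exchange, line broadening, peak overlap, differential endpoint
  saturation per residue.
* **Relaxation** — the Lipari–Szabo spectral density
  J(ω) = (2/5)[S²τc/(1+(ωτc)²) + (1−S²)τ/(1+(ωτ)²)], 1/τ = 1/τc + 1/τe,
  in the standard dipolar + CSA rate expressions with r_NH = 1.02 Å and
  Δσ = −160 ppm (standard amide values, exposed on the model record);
  Rex adds to R2. Decay curves use the standard T1/T2/T1ρ delay lists
  shipped as named presets. This oracle exists to quantify the R2/R1
  estimator's approximation error; it assumes isotropic tumbling and
  per-residue independence (no anisotropic diffusion tensor, no
  interleaving artifacts, no spectral noise correlation).
* **Secondary shifts** — coil values plus planted offsets
  (ΔCα, ΔCβ) = (+2.8, −0.4) ppm in helices and (−1.5, +2.0) ppm in
  strands, which sit inside accepted empirical ranges; they are
  generator parameters, not claims about any particular protein.
  Recovery tests use i.i.d. noise of σ = 0.3 ppm per atom.
* **hetNOE** — plateau value on the core, linear decay to the terminal
  value over a 4-residue ramp, optional planted dips for mobile loops.
  Real profiles decay smoothly and are field-dependent; the generator
  only reproduces the features the classifier consumes.
* **SEC** — standards and samples placed exactly on a known
  Kav/log10(MW) line (defaults: v0 = 8 mL, vc = 24 mL, slope −0.4,
  intercept 1.0, the geometry of a typical 24 mL analytical column with
  a low-MW standard kit), with optional Gaussian jitter on Ve.

Because the generators realize the same functional forms the analyses
invert, passing recovery tests demonstrates correctness of the
implementations and self-consistency of the pipeline — not performance
on real spectra, where exchange broadening, overlap and assignment
errors dominate.

Problem sizes in the recovery tests — 50-residue peak lists, 200 seeds
per property, 20-residue relaxation profiles — are chosen as the
smallest sets on which the planted effects are statistically
unambiguous.

## Degenerate inputs and error conventions

Duplicate (residue, atom) shift entries and duplicate peaks per residue
are validation errors; malformed files raise format errors naming the
offending value. Out-of-window amide positions warn by default and
raise under strict mode (folded/aliased peaks exist in practice).
Tables are canonically sorted on load, so reader output is independent
of on-disk row order. Reports serialize floats at full repr precision.

## Known limitations

* The R2/R1 → τc estimator is biased high outside the slow-tumbling
  regime (see above); it is a screening tool, not a substitute for
  model-free analysis.
* The NMR-STAR reader handles the chemical-shift loop of v3 entries
  only; everything else in an entry is ignored with a logged notice.
* No Kd fitting from CSP isotherms, no line-shape or
  intermediate-exchange modelling, no per-residue model-free (S², τe,
  Rex) fitting, no anisotropic diffusion, no chromatogram peak
  detection, no light-scattering mathematics.
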