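# Methods

## Reaction model

The click step is modeled as an elementary bimolecular reaction between
protein-borne azide sites (A) and dye-DBCO (B):

    dx/dt = K ([A]0 − x)([B]0 − x)

with integrated form, expressed as the fraction of dye reacted,

    x/[B]0 = [A]0 (e^{Kt([A]0−[B]0)} − 1) / ([A]0 e^{Kt([A]0−[B]0)} − [B]0).

Assumptions: all azide sites are equally reactive and independent, so
the site concentration is [A]0 = I.R. × protein molar concentration;
no depletion-of-sites correction for multi-dye binding (sites exceed
dye in the recommended I.R. ≥ 2×aDoL regime); no diffusion-limited or
steric effects, which become visible with bulky payloads or very high
target DoL and would require a refit of K or longer incubations.

Numerics: the rate law is evaluated as `a0·expm1(e)/(a0·expm1(e)+(a0−b0))`
with `e = Kt(a0−b0)`, which is exact and continuous as a0→b0; at
|a0−b0|/max(a0,b0) < 1e-6 the closed-form equal-concentration limit
Kt·a0/(1+Kt·a0) is used instead of the singular quotient; exponents
beyond ±700 return the asymptote min(1, a0/b0) to avoid overflow.
Inversion to incubation time is closed-form and round-trips with the
forward model to 1e-9 relative.

Rate-constant fitting is one-parameter nonlinear least squares in
log-K (scipy `least_squares`, Levenberg–Marquardt). The standard error
is the usual local-curvature estimate: residual variance times the
inverse Gauss–Newton Hessian, transformed back to K. A noiseless trace
is recovered to machine precision; at 2% multiplicative noise with 12
time points the median relative error stays below 2% (checked over 200
seeds per rate constant in the test suite). Traces with no point in
(0.05, 0.95) are rejected as unidentifiable.

## Chromatogram analysis

Peaks are located as the maximum within ±window (defaults: conjugate
8.8 ± 1.0 min, free dye 16.5 ± 1.5 min), their width estimated from the
half-height crossing (σ = FWHM/2.355), and integrated by trapezoid over
apex ± 4σ. The baseline is assumed zero (optionally a constant median
baseline is subtracted); a window with no signal above 3× the robust
MAD noise yields a zero-area peak. Free and conjugated dye are assumed
to have equal extinction at the detection wavelength, so area fractions
equal mole fractions. Reaction-progress traces can alternatively be
built from conjugate peak *heights* normalized to the plateau, matching
the common practice of reading the conjugate elution peak value; both
modes are exposed because the two differ only through peak-shape drift,
which the synthetic generator does not model.

## Spectrophotometric aDoL

Single-wavelength pairs (A280, A at the dye's λmax) are the primary
input; full spectra are reduced by nearest-sample lookup within ±2 nm.
Dye and protein concentrations follow Beer–Lambert with the dye's
280 nm correction factor CF (fraction of its peak absorbance
contributed at 280 nm): protein = (A280 − CF·Amax)/ε280. A corrected
A280 ≤ 0 is an error, not a clamp — it signals a wrong CF or a
dye-only sample. No scatter or baseline correction is applied. CF is
dye-specific; dyes without a registered CF must be given one explicitly.

## MS incorporation ratio

Input is an already-deconvoluted (mass, intensity) peak list; charge
deconvolution, isotopes and glycoforms are out of scope (the MS route
suits small, non-glycosylated proteins). Label counts are
round((m − base)/Δ) with Δ = 83.05 Da by default (average azidoacetyl
increment, azidoacetic acid 101.07 − H₂O 18.02; monoisotopic 83.012 is
configurable). Peaks whose residual exceeds 0.3·Δ, or that round
negative, are flagged and excluded — the 0.3 fraction keeps adjacent
ladder rungs from ever colliding. The I.R. is the intensity-weighted
mean count over unflagged peaks; activation efficiency is
100·I.R./excess rounded half-up to an integer percent (half-up, not
banker's, so 32.5 → 33). Two published-table-style combinations where
an I.R. already rounded to one decimal divides to a neighboring percent
are documented exceptions, not targets.

## Poisson label multiplicity

Pure Poisson: pmf(k; λ=aDoL) computed via scipy in log space. No
finite-site (binomial) correction is applied even though lysines are
finite — with 30–90 accessible lysines on a typical protein and aDoL of
2–8 the correction is below the precision anyone quotes. The default
support cutoff λ + 10√λ + 20 keeps the truncated pmf mass deficit below
1e-9.

## FCS analysis

The model is the standard 3D-Gaussian diffusion autocorrelation

    G(τ) = (1/N) Σᵢ fᵢ (1 + τ/τ_Di)⁻¹ (1 + τ/(s²τ_Di))^{−1/2}

with no triplet term. The structure parameter defaults to s = 5
(typical single-photon confocal) and is configurable; only amplitude
and τ ratios matter for the fractions and brightness ratios computed
here. Fits are weighted least squares (lmfit) with relative weights,
matching the generator's multiplicative noise; real FCS noise models
(photon statistics, afterpulsing) are out of scope. For two-component
fits the fast diffusion time should be fixed to the independently known
free-dye value (default 25 µs; conjugate times scale as MW^(1/3), so a
150 kDa conjugate sits near 133 µs) — with it fixed, free-dye fractions
of 0.05–0.5 are recovered to well under 0.03 absolute at 1% noise. A
fitted τ ratio below 1.6 triggers an identifiability warning rather
than an error. Brightness is CPM = mean intensity / N, with N taken
from the fitted amplitude.

## Planner

Design rules: required I.R. = 2 × target aDoL (the full-consumption
condition); azide-NHS excess = ⌈required I.R. / efficiency⌉ with a 0.30
efficiency prior — the ceiling, not rounding, because under-activation
breaks the aDoL guarantee; click dye at exactly target × protein;
incubation from the rate-law inversion at the requested completion
(default 0.99). Warnings fire below 10 µM dye or 25 µM azide sites,
above the recommended 3–5 attachment band, and for dyes flagged as
incompletely reacting (AZ532, AZ647). The 30% prior is a typical value,
not a per-protein promise — it varies by protein and reagent lot, so it
is an explicit argument. The 2× rule is implemented as stated; data
exist where an I.R. of 7 failed to support an aDoL of 6 while 15 did,
i.e. the rule is a necessary-not-sufficient guideline at high aDoL.

## Synthetic data

The generators emulate the statistical structure each analysis assumes:
chromatograms are two Gaussian peaks (σ 0.15 / 0.10 min on a 0.01 min
grid) splitting a constant total dye area by the rate-law fraction, with
multiplicative noise (default 2%); spectra are Gaussian bands (protein
280 nm σ 12 nm, dye at λmax σ 15 nm) with the dye's 280 nm cross-talk
pinned exactly to CF·Amax, plus additive noise; mass ladders carry
Poisson-pmf intensities truncated at n_max = 15 and renormalized; FCS
curves evaluate the diffusion model on a 64-point log grid (1 µs – 1 s)
with multiplicative noise (default 1%). Peak/band widths, grids and
noise levels are realism choices, all configurable per call. Every
generator is a pure function of its arguments plus a seed. The built-in
reference scenario encodes the monitored antibody experiment: 2 mg/mL
antibody (13.33 µM), I.R. 5.6, 2× dye, K = 4.31 M⁻¹s⁻¹, sampled at
5 min, 55 min, 267 min and 24 h.

What the generators deliberately do *not* model — chromatographic
tailing, PDA spectral cubes, baseline drift, photon shot noise, triplet
blinking, glycoform mass heterogeneity — bounds what passing tests
show: the analysis chain is correct and self-consistent under its own
assumptions, not that it is robust to every instrument artifact.

## Problem sizes and determinism

Stochastic recovery tests use 12-point kinetic traces and 64-point FCS
curves at 200 seeds per condition, and 1e5–1e6 draws for Monte-Carlo
cross-checks of the Poisson and I.R. estimators; these sizes give
sampling error an order of magnitude below the asserted tolerances.
All randomness flows from explicit seeds; identical inputs produce
bit-identical outputs.

## Known limitations

* K = 4.31 M⁻¹s⁻¹ is specific to AZ488-DBCO on an activated antibody;
  other payload/protein pairs need their own fitted K.
* The planner's completion guarantee inherits the all-sites-equal
  kinetics assumption; crowded proteins at high I.R. react slower.
* aDoL via absorbance assumes the conjugated dye's spectrum (ε, λmax,
  CF) matches the free dye's.
* FCS fractions are fluorescence-weighted; converting to mole fractions
  assumes equal per-molecule brightness of the two components, which
  self-quenching violates at high aDoL.
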