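# Methods

This note documents the models behind `mitoinit`, the defaults that
matter, the choices made where several designs were defensible, and what
the synthetic data do and do not establish.

## Confocal trace simulator

**Model.** Molecules of each species in a `SpeciesMix` cross the
detection volume as a homogeneous Poisson process with rate
`occupancy × fraction / mean_transit_time`, so the expected number of
molecules in the volume is the configured occupancy. Each transit has an
exponentially distributed duration (mean `mean_transit_time`) and a
Gaussian temporal intensity profile with σ = duration/4, truncated to
the transit; the photon count of a bin is Poisson with mean equal to the
exact integral of that profile over the bin (so binning introduces no
discretization bias), times the brightness and the number of active
dyes. Diffusion is modeled in time only: the confocal point-spread
geometry is folded into the brightness and transit-time parameters.
This reproduces the burst statistics that coincidence detection consumes
— dispersed burst durations and brightnesses, partial transits, Poisson
shot noise — and is declared a stand-in, not a reconstruction of any
specific instrument's volume model.

**Labels and losses.** A green-labeled species carries its Cy3 dye with
probability `labeling_efficiency_green`. A red-labeled species carries
its dye stack at all with probability `labeling_efficiency_red` and then
`Binomial(n_dyes_red, 1 − bleach_prob_per_transit)` active dyes per
transit; the default `n_dyes_red = 6` reflects multi-dye labeling of the
large subunit (about six Cy5 dyes per ribosome). `labeling_efficiency_red`
deliberately lumps incomplete labeling, complete bleaching and
dissociation into one detectability: measured positive controls bundle
exactly these losses, so calibrating a simulation "to the positive
control" means setting this one number. Channel crosstalk adds
`crosstalk_green_to_red` (default 0.02, typical of good filter sets) of
the green molecular signal to the red channel; each channel gets
independent Poisson background (default 1000 counts/s).

**Defaults.** 1 ms bins; 2 ms mean transit (a large, slow particle such
as a 55S monosome); brightness 25 photons/bin for the single green dye
and 8 photons/bin per red dye at focus; occupancy 0.01, the
single-molecule regime in which accidental coincidence stays at the
percent level. Exceeding 0.01 warns rather than errors, since negative
controls intentionally probe that regime. Random streams are separated
by purpose (arrivals, labeling, photons), so changing, say, a brightness
leaves the arrival pattern untouched; a given (config, mix, seed)
reproduces the trace bit for bit.

**FCS.** `autocorrelation` computes the normalized intensity ACF over
lags 1..max_lag (the zero-lag shot-noise point is excluded) and
`fit_diffusion_time` fits the two-dimensional Gaussian-volume diffusion
curve A/(1 + τ/τ_D). For compact transits with exponentially distributed
durations, the hyperbolic fit's τ_D is a fixed fraction (~0.23) of the
mean transit time rather than the transit time itself — real diffusion
shows slow re-entry tails that this transit model does not have. The
simulator therefore exposes its own ground truth as `analytic_acf`, the
closed-form-in-T, numerically-averaged-over-T model correlation;
recovery tests fit the simulated and analytic curves on the same lag
grid and require 20% agreement. Fitted τ_D values should be compared
against that analytic reference, not against `mean_transit_time`.

## BTCCD

**Burst search.** Bursts are maximal runs of bins at or above a count
threshold; runs separated by at most `max_gap` (default 1) sub-threshold
bins merge; merged runs shorter than `min_bins` (default 2) are
discarded. The default threshold is background + 5 SD, with background
estimated by the channel median (robust because transits occupy a tiny
fraction of bins in the single-molecule regime). These criteria are
explicit knobs because burst-search details vary between labs.

**Gating and coincidence.** The brightness gate keeps bursts at or above
the 0.7 quantile of the burst-brightness distribution (the brightest
~30%), selecting central-volume transits whose partner-channel signal,
if present, is far above detection threshold. A reference burst is
coincident if a partner-channel burst overlaps it by at least one bin.
By default only the reference channel is gated: the gated fraction then
estimates P(partner dye present | central reference transit), which is
the associated fraction. Gating the partner channel as well multiplies
the estimate by the partner gate's keep fraction (~0.3) and is available
as `gate_partner=True` but not the default.

**Reference channel.** Both directions are computable; the API defaults
to red (per labeled ribosome). The acceptance simulations use the green
(mRNA) reference because that is the direction in which the exchange
arithmetic composes mechanistically: green bursts are mRNA-bound
complexes, and their coincidence probability is P(labeled LSU) × red
detectability, so a fully labeled sample calibrated to the
positive-control level and an exchange sample at
exchanged-fraction × pool-fraction reproduce the printed 43% and 27%
without further adjustment.

**Controls and uncertainty.** The chance-coincidence control circularly
shifts the partner bursts by half the trace (destroying real
correlation while preserving both marginals) and recomputes the
fraction; it is distribution-free and testable against independent
simulations. Uncertainty is a percentile bootstrap over reference bursts
at 68% by default, mirroring ±SD-style reporting. No numeric correction
for complex dissociation during acquisition is applied.

## Exchange and binding arithmetic

With a k-fold excess of labeled free subunits over (unlabeled)
monosome-derived subunits, the labeled pool fraction is k/(k+1);
complete exchange predicts coincidence f_pos × k/(k+1); the exchanged
fraction is f_obs / f_pred and the monosome (no-exchange) fraction its
complement, which sum to 1 exactly. Internal values are never rounded;
display helpers round coincidence percentages to the nearest integer and
the competence percentage to the nearest ten, matching how such values
are conventionally printed. An observed value above the prediction
(possible given measurement uncertainty) clamps to 1 with a warning and
a flag rather than erroring. No error propagation of ± values is
performed; the caller owns uncertainty handling.

The calibration line is ordinary least squares *with* an intercept —
buffer background contributes a concentration-independent offset — and
its inversion clamps negative concentrations to zero with a warning.
Converting ribosome A260 to molarity needs an extinction coefficient
that must be supplied explicitly; there is no hidden default.

## Footprint counting

Coordinates are 0-based, intervals half-open, everywhere. The counting
window runs from the first nucleotide of the start codon up to,
exclusively, 30 nt 5′ of the stop codon; the exclusive far boundary is a
convention isolated in `counting_window`. Footprints are assigned by 5′
end only, in the positive-sense orientation of the gene; no P-site
offset is applied. Reads whose 5′ end falls in a declared bicistronic
overlap are tallied as `excluded` (not silently dropped), reads matching
no window as `unassigned`, so counted + excluded + unassigned always
equals the input — a testable conservation law. Whether percent
denominators should also exclude reads on overlap-truncated windows is
not externally documented; this implementation excludes overlap reads
from the denominator and flags the choice here. Antisense reads over an
overlap are `unassigned`, not `excluded`, since no ambiguity exists for
them.

The packaged human annotation lists the 13 mtDNA protein-coding ORFs in
rCRS coordinates, with `stop_first` taken as the first base of the last
annotated codon (mitochondrial stop codons completed by polyadenylation
are treated as occupying that codon). Its bicistronic overlaps are 46 nt
(ATP8/ATP6) and 7 nt (ND4L/ND4). The synthetic generator draws genes
from normalized weights and positions uniformly within the effective
window — it emulates multinomial sampling depth, not codon-level pause
structure, library-to-library variability, or end biases of real
MitoRibo-seq libraries; passing recovery tests therefore validates the
counting arithmetic, not any biological inference. The knockout preset
(ATP6 weight × 0.1, ATP8 × 1.6) emulates the qualitative signature of
losing initiation on the downstream ORF of a bicistronic transcript.

## Problem sizes and numerical choices

Simulated acceptance measurements use 3600 s acquisitions (one hour, the
scale of real single-molecule sessions) at occupancy 0.01, yielding
~2500–3000 gated reference bursts; test-suite simulations use 1800 s
(~1400 bursts) and the statistical tests size their tolerances by the
corresponding binomial or multinomial standard errors. Curve fits use
`scipy.optimize.curve_fit` with an amplitude/half-decay starting point;
a non-decaying ACF raises a diagnostic error instead of returning a
spurious τ_D. Brightness-gate quantiles use numpy's default (linear
interpolation) empirical quantile. Bootstrap and simulators consume
`numpy.random.default_rng` seeds only through explicit arguments.

## Known limitations

* No sub-bin photon timing, pulsed excitation, lifetime or FRET
  modeling; no 3-D Brownian dynamics or triplet kinetics.
* The transit model's τ_D is meaningful only relative to its own
  analytic ACF (see above), not as an absolute diffusion coefficient.
* Chance coincidence is controlled, not subtracted: reported fractions
  include accidental coincidence (percent-level at occupancy 0.01).
* The riboseq module consumes alignments as given; trimming and
  sequential mapping against nuclear/rRNA/tRNA references are upstream
  concerns. No differential-expression statistics are provided.
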