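# Methods

`chromofret` implements a multimodal single-molecule FRET analysis aimed
at systems like chromatin fibers: a few structural states with distinct
inter-dye distances, exchanging on timescales from tens of microseconds
(nucleosome unstacking) to hundreds of milliseconds (register exchange),
observed through two complementary modalities — confocal
multiparameter fluorescence detection (MFD) of freely diffusing
molecules, and camera-based smTIRF of immobilized molecules at 100 ms
frames. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data tests do
and do not establish.

## Kinetic model

States are FRET species: a name, an inter-dye distance `R_DA` (Å) tied
to an efficiency through the Förster relation `E = 1/(1+(R/R0)^6)`, a
quenched donor lifetime `τ_D(A) = τ0(1−E)`, and a relative brightness.
Two built-in dye pairs cover the two labelling schemes: Alexa568/647
(`R0 = 82 Å`, `τ0 = 3.6 ns`) for long distances, Alexa488/647
(`R0 = 52 Å`, `τ0 = 4.0 ns`) for resolving compact states.

Exchange is a continuous-time Markov process with generator `K` in 1/s
(row = from-state; diagonal = −row sum). Rates are per second and times
seconds everywhere except micro-times (ns); mixing µs/ms/s at interfaces
is how unit bugs happen. A `connectivity_mask` pins forbidden
transitions at exactly zero. Each *connected component* of the allowed
graph must be irreducible; the graph as a whole may be disconnected.
That choice is deliberate: the two-register kinetic scheme — one branch
{A, C} ⇌ D, a second branch B ⇌ D, with no register exchange through
the open state on the observation timescale — is two independent
equilibria. Operations that need a unique stationary law
(`stationary_distribution`, `relaxation_times`) refuse disconnected
models; the PDA layer decomposes them into branches with mixture
weights. An explicit `require_irreducible=False` escape exists for
deliberately absorbing schemes (injection experiments).

A `static_fraction` of molecules never exchanges; its state is drawn
from `static_weights` (default: the stationary law). Measurements of
this kind report 20–40% of molecules without detectable exchange on the
~10 ms diffusion timescale; the composition of that locked pool is not
observable from the histograms alone, hence a free weight vector rather
than an assumption.

### Occupancy-time law

The dynamic-PDA kernel is the law of `X = (time in state 0)/T` for a
two-state chain over a window `T`, at stationarity. Point masses are
`π0·exp(−k01 T)` at 1 and `π1·exp(−k10 T)` at 0. Conditioning on the
number of jumps and summing the resulting gamma convolutions gives the
continuous part in closed form,

    p(x)·dx = e^{−k01 t − k10 s} [ π0 ( √(k01 k10 t/s)·I1(z) + k01·I0(z) )
             + π1 ( √(k01 k10 s/t)·I1(z) + k10·I0(z) ) ] T dx,

with `t = xT`, `s = (1−x)T`, `z = 2√(k01 k10 t s)` and `I0, I1` modified
Bessel functions (evaluated in exponentially scaled form for stability
at large `rate·T`). The law is verified against exact Gillespie
sampling (Kolmogorov–Smirnov < 0.02 at 10^5 samples) for window/
relaxation ratios 0.1–10, and its total mass is checked to 1e−9 by
adaptive quadrature. Models with more than two exchanging states use a
vectorized Gillespie occupancy sampler instead (seeded, 10^4 samples per
evaluation by default).

## Synthetic data

The confocal generator emulates: top-hat molecule transits with
exponentially distributed durations (default mean 1.5 ms) separated by
exponential gaps (10 ms); Poisson photon emission at a per-state rate
(default reference brightness 8×10^4 detected counts/s); routing of each
photon to the acceptor channel with probability
`p = (Eγ + (1−E)α) / (Eγ + (1−E)(1+α))` — the exact forward map of the
burst corrections (γ applied at routing, α after routing); micro-times
drawn from the emitting species' exponential decay (donor `τ0(1−E)`,
acceptor 1 ns default) plus Gaussian IRF jitter, wrapped into the
excitation period; Poisson background per channel; a donor-only
molecule fraction at E = 0; and optional pulsed interleaved excitation
with the 31.25 ns period / 15.625 ns slot offset of two interleaved
32 MHz pulse trains, where dual-labelled molecules carry direct acceptor
photons in the second slot.

It does **not** emulate: a 3D-Gaussian focus (transits are top-hat, so
the diffusion shoulder of real FCS curves is only apparent),
triplet/blinking photophysics, acceptor photobleaching inside a burst,
detector dead time or afterpulsing, or EMCCD excess noise. Parameter
recovery on this generator therefore demonstrates the *estimators* are
correct and unbiased under known conditions; it does not certify
robustness to those instrument artifacts.

The TIRF generator produces frame-integrated two-channel traces: the
state trajectory is integrated over each 100 ms frame, donor/acceptor
means are anti-correlated by construction, acceptor and donor bleach
times are exponential with single-step transitions (donor returns to
the pre-bleach total after an acceptor bleach), camera noise is Poisson
× gain plus Gaussian read noise, and injection runs switch a responder
fraction of traces to a second kinetic model at the injection time.

The telegraph generator (one molecule held in focus) exists because FCS
and correlator validation need a stationary signal with an exactly known
correlation function; two-state dwells are drawn in vectorized
alternating blocks.

## Burst analysis

Burst search is the all-photon sliding-window criterion: a photon
qualifies if ≥ m photons fall within ±window/2 of it (defaults: window
500 µs, m = 15, ≥ 60 photons per burst). Runs are additionally split at
inter-photon gaps longer than the window, so that well-separated
transits remain distinct even in nearly background-free synthetic
streams — with realistic background the gap rule is inert because
background photons break the qualification run anyway.

Corrections per burst: background subtraction proportional to duration,
crosstalk removal `F_A = S_R − bg_R − α F_D`, then
`E = F_A/(F_A + γ F_D)`; PIE stoichiometry
`S = (F_D+F_A)/(F_D+F_A+F_RR)`. The fluorescence-weighted donor
lifetime is the micro-time moment estimator — for an amplitude mixture
it estimates `Σ a_i τ_i² / Σ a_i τ_i`, which is the quantity the
⟨τ_D(A)⟩_F axis is defined by — with the expected uniform background
contribution subtracted from the first moment (the mean of uniform
background micro-times is half the observation span and biases small
bursts noticeably). Per-burst maximum-likelihood IRF deconvolution was
rejected: at 30–100 donor photons per burst the moment estimator has
comparable variance and no convergence failures.

FRET lines: the static line is `E = 1 − τ/τ0` with an optional
polynomial linker correction (zero by default; calibrated coefficients
from reference measurements enter as configuration). The dynamic line
between species 1 and 2 is the two-component mixture moment identity
`E(⟨τ⟩_F) = 1 − τ1 τ2 / (τ0 (τ1 + τ2 − ⟨τ⟩_F))`, valid for ⟨τ⟩_F
between the two species lifetimes and meeting the static line at both
endpoints.

## Subensemble lifetime analysis

`ε_D(t)` is the donor decay of the FRET subensemble (bursts with
E > 0.065 by default) divided by a donor-only reference, normalized to 1
at t → 0 (weighted quadratic extrapolation of log ε over the first
quarter of the range). For discrete species it is
`Σ x_i exp(−k_i t)` with `k_i = (R0/R_i)^6/τ0`, fitted by weighted least
squares with free positive amplitudes (reported normalized — a free
scale makes the fit insensitive to the t → 0 normalization) and
multi-start over log-spaced distances.

Two numerical points matter in practice. First, the raw bin-by-bin
ratio is biased exactly where the slowest FRET component lives, because
the reference histogram runs out of counts at late times; by default the
reference is therefore fitted with a single exponential and the smooth
model used as denominator (`reference_mode="histogram"` restores the raw
ratio). Second, per-bin weights use box-smoothed counts rather than raw
`√n` — Neyman weighting on sparse tails systematically favours downward
fluctuations.

A single 10^6-photon dataset does not determine three free distances
when one species is far beyond `R0`: a Cramér–Rao analysis of the
45/60/90 Å, `R0 = 52 Å` configuration gives a ~21% standard deviation on
the 90 Å component regardless of the time range. The package therefore
provides `fit_species_decay_global`, sharing distances across a
titration series with per-condition fractions; with four conditions of
10^6 photons and population shifts typical of a Mg²⁺ titration the same
component is determined to ~3%. This mirrors how such data are actually
analyzed: distances global, fractions local.

## FCS

The multi-tau correlator bins photon times at 1 µs (configurable),
computes 16 lags at the base level and 8 per octave after each
factor-two coarsening, with symmetric normalization; `G → 1` at long
lags for stationary signals. Standard errors come from 10 contiguous
segments correlated independently. Its oracle is a brute-force
photon-pair counter over flat lag windows matching each level's
resolution — no binning cascade — and the two agree within the segment
errors on telegraph streams.

The fit model is
`G(t) = 1 + (1/N)·D(t)·(1 + Σ_i A_i exp(−t/t_Ri))` with the 3D-Gaussian
factor `D(t) = (1+t/t_diff)^{-1}(1+t/(p² t_diff))^{-1/2}` (axial ratio
p = 5 default) or `D = 1` for diffusion-free signals. The global fit
shares relaxation (and optionally diffusion) times across curves with
per-curve `N`, baseline and signed amplitudes; FRET exchange gives
positive kinetic amplitudes in GG/RR and a negative one in GR.
Filtered/species-weighted FCS is out of scope; plain channel
correlations carry the kinetic terms these analyses need.

## Dynamic PDA

The fit axis is the uncorrected proximity ratio `S_R/(S_G+S_R)`;
corrections live in the forward model, keeping the count statistics
exact. Conditioned on a window's total count n, a static species
contributes `Binomial(n, p_i)` at its corrected acceptor probability;
an exchanging component contributes the binomial at the
brightness-weighted time-averaged probability
`p(x) = f1(x) p_1 + (1−f1(x)) p_2`, `f1(x) = Q1 x/(Q1 x + Q2(1−x))`,
integrated over the occupancy law (201-node Gauss–Legendre plus the two
endpoint masses for two-state components; seeded Monte-Carlo occupancies
deposited on a fixed grid for larger components). Conditioning on the
total makes the binomial exact for Poisson emission, because conditioned
Poisson points are i.i.d. with the time-averaged routing law. The
empirical distribution of observed window totals (windows with ≥ 10
photons by default) is used as the count distribution, and the
prediction reuses cached binomial bin matrices on a fixed
601-point probability grid, so fit iterations cost milliseconds.

Observed histograms use the identical integer count-threshold bin
mapping as the prediction; binning `r/n` as floating-point puts
windows whose ratio falls exactly on a bin edge on inconsistent sides
and produces spurious few-percent discrepancies.

Windows are cut from each burst's start in non-overlapping multiples of
Δt, discarding the remainder; the default joint set is {1, 2, 3} ms,
chosen to bracket millisecond exchange (sub-ms sets bracket the fast
branch). Fitting minimizes Pearson χ² with adjacent bins pooled to ≥ 5
observed counts (pooling fixed by the observed histogram so the
objective stays smooth), via least squares on signed Pearson residuals
from a seeded Latin-hypercube multi-start (5 starts default, all starts
logged). Rates are fitted in log space within [1, 10^6] /s; branch
weights via stick-breaking; species efficiencies are held fixed unless
explicitly freed (they are determined by the MFD histograms and
subensemble lifetimes upstream). Model comparison refits each candidate
connectivity and ranks by global reduced χ²; uncertainty follows the
subsampling protocol (three refits on random 70% subsets).

## TIRF analysis

Selection applies the four curation criteria in order, reporting the
first failure: initial donor + β-corrected acceptor total > 600 counts
over baseline (mean of the first 10 frames); ≥ 5 s before the first
bleach (10 s for injection runs); single-step bleaching with donor
recovery to the pre-bleach total when the acceptor dies first (25%
relative tolerance); donor bleach within 120 s. Unannotated traces are
annotated by a cumulative-sum step finder (largest mean drop, accepted
above 5× the robust frame-noise s.d.). β defaults to 0.1 and γ to 1 as
per-dataset configuration.

Population analysis fits n Gaussians to the binned efficiency histogram
(bin width 0.02) by weighted least squares with quantile-spaced starts —
matching the usual presentation of such histograms with s.e.m. bars
rather than a mixture MLE. Cross-correlation uses the normalized
cross-covariance of mean-subtracted channels over pre-bleach frames,
pooled across traces; fits exclude lag 0 (shot-noise spike) and use one
or two exponentials with free sign. Per-trace amplitudes (for the
dynamic-trace fraction, threshold 3× the amplitude's standard error) are
the closed-form linear projection onto the pooled-fit exponential.
Injection analysis classifies responders by a pre/post mean-efficiency
shift (threshold 0.15 default, configurable — the underlying
published selection rule is not printed, so this is a stated choice,
not a claim) and fits the responder-averaged efficiency with a
single-exponential approach to the plateau.

## Accessible volumes and screening

AVs are computed on a Cartesian grid (1 Å default) around the
attachment point: clash exclusion against obstacle atoms (element vdW
radii, hydrogens ignored) inflated by the dye radius, and a geodesic
linker-length constraint. Geodesics are exact Euclidean distances for
points with a clash-free line of sight to the attachment, and Dijkstra
shortest paths on the 26-connected grid graph (seeded by the
line-of-sight nodes with their exact distances) for shadowed points —
the hybrid removes the few-percent metric anisotropy of pure grid
Dijkstra that would otherwise bias free-volume benchmarks. The ACV
variant multiplies the weight of points within a 3 Å contact shell of
the obstacle surface by a configurable factor (default 2 in screening
contexts; 1 = plain AV). Default linker geometry (length 20 Å, width
4.5 Å, dye radius 3.5 Å) is a placeholder calibrated per dye in real
use, not a claimed literature value; the single-radius dye model is the
default because three-radii parameters are dye-specific calibration.

The reported distance is `⟨R_DA⟩`, the weighted mean over position
pairs (exact double loop below 4×10^6 pairs, seeded weighted sampling
above), which is the FRET-relevant average; the distance between mean
positions is available as a diagnostic only. Screening computes
`χ² = Σ ((⟨R_model⟩ − R_meas)/ΔR)²` per structure and species, ranks
per species, flags `χ²/n ≤ 1`, and excludes (but reports) pairs missing
on a candidate.

## Workflow

One global seed fans out to per-stage seeds through SHA-256 of
`"{seed}:{stage}"` (mod 2³¹), so any stage is reproducible in
isolation. Outputs are TSV/JSON written once with fixed float formatting
(`%.17g`, which round-trips IEEE doubles; readers use round-trip float
parsing); identical config + seed reproduces every output byte for
byte. The report records per-stage parameters, key numbers, seeds and
file checksums; `validate_report` compares slash-path keys against
tolerance-tagged expectations.

## Problem sizes in the test suite

The acceptance-style tests run: PDA oracle comparisons at 10^5 windows
per regime; rate recovery at 2×10^4 windows per window duration (three
durations each for the 3.7 ms and 60 µs regimes); connectivity selection
at 5.1×10^4 windows; FRET-line placement at 3000 bursts; lifetime
fitting at 10^6 photons per condition over four conditions; FCS on a
20 s, ~10^6-photon telegraph record; TIRF batteries at 100–200 traces of
120 s; and the determinism check on a 300-burst end-to-end run. These
sizes were chosen to sit in the asymptotic regime of each estimator
while keeping a full run in a few minutes of one CPU.

## Known limitations

- The diffusion term fitted to simulated burst data is apparent, not
  physical (top-hat transits).
- Dynamic PDA assumes the window-total distribution is independent of
  the conformational state; exact only for equal species brightnesses
  (the default), a good approximation for modest brightness contrast.
- The analytic PDA path covers two-state components; larger connected
  components use seeded Monte-Carlo with its ~10^-3 histogram noise.
- Anisotropy is computed only when polarization-resolved channels are
  present, and is reported, not used downstream.
- `ε_D(t)` fitting supports optional fixed per-species Gaussian distance
  broadening (`sigma_r`), and the PDA model an apparent broadening
  `sigma_app`, but widths are never fitted: they are strongly
  anti-correlated with the distances at realistic counts.
- Photobleaching/blinking inside confocal bursts is not modelled; the
  simulator's donor-only fraction plus PIE-based rejection (or the
  E ≈ 0 PDA component for one-laser data) stands in for that artifact
  class.
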