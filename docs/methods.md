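# Methods

This note documents the models implemented in `damfretkit`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions used where the underlying procedures leave
choices open.

## The assay model

Each cell expresses the protein of interest over a hundred-fold or greater
concentration range (arbitrary units; the axis is uncalibrated beyond rough
micromolar anchors, so all rates are in arbitrary concentration units).
Per-cell concentration rises monotonically from zero to its final value c_T
over the induction time T (default 16 h). Nucleation is modeled as an
inhomogeneous Poisson process with rate k·c(t)ⁿ, so the probability that a
cell has nucleated by harvest is

    P(c_T) = 1 − exp(−k_eff · ∫₀ᵀ c(t)ⁿ dt),    k_eff = k · pin_factor,

and for the default linear ramp ∫₀ᵀ c(t)ⁿ dt = c_Tⁿ·T/(n+1). An exponential
ramp (c(t) = c_T·e^{−r(T−t)}, closed-form integral c_Tⁿ(1−e^{−rnT})/(rn)) is
available through configuration. `pin_factor ≥ 1` models the presence of a
pre-existing conformational template (a cross-seeding prion state); no
quantitative value for this enhancement is established, so it is an explicit
parameter with no privileged default beyond 1 (absent).

## The synthetic generator

`simulate_population` emits raw cytometer channels (forward/side scatter,
donor, acceptor, FRET, autofluorescence) for a population of cells:

* **Expression**: final concentrations log-uniform over 10⁰–10² AU by
  default (a log-normal option exists). The two-decade default is the
  assay's defining feature; narrower ranges make the fraction-positive curve
  uninformative.
* **Optics**: channel intensity = gain × concentration × side scatter (side
  scatter is the cell-volume surrogate, so the derived concentration proxy
  acceptor/SSC recovers c_T up to a gain factor). Scatter channels are
  log10-normal with means placed so that typical cells fall inside the
  standard gate coordinates after the logicle transform (T = 10⁷, M = 4.5).
  Spillover of donor and acceptor into the FRET channel (5% and 10%) gives
  the compensation step real work.
* **AmFRET read-out**: non-nucleated cells draw AmFRET ~ N(0, 0.05);
  nucleated cells sit at a class plateau (Q_B 0.6 > Q_U 0.4, reflecting the
  denser packing of lamellar assemblies) with sd 0.05. The negative sd of
  0.05 was chosen so the shifted negative gate (99th percentile + 0.028)
  falls below 25% of the Q_B plateau — i.e. the transitioning band is fully
  detectable above the gate while the control still scores ≤ 1% positive.
* **Transitioning cells**: a configured fraction (default 5%) of nucleated
  cells is assigned AmFRET uniform between 25% and 75% of the plateau,
  modeling incomplete growth. Inside the optional poisoning window
  [poisoning_c, escape_c] this probability increases by a logistic bump of
  depth `poisoning_depth` (default 1) and sharpness `poisoning_m`
  (default 4), producing the plateau-then-rise ("multiphasic") shape in the
  high-AmFRET fraction. The logistic window is a phenomenological
  convention, not a mechanistic polymer-physics model; fit reports flag it
  as such.
* **Artifacts**: 5% doublets (two cells' fluorescence summed,
  forward-scatter width × 1.6 — minimal, but sufficient for the singlet gate
  to act) and 5% non-expressing cells (baseline fluorescence only, removed
  by the expressing polygon).

All randomness flows from a single integer seed through one named
`numpy.random.Generator`; identical seeds reproduce event tables bit for
bit.

What the generator does **not** emulate: instrument drift, acquisition-time
effects, saturation/clipping of detectors, debris, autofluorescence
correlated with cell size, non-Gaussian AmFRET tails, or translation
inhibitor time courses (only `induction_time` is exposed). Passing tests
therefore demonstrate correctness of the analysis chain under the stated
statistical model, not robustness to every instrument pathology.

## Gating and transforms

The logicle (biexponential) scale uses T = 10⁷, M = 4.5, W = 0.5, A = 0 by
default: the transform is named but not parameterized in standard protocol
descriptions, and gate coordinates printed in the 1–5 range are consistent
with 4.5 display decades over a 10⁷ full scale. One parameter set is applied
to all transformed channels. The forward transform inverts the biexponential
by vectorized bisection (100 iterations; ~10⁻¹² relative), and the analytic
biexponential is the exact inverse.

Gate membership is closed (boundary points included) — deterministic and
consistent with common cytometry software. The three stages (cells on
FS00.A/SS02.A; singlets on FS00.H/FS00.W; expressing on FL03.A/FL17.A
polygon) preserve event order and are idempotent. FRET compensation is
one-directional (donor and acceptor out of the FRET channel) because no
pure-FRET control exists; coefficients are user-supplied or fitted from
single-color controls by least squares through the origin.

## The negative gate and fgate

Construction follows the binwise-percentile procedure exactly (64 log bins,
99th percentile, nearest-valid-bin filling, boxcar width 5, +0.028 shift,
lower gate −0.2), with these conventions where the procedure is silent:

* The binning range defaults to raw acceptor 10⁴–10⁸ — wide enough to
  bracket the 2×10⁶ validity floor with headroom on both sides. Binning is
  on raw acceptor intensity, because the floor is stated in intensity units.
* Quantiles interpolate linearly between order statistics.
* Bin validity is decided at the bin's geometric center; nearest-valid
  filling breaks ties toward the lower bin index.
* Boxcar smoothing shrinks its window symmetrically at the edges.
* Whether fgate should be computed over all expressing cells or only cells
  within the binned range is ambiguous; both are reported (`fgate` uses
  in-range events — and therefore satisfies the count-weighted-mean identity
  exactly — `fgate_all` uses all).

The transitioning ("intermediate") population is defined as events above the
binwise gate but below 0.75 × the positive-population plateau, the plateau
being the median AmFRET of positive cells in the top expression decile.
The 0.75 bound is a declared convention (the population is drawn graphically
in practice). When fewer than 1% of cells are positive the plateau, and
hence the intermediate fraction, is reported as undefined rather than zero:
gate false positives alone (expected at the 1% level by construction) must
not define a plateau.

## Kinetic fits

Reaction-order fitting maximizes the binomial likelihood of per-bin positive
counts under the cumulative-probability model, over (log k, log n), from
four starting orders with moment-matched rates; the confidence interval for
n is profile-likelihood based (χ²₁ threshold). Fitting the cumulative model
rather than slopes of log-log plots uses the known ramp integral and the
binomial error structure of the counts. Identifiability requires ≥ 5
non-empty bins and ≥ 3 strictly interior fractions; all-0/all-1 curves are
flagged unidentifiable.

Poisoning detection fits the monophasic model and a poisoned model (the
monophasic curve multiplied by 1 minus a fully-closing logistic window;
sharpness fixed at 4, window edges free, 4 parameters total) and selects by
AICc with the number of informative bins as the sample size and a selection
threshold of Δ = 2. The window sharpness is fixed because it is poorly
identified from 64-bin curves and trades off directly with window width.

Simulation studies in the test suite use 10⁴-cell populations and
100 seeds per scenario for model selection, and 5×10⁴ cells for parameter
recovery — sizes at which binomial noise per bin is a few percent and the
studies complete in minutes.

## Sequence rules

* `contiguity` returns (uni, bi): uni is the maximum over the two 1-based
  parity frames of the longest uninterrupted glutamine run within the frame;
  bi is the longest literal glutamine run. Reported run coordinates are
  1-based inclusive.
* De novo competence is the empirical threshold rule (uni ≥ 5 OR bi ≥ 6).
  The intramolecular nucleus layout search is reported alongside but not
  conjoined into the competence call by default: bilateral-contiguity
  variants with two-residue spacers (e.g. six Qs then two Ns, repeated)
  nucleate de novo yet fail the four-window layout search because their
  gaps are shorter than any allowed loop; conjoining would misclassify them.
* `nucleus_scan` looks for n_strands ordered, disjoint windows of
  strand_len residues, each with glutamine at every position of at least one
  parity of the window, separated by gaps ≥ loop_len (default 4), relaxed to
  3 when a gap consists only of glycine/proline/serine. The 4/3 pair
  reconciles the 36-residue polyQ threshold with the 33-residue tri-glycine
  design and is a declared convention. The search returns the
  lexicographically first feasible layout and agrees with exhaustive
  enumeration (tested exhaustively on short sequences with reduced
  parameters, since the defaults make anything under 33 residues trivially
  infeasible).
* `strand_span(q) = 2q − 1` is the minimal strand length spanning q
  alternating glutamines; whether the physical strand is 2q−1 or 2q residues
  is ambiguous by one flanking residue, and the lower bound is returned.
* Non-glutamine interrupting residues are treated identically by the rules.
  Residue identity does modulate nucleation frequency (serine mildest,
  glycine/asparagine most disruptive), but that modulation is a frequency
  effect outside the scope of a competence rule; CLI reports carry a caveat.
  A known limitation: a single Q→N substitution in one strand of the
  33-residue design abolishes amyloid although global bilateral contiguity
  is unchanged; capturing this requires a growth rule tied to specific faces
  of the nucleus layout, which is reported (layout windows) but not folded
  into the competence call.

## Imaging

The puncta classifier implements the dispersion statistic sd/√mean — named
`cv_sqrt_mean` because it is *not* the standard coefficient of variation — with
the threshold 30 that belongs to this definition; statistics are computed in
float64 on the sum projection. The ellipsoid volume uses the printed formula
(4/3)·π·major·minor² treating the fitted axes as full axes; a `semi_axes`
flag applies the /8-corrected geometry for users who want physical volumes
(all within-package comparisons are consistent either way). Rolling-ball
background subtraction uses the morphological rolling-ball implementation;
exact equivalence with any specific legacy implementation is not claimed.
Synthetic gels use a background gradient of 10% of the smear amplitude, at
which the rolling-ball residual biases recovered smear centers by well under
the 2-px acceptance used in tests.

## Problem sizes

Default test and acceptance runs use 10⁴–10⁵-cell populations, 64-bin
curves, 100-seed selection studies, and exhaustive sequence enumeration up
to length 9 over {Q, N, G} plus 10⁴ random sequences up to length 100 —
sizes chosen so binomial/enumeration coverage is meaningful while the whole
suite runs in well under an hour on one core.
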