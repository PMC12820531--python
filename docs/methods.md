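# Methods

`repstates` re-implements, as a tested pipeline on synthetic data with known
ground truth, the photon-level single-molecule FRET analysis used to resolve
and kinetically characterise the four conformational states (S1–S4: open,
two intermediates, closed) of the Rep helicase. This note records the models,
the numerical choices, and what the synthetic experiments do and do not
establish.

## The measurement being emulated

A doubly labelled protein (donor/acceptor dyes on the 1B and 2B subdomains)
diffuses through a confocal spot at ~pM concentration. Alternating-laser
excitation (ALEX) interleaves donor and acceptor excitation on a nominal
100 µs cycle (45 µs donor / 5 µs off / 45 µs acceptor / 5 µs off); photons
are time-stamped at 10 ns and classified into DD (donor-excitation,
donor-detection), DA (FRET-sensitised) and AA (acceptor-excitation) streams.
Transits appear as ~1 ms photon bursts at a median detected rate of
5.0×10⁴ s⁻¹ over a ~2 kHz background.

FRET efficiency and stoichiometry per burst use the accurate-correction
convention

    F_acc  = F_DA − l·F_DD − d·F_AA
    E      = F_acc / (γ·F_DD + F_acc)
    S      = (γ·F_DD + F_acc) / (γ·F_DD + F_acc + F_AA/β)

with leakage l, direct excitation d, detection factor γ and excitation
factor β.

## Synthetic-data generator (`photon_sim`)

The generator is a rate-gate model, not an optical one: a burst is an
exponential-length interval (mean 1 ms) of in-burst brightness, separated by
exponential background-only gaps (mean 50 ms, the ~50 pM occupancy regime).
No point-spread-function or 3-D diffusion path is simulated; burst-shape
effects (brightness ramps at transit edges) are therefore absent, which is
the main respect in which passing tests understate real-data difficulty.

Within a burst the conformational state follows Gillespie sampling of a
continuous-time rate matrix Q. Photons arrive as Poisson processes whose
channel split encodes the state's FRET efficiency *after inverting the
correction formulas above*, so a corrected analysis recovers the nominal
state efficiencies exactly in expectation and the correction round trip is
testable to tight tolerance. AA photons are generated at a state-independent
rate (stoichiometry is a labelling property, not a conformational one),
yielding corrected S = 0.5 for doubly-labelled transits. Donor-only and
acceptor-only species (labelling is far from complete in the real
experiment) are simulated as configurable fractions. Timestamp collisions
are resolved by shifting to the next free tick (warned above 0.1%).

### Fixture parameters

Published values used as-is:

* state centres E = (0.21, 0.54, 0.82, 0.98); condition weights
  11:23:47:18 % (low salt), 25:25:33:17 % (high salt); the 150 mM ±DNA S1/S2
  weights (18→14 %, 16→22 %); burst counts 1021/1013; median brightness
  5.0×10⁴ s⁻¹; ALEX timing; background-segment length 300 s; all filter
  thresholds (F = 6, m-photon window, 50-photon minima, S ∈ [0.2, 0.8],
  30 ms levels).
* the kinetics fixture's extreme states use the published photon-HMM values
  at 150 mM NaCl + DNA, 0.27 and 0.96.

Synthetic choices (the study does not print them numerically):

* Gaussian widths σ = (0.10, 0.10, 0.07, 0.02), interpolating the published
  0.02–0.18 range with the tight high-FRET peak the histograms show.
* 150 mM S3/S4 weights completed as (−DNA) 0.44/0.22 and (+DNA) 0.44/0.20,
  keeping S3 unchanged (its reported change is insignificant, P = 0.71).
* Interconversion rate matrices: nearest-neighbour chains S1⇄S2⇄S3⇄S4
  satisfying detailed balance with stationary distribution exactly equal to
  each condition's weight vector. The overall scale places mean dwells at
  ~6–10 ms (rates ~45–140 s⁻¹): inside the reported millisecond-to-second
  band, well below the ~2.5×10³ s⁻¹ resolvability ceiling, and long against
  the ~1 ms transit so that states are individually resolvable — a fixture
  whose dwells are shorter than a transit cannot serve as recoverable ground
  truth (state mixtures within bursts are then the *correct* maximum-
  likelihood description). These rates are declared synthetic throughout.
* Mixed-species default 75/15/10 % (doubly/donor-only/acceptor-only) for
  calibration pipelines; background rates (1000, 600, 600) c/s for
  (DD, DA, AA).

## Burst analysis (`burst_core`)

Background: per-stream maximum-likelihood exponential fit to interphoton
delays exceeding `min_delay` (default 10× the record's mean delay), per
300 s segment; memorylessness makes the truncated fit unbiased. On
burst-free records the default threshold retains ~e⁻¹⁰ of delays — pass an
explicit `min_delay` there.

Burst search marks a photon in-burst when any m-photon window containing it
has local rate m/Δt above F× the background rate (m = 10, F = 6); the
dual-channel variant intersects the donor-excitation and
acceptor-excitation masks and demands 50 photons in each, which retains
doubly-labelled transits. Per-burst background subtraction uses
rate × duration **plus one count shared across streams in proportion to
their rates**: a photon-delimited window of a Poisson process contains on
average one more count than rate × duration (inspection paradox), and
ignoring this measurably biases the correction factors derived from dim
calibration populations.

Correction-factor estimation follows the standard sequence: l from the
pooled raw E of donor-only bursts (S_raw > 0.9, guarded by an absolute AA
ceiling against doubly-labelled contaminants), d from the pooled raw S of
acceptor-only bursts, and (γ, β) from the linear relation
1/S = Ω + Σ·E across FRET populations, with β = Ω+Σ−1 and
γ = (Ω−1)/(Ω+Σ−1). Populations are identified by a BIC-selected 1-D
mixture over burst E, and each population's (E, 1/S) coordinate is computed
from its **summed** photon counts: per-burst regression is avoided because
E and 1/S share a shot-noise denominator, and the correlated noise tilts a
naive fit (observed: a slope of −0.22 fitted as +0.07). γ is
well-conditioned when calibrated on well-separated, internally static
populations; on a four-state dynamic mixture it carries a ±0.1 systematic,
which largely cancels in the round trip because the same factors are used
for correction.

Pooled sums in the calibration use unfloored background subtraction
(raw − expected, possibly negative); per-burst reported counts are floored
at zero.

## Mixture decomposition (`mixtures`)

Free fits and BIC selection (BIC = −2 logL + (3K−1) ln n) use scikit-learn's
GaussianMixture (tol 1e-8, reg_covar 1e-6, k-means++ restarts; a fit pinned
at the variance floor counts as degenerate and cannot be selected). E values
are truncated to [−0.2, 1.2] first. The constrained stage freezes the
pooled-fit centres and re-optimises per-condition σ and weights by a small
hand-written EM (σ floored at 5e-3). Goodness of fit (R², reduced χ²) is
evaluated against a 50-bin histogram on [0, 1].

The permutation test permutes condition labels over bursts, re-fits
frozen-centre mixtures, and uses |Δw_k| per state and the half total
variation Σ|Δw_k|/2 overall, with the add-one p-value estimator. The
overall statistic is a documented choice (the reference analysis names no
statistic); it is the natural magnitude of a weight-vector difference.

## Within-burst kinetics (`h2mm`)

The photon HMM treats the hidden state as a Markov chain on the 10 ns
clock with per-tick transition matrix A; between photons separated by dt
ticks the distribution propagates by A^dt, evaluated through the
eigendecomposition of A (real fast path; complex and jittered fallbacks for
non-real or near-defective spectra). The Baum–Welch E-step accumulates
*exact* expected tick-level transition counts across each gap using the
closed form Σ_t λ_a^t λ_b^(dt−1−t) = (λ_a^dt − λ_b^dt)/(λ_a − λ_b), so the
M-step is exact EM and the likelihood is non-decreasing (asserted in
tests). Forward/backward recursions are numba-compiled; forward and Viterbi
agree with exhaustive-path enumeration on small cases to 1e-9.

Observation alphabet: donor-excitation photons only (DD/DA). Feeding AA
photons with wall-clock gaps into an unconstrained photon HMM lets EM learn
a fast phase-tracking state locked to the deterministic 100 µs laser
alternation (observed: an E ≈ 0.5 state absorbing ~half of all photons);
the two-symbol alphabet removes the pathology. The AA/(DD+DA) ratio of the
analysed bursts is retained so stoichiometry-dependent corrections still
apply. The three-symbol alphabet remains available for continuous-
excitation data.

State efficiencies reported from a fitted model are corrected in two steps:
the in-burst background fraction of donor-excitation photons (computed from
the bursts' expected background counts) is inverted out of each state's
emission, then the accurate-FRET corrections are applied.

Model selection fits K = 1…n+1, where n is the last count whose relative
BIC improvement (BIC(K−1)−BIC(K))/|BIC(K−1)| stays ≥ 0.005; the selected
model is the ICL minimiser over the sweep (ICL = −2× the Viterbi
complete-data log likelihood + p ln n). The relative-BIC threshold fixes
the sweep extent and the ICL designates the optimum; the threshold-elbow
count is also reported and disagreement is warned about. On ground-truth
four-state streams at the study's photon budget the relative-BIC
improvement of the fourth state hovers at ~0.004 (the elbow rule would
under-select), while the ICL minimum lands on the true count — both
criteria are kept available.

Uncertainties are profile-likelihood intervals: one parameter (a state's
emission proximity ratio or a transition probability) is held fixed by
projection after each M-step while the rest re-optimise; the one-sigma
bounds are where the profile drops 0.5 below the optimum (bracketed search
+ Brent). Rates are k_ij = A_ij/dt (warning and matrix-logarithm generator
fallback above 0.01 per tick); occupancies are the stationary distribution
of A. The resolvability ceiling k_max = (count rate)/(photons per dwell)
is provided with the study's numbers (5.0×10⁴/20 = 2.5×10³ s⁻¹). Sparse
states below the open-structure FRET prediction minus 0.05 and under 10 %
occupancy can be pruned as acceptor-dark artefacts, with occupancies
renormalised.

## Trapped-molecule levels (`traplevels`)

Traces are binned at 1 ms (flag-exposed). Background bins come from
AIC-selected K-means over bin brightness, scored with the *soft* mixture
likelihood at the cluster parameters — a hard-assignment score always
rewards splitting noise; with a single cluster the trace mean is used
(warned). Changepoints come from recursive binary segmentation with a
Poisson generalised-likelihood-ratio statistic summed over the two
detection channels (df = 2), so pure FRET steps at constant total
brightness are detected; the per-split critical value is Bonferroni-
corrected over candidate positions at α = 0.05 and indistinguishable
neighbours are merged. Level FRET removes donor leakage and divides by the
emission-filter transmissions (0.71 donor / 0.55 acceptor); polarisation
channels are assumed collapsed with the G factor (default 1, not printed in
the study). Level lifetimes are single-exponential maximum-likelihood fits
of the micro-time histogram, convolved with the IRF on the periodic 16.7 ns
(60 MHz) window; boundary optima are flagged. Only levels longer than 30 ms
are reported.

## Ensemble decays (`decayfit`)

Reconvolution fits use weighted least squares with Poisson weights, a
fitted IRF shift bounded at ±0.5 ns, and the **bin-integrated** wrapped
exponential kernel: for excitation uniform within a bin, the probability of
an Exp(τ) delay landing i bins later is C·e^(−i·dt/τ) with a distinct i = 0
term — a centre-sampled exponential misplaces half the first bin's mass and
produces a visibly wrong fit. The amplitude-weighted mean
τ_av = Σαᵢτᵢ/Σαᵢ is the reporting convention (the intensity-weighted
variant is provided); ensemble FRET from spectra is E = A/(D+A) over the
550–650/650–800 nm band integrals.

## Accessible volumes (`avclouds`)

Dyes are modelled AV3-style: a grid (default 1.0 Å) around the attachment
atom, clearance to the nearest heavy-atom surface precomputed via a k-d
tree, linker reachability by Dijkstra flood fill (26-connectivity, metric
step costs, clearance ≥ width/2, path length ≤ linker length, seeded at the
attachment atom which is excluded from the obstacle set), and a dye
position allowed for radius r when its clearance ≥ r; the three radii pool
with equal weight. Rmp is the distance between weighted mean positions;
⟨E⟩ averages 1/(1+(r/R0)⁶) over seeded Monte-Carlo position pairs (10⁶ by
default). The grid metric overestimates Euclidean path lengths by up to
~8 % (documented in the oracle tests). Default dye/linker parameters
(linker 20.5 Å × 4.5 Å, radii 9.5/3.0/1.5 Å donor and 11.0/3.0/1.5 Å
acceptor, R0 = 70 Å) are placeholders standing in for the study's
supplementary values and are isolated in `DyeParams`; structure-based
predictions for the deposited helicase entry therefore require supplying
those parameters and the PDB file.

## Problem sizes

The default test suite and the acceptance script run entirely on synthetic
data: mixture fits at the published burst counts (~1000–2000 draws), burst
pipelines at 2500–4000 simulated transits (~600 analysed bursts,
~5×10⁴ donor-excitation photons for the kinetics fits), 20-level
changepoint traces, 10⁴–10⁵-photon decay histograms, and toy structures for
the accessible-volume oracles. These sizes were chosen so each stage's
estimator operates in the regime where its published counterpart reported
stable results.

## Known limitations

* No optical transit model; no brightness variation within bursts.
* γ/β calibration on a single dynamic multi-state sample is
  ill-conditioned (±0.1 systematic on γ); calibrate on static populations.
* The photon HMM assumes Markovian switching and state-independent
  brightness; acceptor blinking is only representable as an extra state.
* The changepoint and K-means parameters of the reference trap analysis
  are not printed; defaults here are documented choices.
* Structure-based FRET predictions depend on supplementary dye parameters
  not bundled with the package.
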