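# Methods

## Scope

`stiffkmc` simulates well-mixed mass-action reaction networks with the
Modified Next Reaction Method (Mod-NRM) and accelerates *stiff* simulations —
systems in which a few quasi-equilibrated reversible reactions consume nearly
all KMC steps — by reducing the rate constants of those fast reactions
on-the-fly, with quantified computational-cost and approximation-error models
deciding how far to reduce them.

## Simulation engine

Mod-NRM assigns each reaction channel j an internal clock: T_j is the
internal time consumed and P_j the internal time of the next firing;
P_j − T_j is unit-exponential.  A step fires the channel minimizing
Δ_j = (P_j − T_j)/a_j over channels with positive propensity a_j, advances
every clock by a_j·Δ, and replenishes P of the fired channel.  Exact ties in
Δ (a measure-zero event for continuous draws) break to the lowest channel
id, which keeps runs bit-reproducible.  A channel with a_j = 0 has Δ_j = ∞
and its clock frozen, which is exact for its later reactivation.  Pausing at
a window edge t_f advances all clocks by a_j·(t_f − t) and retains the
pending draws, so pause/resume does not perturb the process (verified
bit-exactly in the tests).

Randomness follows the random-time-change discipline used in
common-random-number (CRN) sensitivity studies: one independent stream per
*slow* channel, one shared stream for all *fast* channels.  Streams are
xoshiro256\*\* generators with explicit 4×64-bit state; child states derive
from the master seed via `numpy.random.SeedSequence(master_seed,
spawn_key=(channel_id,))` (the fast stream uses key 0).  Explicit state is
what makes snapshot/restore and CRN replication exact; `numpy`'s own
generators cannot be advanced per-step inside the compiled inner loop.  The
inner loop is `numba`-compiled and sustains roughly 10⁷ steps/s per core,
which is what makes the 10⁷–10⁸-step benchmark runs below routine.

A *snapshot* captures time, populations, rate constants, and the slow
channels' clocks and stream states — deliberately not the fast ones.
Restoring replays the slow reaction path exactly while fast channels re-draw
from the (never rewound) fast stream; replicate-to-replicate differences in
slow firing times are then attributable to the fast dynamics alone.

## Downscaling controller

Every N KMC steps the controller opens a window (t_s, t_f), width w ∈
[w_min, w_max].  The width stays at w_min unless a propensity forecast
predicts fewer than ~5 slow firings in total, in which case it grows in
steps of w_min/2 up to w_max; per-channel sufficiency is deliberately not
required, because channels that do not fire are simply excluded from the
error fit by the common-length truncation (see below).

Gates on the reference (unscaled) chunk:

* **Quasi-equilibrium**: each downscalable forward/reverse pair must satisfy
  |N_f − N_r|/(N_f + N_r) ≤ δ (δ = 0.05); an unsampled pair fails.
* **Ordering**: every declared-fast channel must have fired strictly more
  frequently than every declared-slow channel.
* **Separation**: TSS = log₁₀(min fast frequency / max slow frequency) must
  be at least TSS_min (2 by default).  No slow firings at all yields
  TSS = +∞, flagged as insufficient sampling and aborted.

If the gates pass, n replicates are generated from the snapshot, replicate k
with the *current* downscalable constants divided by df_b^(k−1) (k = 1 keeps
them unchanged and provides the error baseline).

**Cost.**  Each replicate's step count, divided by the reference chunk's
and by the current cumulative factor, gives its cost on an absolute scale
where 1 is a window simulated at the *original* rate constants.  This
anchoring is what lets later attempts remember earlier speed gains: at
cumulative factor 40 the marginal gain of further reduction is ~1/1600 per
unit df, so the error term halts the optimizer early, whereas per-attempt
re-normalization would erase that memory and push every attempt toward its
df_max.  The valid range of the 1/df cost law is bounded by two detectors on
the (log₁₀ df, log₁₀ c) points: sliding 4-point least-squares fits (first
window with slope > −0.9 flags its second-to-last point) and central second
differences taken with respect to the natural-log df coordinate (first
point exceeding 0.05 in magnitude flags its predecessor).  The curvature
convention matters: a true per-decade² second derivative trips on the gentle
bend that the slow-step floor imposes on *any* stiff window long before the
law meaningfully breaks, cutting df_max an order of magnitude too early;
the natural-log normalization is the calibration under which both detectors
flag just where the benchmark's cost curves visibly leave the −1 line.
df_max is the smaller flag; points beyond it are discarded, and a line is
fitted to the rest.

**Error.**  For each slow channel the firing times of the reference chunk
and of each replicate are converted to interarrival times (the first one
measured from t_s), truncated to their common length, and the Euclidean norm
of the difference vector taken.  The norm has units of KMC minutes.  A
channel with no firings in either list is excluded and logged.  One
aggregated power law E(df) = p·df^q is fitted over all channels' points with
df ≤ df_max; per-channel exponents q_j are also fitted, and any q_j < 0.2
aborts the attempt as *saturated* — the error no longer grows with df, which
indicates the window cannot resolve the additional distortion.  Saturation
typically happens when the baseline jitter (the k = 1 norm, caused purely by
fast-stream re-randomization) dominates the small-factor norms; it aborts
roughly one benchmark attempt in six, and the run simply tries again at a
later window.

**Decision.**  df_opt = argmin over [df_current, df_max] of
F(df) = α·C(df) + β·E(df), located by a 2000-point log-grid scan plus
bounded scalar refinement (the optimum need not be a power of df_b).  The
candidate is accepted only if E(df_opt) ≤ e_max (0.05) and E(df_opt) is at
most e_inc (2) orders above the k = 1 baseline (mean of per-channel norms).
On acceptance the window is regenerated once more from the snapshot at
df_opt and registered as the official trajectory, and the reduction becomes
permanent; on any abort the reference chunk is registered, so a failed
attempt costs one extra window at most and never corrupts the trajectory.
With fixed seed and configuration the entire attempt ledger is reproducible
run-to-run.

## Benchmark oscillator

The built-in benchmark is a six-species, nine-reaction cell-cycle-like
oscillator.  Protein X is produced from an operator O at a basal rate k₀ and
from the dimer-bound operator OX₂ at the much larger rate k₁; X dimerizes
reversibly (2X ⇌ X₂, association χ, dissociation χ·b) and the dimer binds
the operator reversibly (O + X₂ ⇌ OX₂, association φ, dissociation φ·a),
closing the positive feedback.  The negative feedback runs through a
regulator present as inactive Yᵢ and active Y: the dimer activates it
(X₂ + Yᵢ → X₂ + Y, k₂), active Y degrades X catalytically (X + Y → Y, λ₁)
and relaxes back (Y → Yᵢ, λ₂).  Two conservation laws follow: O + OX₂ =
O_total and Y + Yᵢ = Y_total.  Parameters (k₀ = 0.15 min⁻¹, k₁ = 50 min⁻¹,
k₂ = 1.88·10⁻³, λ₁ = 9.38·10⁻³ nM⁻¹min⁻¹, λ₂ = 0.01 min⁻¹, a = 159.37 nM,
b = 5.31 nM, O_total = 10, Y_total = 1035) are fixed; the stiffness control
ζ scales only the fast association constants, φ = 9.77·ζ and χ = 3.91·ζ
nM⁻¹min⁻¹, so channels 3–6 are the fast, downscalable set (pairs 3↔4 and
5↔6), controlled by χ and φ alone — downscaling divides forward and reverse
constants alike and therefore preserves both equilibrium constants.

The simulation works in copy numbers with an explicit molecules-per-nM
conversion factor, default 1.0, recorded in every network config.
Dimerization is parameterized so that the macroscopic dimer-formation rate
is χ·x² (stored stochastic constant 2χ with the n(n−1)/2 identical-pair
propensity).  Under these conventions a ζ=10, 500-KMC-minute run reproduces
the benchmark's published stiffness profile: ~2·10⁷ steps in total with
~99.7 % executed by channels 3–6, a fast-over-slow frequency margin of ~2.1
orders of magnitude, and relaxation oscillations of species Y with an
inter-burst interval of 200 ± 26 min.  The initial state (all operator
bound, all regulator inactive) launches a burst at t = 0; bursts last
~40 min and recur every ~200 min, the off-phase clock being the Y
deactivation timescale 1/λ₂ = 100 min.

Two reconstruction residuals are worth knowing.  First, the first ON burst
is somewhat milder here than in the published characterization (~6·10⁶
versus ~8·10⁶ steps by t = 40), although the full-run totals agree.  Second,
the within-burst ratio of total fast to total slow step rates is ~350–400 at
ζ=10, which bounds the cost law's validity (df_max ≈ 25) and therefore the
factor the controller will accept there; configurations with larger ζ do not
hit this bound.  Where published values depend on these in-window details,
the package reproduces the mechanism and the surrounding quantities but can
differ on the specific accepted factor at ζ=10.

## Spectral analysis

Trajectories are sampled on a uniform grid (default 0.1 min) with zero-order
hold, exact for piecewise-constant KMC paths.  The spectral estimator
mean-removes the series, computes the biased autocorrelation (division by
the full length, which keeps the spectrum nonnegative-definite and tapers
large lags) up to half the series length, zero-pads it eightfold, and
applies a type-I discrete cosine transform.  Padding interpolates the
spectrum so that peak locations are not quantized to the coarse grid — on
500-minute runs the raw grid only offers periods {500, 250, 167, …}, while
the padded estimate localizes near the 200-minute inter-burst interval
measured independently from burst onsets.  The information bandwidth
1/(2·max_lag·dt) is reported alongside and is the honest "one bin" for
frequency comparisons.  One caveat applies to run-to-run comparisons of a
noisy oscillator: the dominant-peak location itself scatters between
independent realizations (the oscillator's mean period is a fluctuating
quantity), and at practical run lengths this scatter exceeds the
information bandwidth; the comparison report therefore carries the
frequency ratio and the per-species distribution distances as the primary
agreement indicators alongside the strict one-bin flag.  Species
distributions are compared as empirical probability mass functions under
total-variation distance.

## Problem sizes

The test and acceptance runs use: three 500-minute ζ=10 characterization
runs; one first-attempt study at ζ=100 (window (1.503, 10.503), ~5·10⁷
steps including replicates); a ζ=1000 run to t = 45 with windows of width 5;
and original-versus-downscaled validation runs of 10⁵ KMC minutes at ζ=10.
These reproduce the published study design at the original parameter values,
with the validation run length reduced from 5·10⁶ to 10⁵ KMC minutes — still
~500 oscillation cycles, ample for the spectral and distributional
comparisons made on it.

## Known limitations

* Fast/slow classification is user-provided; no automatic partitioning.
* Only mass-action propensities (zeroth, unimolecular, bimolecular); no
  Hill/Michaelis–Menten forms, delays, or time-varying constants.
* Downscaling applies to declared reversible pairs only; rate constants are
  never scaled back up.
* The cost/error models are power laws fitted within one window; windows
  with saturated error abort rather than extrapolate.
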