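# Methods

This note records what each stage of the pipeline computes, the model
behind the synthetic data, the parameter values with their rationale, and
the limits of what the validation suite demonstrates.

## Preprocessing

Recordings are expected as multichannel sample matrices (tab-separated
ASCII with a channel-label header, or EDF via MNE) at a nominal 512 Hz.
The default montage is the 21-electrode international 10-20 set (Fp1, Fp2,
F8, F4, Fz, F3, F7, A2, T8, C4, Cz, C3, T7, A1, P8, P4, Pz, P3, P7, O1,
O2); Fp1, Fp2, A1 and A2 are excluded by default as artifact-prone, which
leaves the 17 network nodes. Retained channels are re-referenced to the
common average; after this step the per-sample channel mean is zero by
construction. A montage channel missing from a record is a hard error
naming the channel — silent channel substitution is never acceptable in a
paired design.

Epochs are fixed-length contiguous windows cut from the start of the
recording, by default four windows of 4096 samples. At 512 Hz that is
8.0 s per epoch; documentation in this clinical literature sometimes
quotes 8.19 s for a 4096-sample epoch (an effective 500 Hz rate), so the
sample count is treated as authoritative and the duration as derived.
Epoch extraction copies samples bit-exactly; no resampling is performed.

Band-pass filtering is a 4th-order Butterworth applied forward and
backward (`sosfiltfilt`), i.e. an 8th-order zero-phase magnitude response.
Zero phase is not cosmetic here: any phase distortion would bias a
connectivity measure built entirely from phase differences. Band edges
are delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz; the relative-power
analysis splits alpha into 8–10 and 10–13 Hz.

## Phase Lag Index

Instantaneous phase is the complex argument of the Hilbert analytic
signal. The analytic signal is unreliable near record edges, so a number
of samples at each end is excluded from all phase averaging: 10% of the
epoch per end, capped at one period of the band's lowest frequency
(`ceil(fs / low)`). For an 8 s alpha-band epoch the cap (64 samples)
binds; for a delta-band epoch the 10% rule binds.

The PLI of two phase series is `|mean(sign(wrap(a - b)))|` over retained
samples, with the difference wrapped to (−π, π] and `sign(0) = 0`, so
exactly-zero phase differences (the signature of volume conduction)
contribute nothing. PLI is computed per electrode pair per epoch and
arithmetically averaged over epochs. The estimator is symmetric in its
arguments, invariant to a common phase offset and to signal amplitude;
these are tested as properties.

Relative band power uses Welch periodograms (segment length
`min(n_samples, 4·fs)`) per channel and epoch; band power is the sum of
PSD bins in `[low, high)` (half-open, so adjacent bands are disjoint)
divided by power in the 0.5–30 Hz total band, then averaged over channels
and epochs. The denominator band is configurable because conventions
differ; 0.5–30 Hz (the union of the analysis bands) is the default.

## Weighted network measures and surrogate normalization

The weighted clustering coefficient of node i is the triangle-weight
ratio `Σ w_ik w_il w_kl / Σ w_ik w_il` over ordered pairs k ≠ l with
i, k, l distinct. The implementation collapses the triple sum to
`diag(W³)` over `(Σ_k w_ik)² − Σ_k w_ik²`, which is exact for a zero
diagonal; tests compare it against a literal brute-force triple sum.
Ordered-pair summation double-counts numerator and denominator alike, so
the ratio equals the unordered version; for 0/1 weights it reduces to the
unweighted clustering coefficient. Nodes with fewer than two weighted
neighbours get C_i = 0.

Path length uses reciprocal weights as edge lengths (strong coupling =
short functional distance), with zero weights treated as absent edges, and
Dijkstra shortest paths (scipy's csgraph); L_i is the mean distance to the
other N − 1 nodes. A disconnected graph is a hard error naming the
components: infinite means are scientifically meaningless, and full PLI
matrices are in practice strictly positive.

Surrogate networks randomly permute the upper-triangle off-diagonal
weights and mirror them — the weight multiset is preserved while the
topology is destroyed. Fifty surrogates per network are used for
normalization (normalized C = C/⟨C_surr⟩, normalized L = L/⟨L_surr⟩); at
17 nodes the batch-to-batch coefficient of variation of the ensemble
means is well below 1% (measured at ≈0.15%, recomputed by
`scripts/acceptance.py`). Permutations that happen to disconnect the
graph (possible only when zero weights exist) are resampled, with a retry
cap of 100.

## Spanning tree

The tree is built by Kruskal's algorithm over edges in *descending*
weight order — a maximum spanning tree of PLI, equivalently the minimum
spanning tree of reciprocal weights (tested as an internal equivalence).
Equal-weight ties are broken by lexicographic label pair, so degenerate
synthetic inputs yield reproducible trees. The tree depends only on the
weight ordering, hence is invariant under monotone weight transforms.

Leaf number counts degree-1 nodes; the diameter is the hop-count longest
shortest path, found by a double breadth-first sweep (exact on trees).
Hops rather than summed reciprocal weights are used because the bound
`diameter ≤ m − leaf + 2` holds only for hop counts. Both measures are
normalized by m = N − 1; other normalizations (e.g. `(leaf − 2)/(m − 2)`)
rescale but never change the sign of any group contrast.

## Statistics

Within-group condition effects use the classical paired t-test
(`t = mean(d)/(sd(d)/√n)`, d = sleep-deprived − routine, two-sided,
df = n − 1). Identically zero differences return t = 0, p = 1; a constant
nonzero difference has an undefined statistic and is an error.

The condition × group interaction is computed through the exact 2×2
repeated-measures identity: the interaction F equals the square of the
pooled two-sample t comparing per-subject difference scores between
groups, with df = (1, n₁ + n₂ − 2). This is algebraically identical to a
general mixed-model fit for this design (verified in tests against
pingouin's `mixed_anova` to floating-point precision) while being exact,
dependency-light and self-checking. Every subject must contribute both
conditions; anything else is an error naming the subject.

FDR correction is Benjamini–Hochberg step-up at q = 0.05, applied
independently within each frequency band; the family is the set of
measures of one report table in that band (four network/MST measures, or
the five power bands as one family). The per-band family reflects the
view that frequency bands index distinct functional networks; per-measure
across-band families are the main alternative and would give a different
(usually stricter) correction for single-band effects.

The interaction table is produced twice: for the full cohort, and for the
subset analysis that keeps only patients whose sleep-deprivation
recording carried added clinical value while retaining *all* controls.

## Synthetic data model

Each channel i is `cos(φ_i(t))` plus additive white Gaussian noise (the
noise is broadband on purpose — it exercises the filter + Hilbert chain).
The intrinsic phase is a carrier at the band-centre frequency plus a
stationary Ornstein–Uhlenbeck jitter (sd 1.2 rad, correlation time
0.3 s, linewidth ≈ sd²/τ < 1 Hz, i.e. narrowband within any analysis
band). A mean-reverting jitter rather than a pure random-walk is
essential: the time-averaged sign of a random-walk difference obeys the
arcsine law and does not converge to zero, whereas an ergodic jitter
guarantees that the PLI of uncoupled channels decays toward zero as
epochs lengthen.

Coupling is intermittent entrainment. Time is divided into 0.25 s blocks;
in each block, channel i adopts the phase of a coupled lower-index
channel j (plus the imposed lag, drivers chosen with probability equal to
the coupling strength) and keeps its own intrinsic phase otherwise. The
entrained phase is the driver's *final* phase, so chains propagate phase
hop by hop with accumulating lag. Consequences that the tests rely on:

- PLI of a directly coupled pair ≈ its coupling strength (locked blocks
  contribute sign consistency c, unlocked blocks ≈ 0), and is monotone in
  it;
- with the default lag of π/2, a two-hop pair's locked offset is π, where
  the wrapped sign is symmetric, so indirect pairs are systematically
  weaker than backbone edges and the maximum spanning tree of the
  estimated PLI matrix recovers the programmed backbone;
- full coupling with zero noise drives the estimator to its upper bound.

A small always-on per-channel OU jitter (sd 0.15 rad, τ 0.05 s) keeps
entrained offsets from being numerically exact, so sign statistics behave
continuously even for noiseless specs.

Cohorts assign each subject a coupling backbone
`α·chain + (1 − α)·star` (backbone strength 0.85, 17 channels,
alpha-band carrier, noise sd 0.3). Baseline α is 0.5 with per-subject
normal jitter (sd 0.08); sleep deprivation shifts α by +0.35 in patients
(toward the chain/path) and −0.35 in controls (toward the star), again
with subject-level jitter. Cohort defaults are the study design: 21
patients, 17 controls, four 4096-sample epochs at 512 Hz per recording,
15/21 patients flagged added-value. The shift magnitudes are free
parameters — no quantitative effect size is available to calibrate them —
so power obtained on synthetic cohorts characterizes the pipeline, not
any clinical population. One global seed fans out to per-subject
substreams (`numpy.random.SeedSequence`), making cohorts reproducible
while keeping subjects independent.

What the generator does **not** emulate: epileptiform transients, sleep
staging and drowsiness, volume conduction (zero-lag mixing), 1/f
background spectra, electrode artifacts, or inter-channel amplitude
covariance. Passing tests therefore demonstrate correctness of the
estimators and the recovery of programmed phase-lag structure — not
robustness to every property of clinical EEG.

## Problem sizes and numerical choices

The test suite validates oracle equivalences on small graphs (exhaustive
spanning-tree enumeration up to 7 nodes, brute-force clustering up to 8),
runs one full-scale synthetic cohort (38 subjects × 2 conditions,
alpha band) for parameter recovery, and uses 500–1000 label permutations
for null calibration; the bundled demo cohort uses shortened recordings
(two 1024-sample epochs) to stay small. Determinism is enforced
throughout: fixed seeds, seed-derived per-recording surrogate streams,
lexicographic tie-breaking, and provenance headers (package version,
config hash, seed) on every output file.

Known numerical edge cases: constant signals have undefined phase
(error); zero-variance paired differences are an error unless identically
zero; a surrogate mean of zero cannot normalize (error); disconnected
inputs are errors everywhere rather than silently patched, because the
clinical pipeline guarantees full matrices.
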