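# Methods

`forktrace` analyses DNA replication at the single-molecule level from
nanopore reads of cells pulse-labelled with two thymidine analogues. The
input is a per-read, per-thymidine probability track: for every thymidine
position on a mapped read, the probability that the base is EdU and the
probability that it is BrdU, as produced by an upstream analogue-detection
model. Under the standard protocol — a 5-minute EdU pulse, a 10-minute
BrdU pulse, then a thymidine chase — each active replication fork leaves
an ordered two-colour footprint: an EdU track laid first, then a BrdU
track in the direction of travel. Everything downstream (fork direction,
speed, stalling, stress signatures, S-phase trends, treatment effects)
derives from the geometry and call statistics of these footprints.

All coordinates are 0-based, half-open, in reference space. Reads shorter
than 20 kb of mapped length are not used for calling.

## Segmentation and fork calling

A call at a thymidine is *positive* when its probability strictly exceeds
0.5. Candidate segments are maximal runs of non-overlapping 1-kb genomic
windows in which the positive-call fraction for one analogue is at least
0.3, exceeds the other analogue's fraction, and the window holds at least
5 thymidines (windows are genomic rather than thymidine-counted, so a
floor guards AT-poor windows). Runs shorter than 1 kb are discarded.

Each candidate is then trimmed: the mean incorporation f\* is measured
over the middle third of the segment, and a 1-kb window is advanced
inward from each end — anchored at successive thymidine positions — until
it first meets f\*. If the very first window already meets f\*, the
boundary is left where candidate detection put it. Per-thymidine
anchoring makes noise-free boundary recovery essentially exact (a few bp),
which is what the parameter-recovery tests measure. Trimming only
shrinks a segment and is idempotent on plateau-shaped tracks.

Segments are paired into forks along the read: EdU-then-BrdU in reference
order is a rightward fork, BrdU-then-EdU leftward. Pairing maximises the
number of forks and then minimises the total pairing gap (a dynamic
programme over the ordered segment sequence), tolerating a gap of up to
5 kb between partners, since analogue detection tends to leave a small
gap between the two tracks. A segment tightly flanked (within one window)
by the opposite analogue on both sides is a merged junction — two
converging forks share one continuous BrdU region, two forks diverging
from an origin that fired during the EdU pulse share one EdU region — and
is split at its midpoint, which is exact when the two forks move at equal
speeds and is otherwise a bounded approximation. Adjacent diverging EdU
segments yield an origin call (the interval between the inner EdU ends, a
point when they touch); adjacent converging BrdU segments yield a
termination. Forks on such reads carry flags used by the exclusion rules
below.

The fork *track* spans from the far end of the EdU segment to the far end
of the BrdU segment.

## Fork speed

Speed = track length (kb) / 15 min (total pulse). Forks are excluded — a
tagged outcome, not an error — when they sit on a read with a called
origin or termination, or start/end within 3 kb of a read end; in those
cases the footprint is truncated and the speed would be biased low.

## Stall score

B is the fraction of thymidines called BrdU-positive in the 2-kb window
just inside the BrdU end of the fork track (track end for a rightward
fork, track start for a leftward fork — the trimmed end anchors the
window); A is the same fraction in the 2-kb window just outside. The raw
score R = (B − A)/B is scaled to

    score = α·log(1 + e^{β(R−1)}) − α·log(1 + e^{−β}),

clamped below at 0. The scaling is exactly 0 at R = 0, monotone, and maps
R = 1 to just under 1. Two parameter presets are carried: v3 (α = 1.55,
β = 3) and v4 (α = 2.63, β = 1), matching the two published detection-model
generations; the v4 rescaling keeps scores comparable across the cleaner
calls of the newer model. A score is declined (with a reason) when the
outside window runs off the read, the fork is in a termination, an
insertion/deletion longer than 100 bp lies in either window, B = 0, or a
window holds fewer than 10 thymidines (the thymidine floor is ours: the
2-kb windows are genomic and a handful of thymidines would make B and A
degenerate fractions). Negative R (A > B) is allowed into the scaler and
clamps to 0. If a track carries no indel annotations at all, the indel
rule is disabled with a log message rather than silently passed.

## Replication-stress signatures

Eight features per fork: total track length, EdU track length, BrdU track
length, the four positive-call fractions (BrdU-in-EdU-segment,
EdU-in-EdU, EdU-in-BrdU, BrdU-in-BrdU), and the stall score. Forks with a
declined stall score are skipped. Features are rescaled per column to
(x − median)/IQR (a zero-IQR column is zeroed with a warning), then
embedded in 2-d with UMAP using 25 nearest neighbours, min_dist 0, and
the Chebyshev metric; 125 forks per sequencing run are subsampled
(seeded, reproducible) before embedding. K-means with K = 5 runs on the
embedded points by default (running in feature space is an option — the
choice is genuinely open since centroids are displayed on the embedding);
a cluster-by-condition confusion table and purity summarise separation.
Gaussian KDE with default bandwidth provides the density view. A
"no-speed" mode drops the three length features, leaving the
5-dimensional incorporation/stall space.

Note a geometric consequence of IQR rescaling under the Chebyshev metric:
features that are pure noise still spread O(1) after rescaling, so
conditions that differ in a minority of features separate only partially.
The tests assert contrasts (separable vs chance) rather than absolute
purity for such constructions.

## Replication timing (Trep) and S-phase trends

Multi-fraction replication-timing profiles are given per 50-kb bin with
one signal value per S-phase hour. The cumulative signal, normalised to
[0, 1], is fitted by least squares with a logistic
S(t) = 1/(1 + e^{−k(t−Trep)}); Trep is the half-replication time. Fits
failing to converge, with k ≤ 0, with Trep far outside the sampled hours,
or with RMS residual above 0.15 mark the bin missing. The fit is
invariant to uniform rescaling of the raw signal. Each fork takes the
Trep of the bin containing its track midpoint (the least biased single
point for a 15-minute footprint); midpoints exactly on a boundary go to
the right-hand half-open bin; forks in missing bins are dropped with a
log message.

Trends over S-phase: forks are grouped by floor(Trep) hours; hours with
fewer than 5 forks are dropped and at least 3 hours are required. The
per-hour medians are regressed on the hour by ordinary least squares;
Pearson R is reported on the medians and the p-value is one-sided
(slope > 0 expected for speed, slope < 0 for stall score). Exchanging the
alternative maps p to 1 − p.

## Treatment effects (hierarchical Bayes, ROPE)

Speed: forks ~ Normal(θ_rep, σ); replicate means θ_rep ~ Normal(μ_group, τ);
priors μ_untreated ~ N(1.5, 0.5), μ_treated ~ N(0.7, 0.5) (kb/min), and
HalfNormal(0.5) on both σ and τ.

Stall score: scores ~ Beta(μ_rep·φ, (1−μ_rep)·φ) with precision
φ ~ Gamma(2, rate 0.1) shared across all replicates and both groups (a
per-group option exists — the sharing scope is ambiguous in principle and
shared-everywhere is the simpler model); group means carry Beta(2, 5)
priors. How replicate means derive from the group mean is an open design
point for a Beta hierarchy; here θ_rep ~ Beta(μ_g·κ, (1−μ_g)·κ) with
κ ~ HalfNormal(10), surfaced in the priors config. Scores of exactly 0
or 1 are nudged inward by 10⁻⁴ to keep the likelihood finite.

Posterior sampling uses an affine-invariant ensemble MCMC sampler (emcee)
with differential-evolution moves over an unconstrained parameterisation
(log scales, logit means) with analytic log-densities. Sufficient
statistics (per-replicate n, mean, centred sum of squares; or n, Σlog x,
Σlog(1−x)) make each log-posterior evaluation O(#replicates), so a fit
takes a few seconds. Defaults: 32 walkers, 1000 tuning steps discarded,
4000 retained steps thinned to ≥2000 draws. Convergence is reported as
split-R̂ across four walker groups with a 1.01 threshold; a
non-converged fit still returns, flagged.

Reported quantities: Δ1 = treated − untreated group mean; Δ2 (Δ3) =
absolute difference of the untreated (treated) replicate means — computed
as max − min per draw, which for the usual two replicates is exactly the
absolute difference and is invariant to replicate relabelling; adjusted
effect = Δ1 − Δ2 (Δ3 is reported but plays no role in significance). An
effect is significant when at least 95% (boundary inclusive) of the Δ1
posterior lies outside the region of practical equivalence, ±0.1 kb/min
for speed and ±0.05 for stall score.

## The simulator

The simulator is first-class code and defines the conditions every other
module is tested under. On a 5-Mb synthetic genome (60% AT, thymidines
i.i.d. at density AT/2 per base), origins are placed at 4 per Mb and fire
between 45 minutes before the EdU pulse and the end of the EdU pulse;
each origin launches a leftward and rightward fork with speed drawn from
Normal(1.4, 0.3) kb/min (floored at 0.1). Label intervals follow each
fork's trajectory intersected with the pulse windows. A stalling fork
(per-fork probability, default 0) stops instantly at a time drawn
uniformly within the BrdU pulse; pause-and-resume is not modelled.
Converging forks from adjacent origins are truncated at their meeting
point (found by bisection on the piecewise-linear trajectories) and
recorded as a termination; full whole-genome kinetics (passive
replication, re-firing) are not modelled. A fork that runs through the
whole pulse keeps incorporating BrdU at linearly declining levels for 3
minutes of chase (the analogue pool dilutes gradually), which is what
gives healthy forks their characteristic raw stall scores around 0.2–0.4
and distinguishes them from the abrupt stop of a genuine stall.

Reads (default 50) are lognormal with N50 90 kb (floor 20 kb), placed
uniformly. Emission is per-thymidine independent: labelled positions draw
their analogue probability from Beta(8, 2) (P(call) ≈ 0.83), unlabelled
from Beta(2, 8) (false-call rate ≈ 0.02); `noise_free` substitutes exact
1/0. Emission carries no sequence context, basecalling error, or
strand asymmetry — so passing tests demonstrate the correctness of the
segmentation/scoring logic on well-specified footprints, not robustness
to the full noise structure of real nanopore data.

Ground truth records every fork's intervals, direction, speed, stall and
termination status. `truth_compare` matches calls to truth per read
(direction agreement, both track boundaries within tolerance) and reports
precision, recall, and mean boundary error. Forks whose boundaries are
not independently recoverable on a read are excluded symmetrically from
both sides: calls flagged near-read-end or origin/termination members
(their inner boundary is a split estimate), truth forks that terminated
or whose footprints abut a neighbour's visible on the same read, and a
buffer zone between "must be recovered" (interior by ≥1.5 kb with both
segments ≥1.5 kb) and "may legitimately be called" (anything fully on the
read) avoids counting borderline edge cases either way.

## Problem sizes used in tests

The test suite and the acceptance script run simulations of 60–300 reads
on the 5-Mb genome (tens of recoverable forks per run), 20-seed
repetitions for the Bayesian recovery/null checks at 200 forks × 2
replicates per group, and 200 null replicates for the trend-test
calibration. These sizes give the binomial/posterior checks their stated
resolution while keeping a full run of the suite within a few minutes.

## Known limitations

* Candidate detection and trim granularity are declared parameters; the
  reference single-molecule caller does not publish its internals, so
  agreement is at the level of the documented behaviour, not the binary.
* Midpoint splitting of merged junction segments is exact only for
  equal-speed fork pairs.
* The Beta-hierarchy replicate-level link (κ) is an interpretation, made
  explicit in configuration.
* The stall score measures abruptness of BrdU termination; the package
  makes no claim about the biological cause of any individual stall.
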