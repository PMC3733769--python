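# Methods

This note records the models and procedures `mcnet` implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical and design choices made where the design was open.

## Superimposition and transfer

The generalized Procrustes fit removes similarity information (scale,
position, orientation) from each configuration using the **reference
landmarks only**: each configuration is scaled to unit centroid size
(centroid size = √Σ‖xᵢ − x̄‖², the scale measure), centered at the origin,
and rotated by the det +1 rotation minimizing the summed squared distance
to the consensus; the consensus is re-estimated as the mean of the aligned
configurations, recentered and rescaled to unit centroid size, and the
loop repeats until the summed squared Procrustes distance changes by less
than 1e-10 (hard cap 1000 iterations, after which a convergence error
reports the residual; in practice the fit converges in well under 20).
Reflections are excluded because all specimens are digitized on the same
anatomical side, so an improper fit would be meaningless.

The per-configuration transform (centroid, centroid size, rotation) is
then applied verbatim to the measurement points — they are never refit.
Estimating the transform on stable anatomy and transferring it keeps the
superimposition itself from manufacturing covariance among the points
whose covariance is the object of study.

**Orientation gauge.**  A converged consensus is defined only up to a
global rotation.  The consensus is rotated onto its principal axes (major
axis on x), with the 180° ambiguity resolved by requiring the first
landmark with a non-negligible major-axis coordinate (|x| > 1e-8) to lie
on the positive side.  This makes the output invariant to arbitrary
per-configuration similarity pre-transforms and to specimen order.  The
price is that input already aligned in some other pose is returned in
canonical pose rather than unchanged; since every downstream statistic
(Rv) is rotation-invariant, the gauge has no scientific effect.  For
shapes with an (exactly) isotropic landmark covariance the principal axes
are undefined and the gauge is arbitrary but still deterministic.

Replicate digitizations enter the fit as separate configurations, so
measurement error passes through the same alignment as signal; specimen
means are taken afterwards.

## Procrustes ANOVA

With a balanced design (n ≥ 2 specimens, r ≥ 2 replicates each) the
summed squared deviations of the aligned measurement coordinates around
the grand mean decompose exactly (to round-off) into a between-specimen
term and a within-specimen replicate term:

    SS_ind = r·Σᵢ ‖m̄ᵢ − m̄‖²,   SS_err = Σᵢⱼ ‖mᵢⱼ − m̄ᵢ‖²,

summed over all landmarks and both coordinates.  Degrees of freedom use
the similarity shape-space dimensionality d = 2k − 4 for k 2-D landmarks:
df_ind = (n−1)·d, df_err = n(r−1)·d.  d is recorded in the output table so
alternative conventions are auditable; note d cancels in the F ratio
F = MS_ind/MS_err, so the choice affects reported mean squares, never the
test statistic.  Identical replicates give SS_err = 0; the table then
flags `zero_error`, reports F = ∞ and p = 0 rather than dividing by zero.
The p-value otherwise comes from the F(df_ind, df_err) upper tail.

This d is a convention: the measurement points are transformed with
parameters estimated from the reference landmarks, so strictly fewer than
four degrees of freedom are removed from their own coordinates.  Tests
that simulate aligned data directly therefore calibrate the F ratio
against df built from the full 2k dimensions.

## Rv coefficient

Each landmark's block is the N×2 matrix of its coordinates across
specimens, column-centered (per coordinate) because Rv is defined on
covariance structure.  With S_AB = AᵀB,

    Rv = tr(S_XY S_YX) / √(tr(S_XX²)·tr(S_YY²)).

Equivalently tr(W_X W_Y)/√(tr(W_X²)tr(W_Y²)) with W = XXᵀ configuration
matrices — the squared-cosine (Escoufier) form; block orientation matters
and the N×observations-by-2-variables convention is the one under which
the coefficient is the multivariate generalization of the squared Pearson
correlation.  Properties relied on throughout: Rv ∈ [0, 1]
(Cauchy–Schwarz on the matrix inner product), symmetry, invariance to
rotation and positive scaling of either block, translation absorbed by
centering.  A zero-variance block raises an undefined-correlation error.
At least 3 observations are required; the matrix builder defaults to
specimen means when replicates exist (the ANOVA certifies error is
negligible, and the correlations target between-individual variation),
with `all_replicates` as an explicit alternative.

## Thresholding

Edge i–j is retained with weight Rv_ij iff Rv_ij **strictly** exceeds τ
("above the threshold"); equality drops the edge.  τ = None keeps all
pairs (complete weighted graph); τ ≥ 1 yields an edgeless network and a
warning.  The node set always equals the label set: isolated nodes are
retained and resolve to singleton modules.  Thresholding by statistical
significance is deliberately not the default — with 171 simultaneous
tests the type-I error is uninterpretable — and is not offered as a
packaged option.

## Spin-glass module extraction

The energy of a module assignment σ is

    H({σ}) = − Σ_{i<j} (W_ij − γ·p) δ(σ_i, σ_j),

summed over unordered pairs (an ordered-pair sum is exactly twice this
and has the same minimizers; reported energies use the unordered
convention).  The null model is a weighted Erdős–Rényi graph: every pair
carries the same expected weight p = (Σ_{i<j} W_ij)/(k(k−1)/2).
Preserving total weight gives two identities used as self-checks: the
all-singleton partition has H = 0, and the all-in-one partition has H = 0
at γ = 1.  The resolution γ defaults to 1.  The number of spin states q
equals the node count, so the number of modules is effectively
unconstrained.

**Annealing schedule** (all config-exposed): random initial assignment
from the trial seed; single-spin Metropolis updates; per temperature
stage, 50 sweeps of k updates; geometric cooling with factor 0.99; the
start temperature is auto-calibrated per trial so uphill moves from the
initial state are accepted with probability ≈ 0.9; the run stops at
T = 1e-3 or after 200 consecutive stages without improving the best
energy seen, and the **best-visited** state (not the final one) is
returned.  The 200-stage patience matters: a patience measured in stages
interacts with the cooling rate, and a shorter one can halt the run while
the system is still hot, stranding a few percent of trials in local
minima; at 200 stages the annealer reaches the exhaustively verified
optimum in effectively every trial on networks up to ~20 nodes (checked
against full partition enumeration, Bell-number bounded to ≤ 12 nodes).
A network whose couplings W_ij − γp are all within 1e-12 of zero is
degenerate — every partition has the same energy — and is resolved
deterministically to the all-singleton partition, flagged as degenerate.

Repeated trials (seeds spawned deterministically from a master seed via
`numpy.random.SeedSequence`) are tallied as canonical partitions: modules
ordered by their smallest member's position in node order, members in
node order, so index permutations collapse to one solution.  Entries are
sorted by descending frequency with the canonical form as a deterministic
tie-break.  Whatever equal-energy state a trial lands in is tallied
as-is: solution multiplicity is itself the signal of landscape ambiguity.
A module's **reproducibility** is the fraction of trials whose partition
contains exactly that node set as one module.

## Robustness analyses

The threshold sweep rebuilds the network at each level and reruns the
frequency analysis with the same annealing configuration, so a
single-level sweep reproduces a direct run exactly.  Architecture
agreement between levels is **exact canonical-partition equality**; an
adjusted Rand index (scikit-learn) is reported alongside as a graded
diagnostic, never as the pass criterion.  Leave-one-out reruns the entire
pipeline — superimposition onward — for every n−1 subset with one shared
master seed, and reports each subset's top partition, exact agreement
with the full-sample top, and the agreement fraction; `stable` flags an
agreement fraction ≥ 0.9 (a reporting convention, not a significance
statement).

## Synthetic generator

The generator emulates the study design end to end: k_ref reference
landmarks on a unit-radius ring and k_mp measurement points on an inner
ring (radius 0.6); per specimen, each planted module draws one shared 2-D
Gaussian displacement (sd `module_effect_sd`, default 0.10) added to all
its members — a common-factor construction that directly realizes tightly
correlated units — plus independent isotropic noise per landmark (sd
`noise_sd`, default 0.02, also applied to the reference landmarks); the
whole configuration then receives a random similarity nuisance (rotation
U(0, 2π), per-axis translation U(−0.5, 0.5), log-uniform scale in
[0.5, 2]); each of the `replicates` digitizations (default 2) adds
independent error (sd `digitization_sd`, default 0.004, well below the
landmark noise, as a certified-precision digitizing setup would produce).
Defaults give an effect-to-noise ratio of 5.  Presets match the two study
designs: 21 reference + 19 measurement points with n = 24 and four
planted modules of sizes 5/5/5/4, and 18 + 16 with n = 16 and modules
MP1–3 / MP4–7 / MP8–12 / MP13–16.  The planted partition and the
nuisance-free measurement coordinates are returned as machine-readable
truth.

What it does **not** emulate: real wing geometry (landmarks are rings,
not vein junctions), non-Gaussian or size-correlated (allometric)
variation, spatial autocorrelation between neighboring points beyond the
planted blocks, asymmetry, or pixel quantization.  Passing recovery tests
therefore show the pipeline correctly extracts block-correlation
structure through superimposition noise and similarity nuisance — not
that any particular biological dataset has such structure.

**A real small-sample limitation the generator exposes.**  Between-module
Rv is pure sampling noise of order O(1/n) but with a heavy right tail:
the cross-block covariance of two modules is dominated by the chance
sample correlation of their factor draws, which the effect size does not
shrink.  At n = 24, roughly a quarter of generator seeds produce one
cross-module block whose Rv exceeds the null expectation p, making a
merged partition the *genuine* energy minimum.  This is a property of
correlation-network inference at small n, not of the optimizer — which is
exactly why the leave-one-out and threshold-sweep diagnostics are part of
the pipeline.

## Problem sizes in the test and acceptance runs

Sizes were chosen as the smallest that exercise each claim cleanly: the
annealer-vs-enumeration check uses 20 random networks of 5–9 nodes with
100 trials each (enumeration is exact up to 12 nodes); planted-module
recovery uses the 24-specimen preset with 1,000–2,000 trials; the
acceptance script runs the sweep at 500 trials per level and the
leave-one-out at 200 trials per subset; the ANOVA null calibration uses
500 simulated designs.  The pipeline default of 10,000 trials is the
recommended production setting for real data.

## Known limitations

- 2-D landmarks only; no semilandmark sliding, no asymmetry decomposition,
  no partial least squares.
- The Rv is computed between landmark *pairs* (2×2 blocks); multi-landmark
  block Rv is out of scope.
- The ER weighted null is the only packaged null model; degree-corrected
  (configuration) nulls change the energy and can change the argmin.
- Reported occurrence frequencies depend on the annealing schedule as well
  as the landscape; only their ranking and the exhaustively verified
  minima are schedule-independent.
- TPS input carries no roles or replicate numbers: roles come from a
  side-channel map and repeated IDs are numbered as successive replicates
  in file order.
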