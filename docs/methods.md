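# Methods

## Problem setting

We optimize a vector objective `f : X → R^M` over molecules, where every
component is expensive to evaluate (simulation or experiment) and the
design space cannot be enumerated.  All objectives are handled internally
in maximization orientation: a `MinMaxSpec` negates minimized objectives
exactly once at ingestion and un-negates on output, so a single dominance
code path serves every direction combination.  Evaluations are assumed
noise-free and deterministic; re-querying a molecule is therefore never
useful, and the loop guarantees no molecule is labeled twice.

## Pareto front and hypervolume

Dominance uses strict floating-point comparison with no tolerance, and
duplicate objective vectors collapse by exact equality — determinism is
worth more here than robustness to representation noise, which the
observation-noise floor in the surrogate already supplies.

Hypervolume `HV(P; r)` is computed exactly by a sorted sweep for M = 2 and
a dimension-sweep recursion for M = 3 (slice along the third coordinate,
2-D sweep per slab).  For M ≥ 4 a uniform Monte-Carlo fallback with
2 × 10^5 samples (relative tolerance ~10^-2) is used; the experiments this
package targets are M = 2, so no general exact M-dimensional algorithm is
included.  Per-candidate hypervolume improvement at M = 2 is vectorized
over the pool via the staircase decomposition of the dominated region,
which is what makes L × N improvement evaluations per iteration cheap.

The reference point `r` is fixed at the start of a run as the
componentwise nadir of the *initial* labeled objectives, minus a
configurable slack `eps_ref` (default 0, so boundary points contribute
zero volume).  Whether an offset from the exact nadir should be applied
was genuinely open; zero is recorded in the config and used throughout.
Generated candidates can fall below `r`; their improvement contribution is
clipped at the box boundary (componentwise max with `r`), which keeps HVI
well defined and nonnegative for arbitrary posterior draws.

## Surrogate

One independent Gaussian-process regressor per objective
(scikit-learn `GaussianProcessRegressor`): ARD squared-exponential kernel
with a constant amplitude factor and a white-noise term bounded below by
10^-6 on the standardized label scale.  Features are z-scored per
dimension, labels per objective; hyperparameters maximize the marginal
likelihood with one restart.  No cross-objective covariance is modeled —
the acquisition only needs per-objective joint draws over the pool, and
independent GPs keep the factorization cheap and the estimator unbiased
under that assumption.

Joint sampling computes the dense posterior covariance over the pool per
objective and factorizes it with a jitter escalation ladder
(10^-8 → 10^-4); factorization failure after the ladder raises an error
naming the pool size and jitter reached.  Pools above a cap (default 5000)
are sampled in independent chunks with a logged warning — the joint
structure then holds only within chunks.  Pathwise sampling via random
Fourier features would remove the cap and is an acknowledged extension
point, not implemented.

The small noise floor has a second role: it breaks improvement ties, so
the per-draw argmax is almost surely unique.  Exact floating-point ties
are still broken deterministically by lowest pool index, and a draw whose
maximum improvement is exactly zero credits no candidate — the tally sum
can therefore fall below one, which is informative (it is the probability
that the pool contains any improver at all).

## Acquisition

`estimate_pmhi` computes, per posterior draw, every candidate's `ΔHV`
against the *fixed* incumbent front (the front is never augmented within a
draw — this keeps the additive decomposition exact), finds the winner, and
tallies indicators.  `select_batch` sorts by probability; the sorted
prefix is provably the exact maximizer of the additive batch score over
all size-q subsets, and the test suite verifies this against exhaustive
subset enumeration.  When fewer than q candidates have positive
probability, remaining slots are filled by descending probability of being
nondominated with respect to the *observed* front under the draw.  Ranking
against the observed front (rather than a per-draw sampled pool front) was
an open choice; it is cheap, monotone in candidate optimism, and
independent of pool composition, and is recorded here as the package's
definition.

The constrained variant enforces feasibility per draw using auxiliary
posterior draws: infeasible candidates are excluded from that draw's
argmax; draws where the whole pool is infeasible are dropped and
probabilities renormalized over contributing draws (a draw that is
feasible but non-improving still counts in the denominator, mirroring the
unconstrained estimator).  With one objective the estimator reduces to
qPO — the probability of attaining the pool-wide sampled maximum — and the
two code paths are verified to return bit-identical vectors when the qPO
incumbent equals the front/reference value.

Candidates already labeled are removed from the pool before scoring:
under noise-free evaluation a duplicate query can never improve the front.

## Generator

String-space GA over a robust token grammar built for this package: atom
tokens with bond-order prefixes over the neutral organic subset
{C, N, O, F, P, S, Cl, Br}, branch push/pop markers, and relative ring
closures.  The decoder tracks free valence and caps or skips unrealizable
tokens, so arbitrary token sequences decode to valid molecules —
single-token edits on encoded drug-like seeds decode to valid SMILES at
≥ 99% (empirically ~100%), which is the property that makes random string
edits a usable mutation operator.  Molecules outside the grammar (charges,
isotopes, radicals, fragments) fail to encode and are rejected, a normal
outcome counted by the generator.

GA details (all config, none claimed to be canonical): population 60,
25 generations, mutation rate 0.9, crossover rate 0.4 (single-point with a
shared split fraction, so self-crossover is the identity), elite fraction
0.2.  The population initializes half from the top-fitness labeled
molecules and half uniformly at random from the labeled set.  Fitness is a
weighted sum of standardized posterior means plus β × mean posterior sd
(β default 1.0); the simplex weights are resampled uniformly every
generation so different generations push toward different trade-off
regions.  Every valid, filter-passing, previously-unseen individual from
any generation accumulates into the pool until N (default 5000) is
reached; a budget-exhausted smaller pool is returned with a warning.

Filters: SMILES length ≤ 108 and synthetic-accessibility score ≤ 8 by
default — deliberately mild constraints that guard against the known
degeneracies of unconstrained logP optimization rather than model real
discovery criteria.  The SA score is the Ertl–Schuffenhauer
fragment-contribution score (RDKit contrib); when its fragment table is
unavailable the filter degrades to a ring-count + size heuristic with a
logged warning, and most tests use the heuristic so the suite has no
data-file dependency.  An optional required-substructure SMARTS filter
supports scaffold-constrained campaigns.

## Loop

Per iteration: refit surrogate on all labeled data → generate pool →
joint posterior draws (L = 256 by default) → qPMHI + fallback → query the
oracle on the batch → update data and front.  Defaults follow the shipped
benchmark configuration: T = 20 iterations, batch q = 50, pool N = 5000.
Generator "retraining" is realized by refitting the GA fitness on the
updated surrogate each iteration; there are no generator weights.

Determinism: per-iteration fit/sample/generator streams are split from
`SeedSequence([master_seed, t])`, so a run is a pure function of its
master seed and initial data, and checkpoint resume (labeled table +
metrics + config snapshot, written atomically each iteration) reproduces
an uninterrupted run bit-for-bit.  An oracle failure on a candidate skips
it and substitutes the next-ranked candidate; early stopping is available
as an HV-stall patience rule (off by default) or a user callback, and the
stop reason is always reported explicitly.

## Synthetic benchmark

The download-free benchmark maps strings deterministically to Gaussian
hash coordinates `z` (stable blake2b-seeded PCG64), builds latent scores
`y_0 = z_0`, `y_m = ρ z_0 + √(1−ρ²) z_m`, and warps each latent through
the strictly increasing map `y + 0.3 tanh(y)`.  Because the warp is
monotone per objective it preserves all dominance relations of the
latents: ρ = +1 gives co-monotone objectives (single Pareto point),
ρ = −1 a perfect trade-off (every point nondominated), and the default
ρ = −0.5 a nontrivial front.  The surrogate sees the same hash coordinates
as features, so there is real signal to learn.  What this emulates is the
*selection* problem — correlated, smoothly structured objectives over a
discrete pool; what it does not emulate is chemistry: no structure–
property relationships, no activity cliffs, no feature noise, no
synthesis constraints.  Passing the ablation therefore shows the
acquisition machinery works as designed, not that any specific chemical
campaign will succeed.

The ablation harness fixes a pool with known ground truth and compares
acquisitions under a paired-seed design (shared initial labeled subset
and reference point per replicate): qPMHI, greedy ranking by HVI of the
posterior mean, and uniform random selection without replacement (the
Sobol-style space-filling baseline reduces to uniform choice on an
unstructured discrete pool).  Metrics are the labeled-front hypervolume
and the fraction of the pool's true Pareto members recovered (denominator:
the fixed pool's own front), with 95% normal-approximation confidence
bands over replicates.  The default comparison scenario uses a pool of
2000, 100 initial labels, q = 50, 10 iterations, L = 64, 5 replicates —
sizes chosen so the full paired comparison runs comfortably on one CPU
while leaving the GP fits well conditioned; at these sizes qPMHI reaches
full Pareto recovery and uniform selection does not.

## Known limitations

- Exact hypervolume only to M = 3; M ≥ 4 falls back to Monte Carlo.
- Independent per-objective GPs ignore cross-objective correlation; a
  correlated surrogate would need only a conforming `sample_joint`.
- The descriptor featurizer is a 10-dimensional physicochemical summary;
  fingerprint/Tanimoto kernels are a natural extension of the surrogate
  interface but are not shipped.
- The token grammar covers neutral single-fragment organics; salts,
  charged species and organometallics are rejected at encoding.
- No synthesizability planning: the SA-score filter is a heuristic gate,
  not a route check.
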