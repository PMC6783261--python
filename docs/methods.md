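# Methods

## The simulation model

`tedyn.engine` implements a constant-size Wright–Fisher population of N
haploid individuals. A genome is a presence/absence vector over
16 chromosomes × 200 ordered loci (3200 potential TE insertion sites) plus
one unlinked biallelic modifier locus. Relative fitness with *n* copies is
`w(n) = exp(−a n − b n²/2)`; *a* is the per-copy selection strength and *b*
the synergistic epistasis between copies (quadratic log-fitness term).

**Generation cycle.** (1) N parents are sampled with replacement with
probability proportional to fitness. (2) Offspring are clonal copies of
their parent, except in sexual generations — every generation whose index
is a positive multiple of `sex_interval` — where each offspring arises from
fusion of two *distinct* fitness-sampled parents followed by recombination.
(3) Transposition acts on the newly formed offspring: each copy duplicates
with probability `u` (`u_meiotic` for recombinant offspring) into a site
chosen uniformly among the currently empty sites; if no empty site remains
the insertion is skipped (irrelevant at ~50/3200 occupancy). (4) Excision
removes each copy independently with probability `v`, plus
`modifier_delta_v` in modifier carriers. The modifier has no direct fitness
effect and no recurrent mutation; it changes frequency only through
inheritance and hitchhiking.

**Recombination.** Each chromosome receives a Poisson(1) number of
crossovers ("on average one crossover per chromosome") with positions
uniform over the 199 inter-locus boundaries; the starting parent of each
chromosome is chosen fairly, and the offspring copies each locus from the
currently active parent. Internally only the parity of crossovers per
boundary matters, which the engine exploits (exact Poisson thinning, no
approximation). The modifier is inherited from either parent with
probability ½ independently of all chromosomes.

**Founding and burn-in.** A single founder receives `founder_copies` (50)
TEs uniformly without replacement, populates the deme clonally, the
modifier is then assigned to each individual independently with probability
`modifier_init_freq`, and 20 burn-in cycles of transposition-then-excision
run on every individual separately with no selection and no resampling.
One burn-in cycle equals one mutation pass (the cycle count is taken at
face value); the modifier-adjusted excision rate already applies during
burn-in, which is negligible at the preset rates.

**Sampling.** Mean load, load variance and modifier frequency are recorded
at generation 0 (post burn-in) and every `sample_every` (10) generations;
experiments run `n_replicates` (10) independent replicates whose RNG
streams are spawned from the master seed (`SeedSequence.spawn`), giving
bit-for-bit reproducibility.

## Parameter presets and their calibration

Exact rate values are not fixed by the source material, so the package
ships two named presets chosen once, from first principles plus a one-time
pilot grid, and frozen.

**`yeast-modifier`** (`u=1e-5`, `v=1e-6`, `a=1e-3`, `b=0`,
`modifier_delta_v=1.5e-4`, `modifier_init_freq=0.1`): the regime in which
TE activity rates can evolve. Baseline `u` is the order of measured Ty
transposition rates; baseline excision is much rarer. Two quantitative
effects drove the calibration away from the naive closed form
`n(t) = 50·exp(−Δv·t)` (which would suggest `Δv ≈ 2e-4` for ~9 copies lost
by generation 1000):

* selection also responds to the load variance that carrier excision
  creates, adding to the loss; with `Δv=1.5e-4` the *total* asexual
  endpoint loss at N=10⁴ is ~8–9 copies (final load ~41–42 of 50);
* the hitchhiking selection coefficient of the modifier is
  `s(t) ≈ a·Δn(t) ≈ a·50·Δv·t` early on, so at very low initial frequency
  the sweep is drift-dominated and stalls in many replicates.
  `modifier_init_freq=0.1` represents a standing defense variant common
  enough (10³ carriers at N=10⁴) that the sweep is reliable, while in
  sexual populations recombination still halves the modifier–load
  association every episode and keeps the modifier's frequency low
  (~0.1–0.4 by generation 990) and the sexual loss at ~2 copies.

**`no-modifier`** (`u=v=3e-4`, `a=5e-3`, `b=0`): the contrast without
activity evolution. Selection can only act on copy-number *differences*;
balanced transposition/excision at 3e-4 maintains segregating
insertion/excision variants, and `a=5e-3` makes the recombination-driven
difference in selection efficacy (sexual populations lose TEs faster)
large relative to replicate drift. Weaker selection or lower rates gave
overlapping sexual/asexual replicate distributions at desk scale.

## Scaled problem sizes

The full experiment simulates 100,000 individuals; population size is a
free parameter here, and the shipped tests and `scripts/acceptance.py` use
N=10,000 (modifier scenario, and the pure-excision decay check) or N=2,500
(no-modifier contrast), with 10 replicates — sizes at which the contrasts
of interest dominate drift and a full two-mode comparison runs in minutes.
Assertions are distributional (means, orderings, standard-error bands),
not pointwise.

## Summaries

`fit_loss_regression` pools the (generation, mean load) samples of all
replicates into one OLS fit (a per-generation-mean variant is available;
both slopes coincide for balanced sampling) and reports
`tes_lost_1000 = −slope × 1000`. `modifier_fixation_time` returns the
first sampled generation at or above a frequency threshold, default exactly
1.0 (allele counts are discrete). In the acceptance comparisons the
threshold 0.9 ("near fixation") is used with censoring at the horizon,
because at N=10⁴ and `a=1e-3` the last leg of the sweep (absorbing the
final few non-carriers) is drift-limited and can outlast the 990-generation
experiment even when the sweep is complete for every practical purpose.

## Permutation ANOVA

`PermutationAnova` fits the fixed model family
`count ~ coverage + generation + mode + generation:mode` (generation
numeric, mode a sexual/asexual indicator) with sequential type-I sums of
squares in that order, computed exactly via an ordered thin-QR
decomposition (the j-th term's SS is `(qⱼ'y)²`). Per-term p-values are
`(1 + #{F* ≥ F_obs}) / (1 + B)`.

Permutation schemes: **Freedman–Lane** (default) permutes, for each term,
the residuals of the reduced model containing the preceding terms and adds
them back to the reduced-model fit before recomputing that term's F — the
appropriate conditioning when coverage is a nuisance covariate; **raw**
permutes the response itself. With Gaussian errors both converge to the
classical F-test p-values (verified at B=10⁴ within 0.02). A constant
response is defined to give F=0 and hence p=1. The seed is a required
argument: permutation p-values are otherwise irreproducible. Samples under
one-fold mean coverage are excluded before analysis (`coverage_filter`,
strict inequality: exactly 1× is retained).

`residualize` removes the linear coverage effect from counts (detection
probability depends on sequencing depth); with constant coverage it falls
back to centring. `tes_lost_from_residual_slope` converts the OLS slope of
residuals on generation into copies lost per 1000 generations and an
implied final count against the 50 ancestral full-length copies; positive
slopes are reported as negative losses (gains) by the documented sign
convention.

## Insertion-call post-processing

`deduplicate` merges calls of the same physical insertion reported by
different detectors: within each (strain, generation, chromosome, family)
the calls are single-linkage clustered along the chromosome with a 100 bp
default breakpoint tolerance (typical split-read vs discordant-pair
scatter; configurable), keeping the median position/length and the
detector list. The operation is idempotent. `classify_by_length` tags each
insertion: `full_length` when within 500 bp of the family's canonical
length, `solo_LTR` for 220–420 bp, `truncated` strictly between the solo
ceiling and the full-length floor, `other` otherwise; unknown families can
only be solo-LTR or other (a would-be full-length call logs a warning).
Canonical Ty1–Ty5 lengths ship as an editable table (Ty1 5918/334,
Ty2 5959/332, Ty3 5351/340, Ty4 6223/371, Ty5 5375/251 bp full/LTR, from
the yeast TE literature). The "within a 500 bp range" rule is read as
|observed − canonical| ≤ 500; a stricter reading (LTR pair within 500 bp of
the internal sequence) would need per-part coordinates that call tables do
not carry. All coordinates are 0-based half-open.

## Synthetic data: what it emulates, and what it does not

`gen_count_table` reproduces the experiment's design matrix — 4 sexual +
4 asexual strains, generation 0 plus every 90 generations to 990 (the
12-point reading of the ambiguous design; configurable) — with a latent
linear truth per mode (defaults: −0.009 copies/generation asexual, 0
sexual, i.e. ~9 of 50 copies per 1000 generations), Gaussian strain-level
noise (0.5 copies), and observed counts binomially thinned by a saturating
coverage-dependent detection probability `1 − exp(−k·coverage)` with
`k = ln 2` (50% detection at 1×) and per-sample coverages uniform on
5–50×. The constant `detectable_fraction = 24/50` records that the
insertion callers resolve only about half of the ancestral full-length
copies; it is deliberately *not* applied inside `gen_count_table`, whose
counts live on the truth scale so that slope-based loss recovery against
the 50-copy ancestor is meaningful. `gen_insertion_records` programs an
exact full/solo/truncated composition with 1–6 detectors per insertion and
bounded breakpoint jitter; `gen_read_count_series` programs a relative
read-fraction decline (default 23.5% over the experiment) into exact read
counts.

Real data differ in ways the generators do not model: detector-specific
false positives and biases, non-linear load trajectories, shared genomic
backgrounds across time points (the same strain is resequenced, so
residuals are autocorrelated), and mappability structure along the genome.
Passing the recovery tests therefore validates the estimators' correctness
under the stated sampling model, not robustness to those real-data
pathologies.

## Numerical choices

Sparse per-individual sorted site arrays with copy-on-write replace a
dense N×3200 occupancy matrix except inside sexual generations (dense only
for the recombination pass); empty insertion targets are rejection-sampled
(exactly uniform over empties) with an enumeration fallback near
saturation; crossover parities use exact Poisson thinning. Mutating
individuals go through the same per-genome kernels as the public
single-genome operations, so the two code paths cannot diverge; an
enumeration oracle cross-checks the one-generation offspring-load law.
Ties in permutation F statistics count as exceedances (conservative);
p-values are bounded below by 1/(B+1).

## Known limitations

No diploid phase beyond transient fusion, no mating-type loci, no
per-family TE classes inside the simulator, no ectopic-recombination
fitness costs, single deme. The ANOVA exposes only the study's model
family, with generation as a numeric covariate and no multiple-testing
correction across terms. Loss regression ignores trajectory
autocorrelation (no mixed-effects variant).
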