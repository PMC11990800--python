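# Methods

## Model overview

`karyosim` simulates the evolution of a cancer cell population whose cells
are distinguished by their karyotypes and driver mutations, and infers the
selection and instability parameters of that model from cohort-level
copy-number summaries.

The genome is discretised into fixed-size bins. A cell's genotype is, per
chromosome, a list of homologs, each carrying an integer copy number (CN)
per bin; plus a list of mutations, each addressed to a specific CN unit
(chromosome, homolog, bin, unit). Because mutations ride on CN units,
amplification of a mutated unit multiplies the mutation and deletion removes
it. A clone is the set of cells sharing one genotype.

### Events at division

Five CNA mechanisms plus driver mutation can occur when a cell divides:

| event | per-division probability | action |
|---|---|---|
| whole-genome duplication | `p_wgd` | one daughter receives two copies of every homolog |
| chromosome missegregation | `p_misseg` per homolog | a homolog is misplaced: one daughter gains it, the other loses it |
| arm missegregation | `p_arm_misseg` per homolog | one arm of a homolog moves entirely to one daughter |
| focal amplification | `p_focal_amp` | CN doubled across a bin range on one homolog |
| focal deletion | `p_focal_del` | CN zeroed across a bin range on one homolog |
| driver mutation | `p_driver_mut` | one wild-type CN unit of a random driver gene becomes mutant |

Focal event lengths are Beta-distributed fractions of the arm length
(`max(1, round(Beta(a,b) * arm_bins))` bins, uniform placement). In lineages
that have undergone WGD, both missegregation probabilities are multiplied by
the WGD-aneuploidy rate `alpha` (clamped to 1). Several events may co-occur
in one division; they are applied in the fixed order WGD, chromosome
missegregation, arm missegregation, focal amplification, focal deletion,
driver mutation, each acting on the already-updated daughter pair. Which
daughter receives the WGD / gained homolog / amplified region is a fair coin
flip. When events co-occur, later events sample their targets from the
current state of the daughter they act on; an op that references a homolog
removed by an earlier event in the same division is skipped. Co-occurrence
has probability of order `p^2` per division, so this convention is
practically invisible but keeps every division replayable.

### Fitness

Three selection models give a cell `k` its fitness rate `s_k`:

* **arm model** — each arm `r` has a selection rate `lambda_r > 0` and
  `s_k = prod_r lambda_r^(c_r / c)`, where `c_r` is the mean total CN over
  the arm's bins and `c` the genome-wide mean bin CN (ploidy). Arms with
  `lambda_r > 1` reward gains, `lambda_r < 1` rewards losses.
* **driver model** — each driver gene has wild-type/mutant allele rates
  derived from a base rate `lambda_d >= 1` (oncogene: `lambda_d`,
  `lambda_d^2`; tumor suppressor: `1/lambda_d`, `1`), and
  `s_k = prod_d lam_WT^(2 n_WT / c) * lam_MUT^(2 n_MUT / c)` with `n_WT`,
  `n_MUT` counted from the CN profile and mutation addresses. Mutating or
  losing a TSG allele, and mutating or gaining an OG allele, raise fitness.
* **hybrid** — the product of the two.

The numerators `c_r` are exact (unrounded) mean arm copy numbers; the
normalising ploidy `c` in the exponents is the lineage's **reference
ploidy** `2 * 2^wgd_count`. This choice is deliberate, and the design was
genuinely open. Three candidates exist: (a) the rounded mean bin CN — but
then `round(2x)/round(2c)` differs from `round(x)/round(c)` and a
whole-genome duplication changes fitness, contradicting the model's central
premise that a tetraploid cell is not intrinsically fitter; (b) the exact
mean bin CN — WGD-invariant, but now losing *neutral* material shrinks the
denominator and raises the dosage exponents of selected arms, so dosage
concentration by loss is rewarded; at desk scale this reverses the expected
ploidy response to GAIN-arm selection; (c) the lineage reference ploidy —
exactly WGD-covariant (both `c_r` and `c` double), insulates each arm's
exponent from changes elsewhere in the genome, and coincides with the
rounded mean CN in the near-diploid / near-tetraploid regime where the
model operates. The package uses (c). The integer-rounded `arm_cn` and
`ploidy` reductions (round half away from zero) are the reported summary
statistics and feed the viability checks.

**Viability checkpoints** set fitness to zero for karyotypes beyond
configured limits. Defaults: ploidy ≤ 8, max bin CN ≤ 20, max bin CN /
ploidy ≤ 5, nullisomic bins ≤ 5% of the genome, WGD count ≤ 2, unlimited
driver count. These were chosen to be permissive (they rarely bind in the
test-scale runs) but explicit, and are all overridable.

### Population dynamics

Cell lifespans are exponential with turnover rate `lam` (time is measured in
expected lifespans; `lam = 1` by default). At the end of its lifespan a cell
divides with probability

```
p_div = g(t) * f(s_k),   g = Pbar / (Pbar + P),   f = s_k * P / sum_cells s
```

and dies otherwise. `g` is a negative feedback keeping the population `P`
near the expected size `Pbar(t)` (at `P = Pbar` with neutral fitness,
`p_div = 1/2`: homeostasis); `f` rewards cells whose fitness exceeds the
population mean. `p_div` is clamped to `[0, 1]`; when every cell has fitness
zero, `p_div = 0`. Schedules for `Pbar(t)`: constant, exponential, logistic,
and "growth modes" 1–10 that start from a common base size and grow
exponentially at a rate proportional to the mode index (mode 1 constant) —
in growing populations the feedback is weaker, so low-fitness subclones
survive and diversity rises.

Evolution is advanced by tau-leaping over clones: per step of length `tau`
and per clone of `n` cells, `Binomial(n, 1 - exp(-lam*tau))` cells end their
lifespan, of which `Binomial(., p_div)` divide; division events are drawn
per clone from the event probabilities, and event-carrying divisions found
new clones (the event set of such a division is sampled exactly from the
joint law conditioned on at least one event, via a first-nonzero-category
decomposition with a truncated binomial). `p_div` is frozen per clone at the
start of each step, the standard tau-leap approximation. The default
`tau = 0.01` lifespans keeps per-step per-cell probabilities well below one;
the desk-scale profiles use `tau = 0.25` (per-step lifespan-end probability
0.22), which the exact-oracle comparison shows is still accurate for the
population statistics used here. An exact event-by-event (Gillespie-style)
simulator with the same output schema serves as a validation oracle at small
population sizes; it re-evaluates the feedback at every single event.

The recorded history stores, per clone and time step, the end-of-step cell
count, within-clone division count and death count, plus each clone's
parent, founding time and the replayable op list that transforms the parent
genotype into it.

### Sampling and phylogeny

A sample of `n` cells is drawn uniformly without replacement at final time
(multivariate hypergeometric across clones). The sampled-cell tree is built
backward in time from the recorded counts: within a step, each recorded
within-clone division is a candidate coalescence — its two daughters are a
uniform pair among the clone's `n` cells, so two of `k` tracked lineages
coalesce with probability `k(k-1)/(n(n-1))`, with `n` decremented per
processed division and coalescence times drawn uniformly within the step
(ordered). At a clone's founding, its lineage re-assigns to the parent
clone, coalescing with a tracked parent lineage with probability `k_p/n_p`
when the sibling daughter stayed in the parent (when both daughters founded
clones, the mother was consumed and no such coalescence is possible).
Within-step ordering of deaths relative to divisions is not resolved by the
recorded counts; the census used for pairing is the end-of-step count, an
approximation that vanishes as `tau` shrinks. Lineages that fail to coalesce
by the simulation start are joined at `t0` by zero-length binary splits
(MRCA age −1). MRCA age is reported as
`(t_MRCA - t_end)/(t_end - t0) ∈ [-1, 0]`.

Every branch carries the clone-founding ops it traverses, so replaying ops
root-to-tip reconstructs each tip's genotype exactly — this is tested, and
it is what makes the tree usable for event clonality statistics: events on
the ancestry of the MRCA's clone are clonal, events on branches below it
subclonal.

### Neutral overlay

After the tree is fixed, passenger SNVs and neutral CNAs are superimposed
per branch as Poisson counts with mean `rate × expected divisions`. The
default clock takes expected divisions as `branch duration × lam / 2`
(at homeostasis about half of lifespan ends are divisions); an exact mode
integrates the recorded per-clone division-per-cell rates over the branch.
Neutral CNAs are applied to the tracked lineage only (a neutral
missegregation gains or loses with equal probability) and bypass viability
checks — the tree is already fixed, so a lethal neutral event cannot
retroactively kill a sampled lineage. Passenger SNVs receive CN-unit
addresses drawn CN-weighted across the genome and are thereafter multiplied
and lost by downstream CNAs exactly like driver SNVs.

## Summary statistics

Per sample: pseudobulk profile (rounded per-bin mean total CN over sampled
cells), per-arm gain/loss calls (rounded arm CN vs baseline 2 for non-WGD
analyses), FGA (fraction of bins differing from the rounded sample mean
ploidy — so a freshly doubled genome has FGA 0 and accumulates FGA through
post-WGD instability), WGD status (majority of sampled cells with at least
one WGD), Shannon index over sampled clone frequencies, monosomy fraction,
MRCA age, clonal/subclonal event counts. Cohort level: per-arm `fr_gain` /
`fr_loss`, WGD proportion, and the WGD FGA difference
`mean(FGA|WGD) − mean(FGA|non-WGD)`.

For the WGD statistics the per-sample FGA is computed on the pseudobulk of
the majority WGD-status component of the sample. A naive whole-sample
pseudobulk makes a 60/40 diploid–tetraploid mixture round to CN 3 genome
wide, inflating FGA in mixed samples on both sides of the WGD call; bulk
pipelines calibrate purity/ploidy to the dominant clone, which the
majority-component pseudobulk mirrors.

Arm classification: arms passing the cohort frequency filter
(`|fr_gain − fr_loss| >= 0.1`; the signed-difference variant is available as
an option) are GAIN arms if their mean posterior selection rate exceeds 1
and LOSS arms if below 1; the report includes the mean rate of GAIN arms and
the mean inverse rate of LOSS arms.

## Inference

All three tasks share one ABC engine. Parameters are drawn from uniform
priors; one cohort is simulated per draw, matched in size to the observed
cohort so reference and observed summaries carry the same sampling noise;
each parameter is regressed on the summary vector with a random forest
(scikit-learn, 300 trees, leaf size 5), and posterior weights follow the
random-forest ABC convention: training rows that share the observed
vector's leaf in a tree receive weight inversely proportional to the leaf's
occupancy, averaged over trees. A rejection engine (nearest 10% by
normalised Euclidean distance, Epanechnikov-weighted local-linear
adjustment, clipped to the prior support) is available as a fallback. Point
estimates are MAP values: the mode of a Gaussian-kernel density (Silverman
bandwidth) over the weighted draws, evaluated on a 512-point grid over the
prior support; degenerate weight sets fall back to the highest-weight draw.

* **Arm selection** — observed: per-arm `fr_gain`/`fr_loss`. Arms failing
  the frequency filter are fixed at `lambda = 1` and excluded; the free
  parameters are the filtered arms' rates (`U(0.5, 1.5)`) and the
  arm-missegregation probability. Cohorts below 10 samples are refused.
* **WGD** — observed: WGD proportion and FGA difference, with arm
  parameters held fixed; free parameters `log10 p_wgd` and `alpha`. Cohorts
  with WGD proportion ≤ 10% are refused.
* **Driver genes** — observed: per-gene mutation/gain/loss frequencies in a
  chromosomally quiet cohort; the driver mutation rate is fixed and the
  free parameters are each gene's `lambda_d` and the focal-deletion
  probability. Genes can be labelled TSG/OG from the cohort itself (loss
  frequency above gain frequency → TSG), with an annotation fallback for
  ties. Focal length Beta parameters are fitted by maximum likelihood
  (`scipy.stats.beta.fit` with the support fixed to [0, 1]).

Known joint nonidentifiability: with bulk-style summaries, high CNA
probabilities with weak selection and low probabilities with strong
selection produce similar event counts; the engine reports the resulting
ridge rather than resolving it (fixing the whole-chromosome missegregation
probability, as the arm task does, is the practical mitigation).

## Study scales

Two named profiles fix the study conditions.

* `paper` — published-scale settings: 24-chromosome human genome (hg19
  lengths, 500-kb bins — the bin total depends on the reference convention
  and is close to, not exactly, any particular published count),
  `p_misseg = 5e-5` per homolog per division, arm-missegregation prior
  `U(1e-5, 1e-4)`, `alpha ~ U(0, 300)`, `log10 p_wgd ~ U(-6.5, -3.5)`,
  1,000 sampled cells, 10,000 reference simulations.
* `test` — the desk-scale design used by the test suite and the acceptance
  script: 4-chromosome toy genome (50/40/30/20 Mb, 1-Mb bins, centromeres
  at 40%; 140 bins, 8 arms), tumors founded by a single diploid cell with a
  carrying capacity of 150 cells over 25 generations (`tau = 0.25`), 50
  sampled cells, 2,000 reference simulations, and cohorts of 20 samples for
  the arm-selection task (typical of per-cancer-type cohorts; at the
  10-sample refusal threshold the 0.1-granular frequencies cannot
  rank-order clustered selection rates) and 10 for the driver task. Event
  probabilities are scaled up (`p_misseg = 0.002`, arm prior
  `U(0.004, 0.016)`, `alpha ~ U(1, 15)`, `log10 p_wgd ~ U(-2, -0.8)`,
  driver `lambda_d ~ U(1.0, 1.4)` with mutation probability 0.02) so that
  the expected number of events per tumor, and hence the selection
  footprint in cohort frequencies, is comparable to a full-scale run. The
  single-founder start matters: events arising during the initial expansion
  reach high cell fractions by founder effects, which is what lets
  selection separate gain from loss frequencies within 25 generations.

What the synthetic cohorts do **not** emulate: sequencing noise and calling
error, purity/subclonality deconvolution, real genome segmentation,
inter-patient heterogeneity in dynamics or turnover, and mutational
processes beyond the six event types. Passing recovery tests therefore
demonstrates the internal consistency of simulator + summaries + ABC at
realistic signal-to-noise, not performance on real cohorts.

## Numerical choices

* Rounding is half-away-from-zero everywhere a "nearest integer" is taken
  (banker's rounding would bias ties).
* Genotype bins are 0-based half-open internally; exported CN tables use
  BED-style bp intervals; Newick branch lengths are simulation time units.
* The centromere-containing bin terminates the p-arm; a bin belongs to
  exactly one arm.
* Clone identity is lineage-based: every event-carrying division founds a
  new clone even if its genotype coincides with an existing one; clone
  counts are therefore upper bounds on genotype counts, and the phylogeny
  is exact by construction.
* Simulations are deterministic given a `numpy.random.Generator`; a single
  seed drives the whole pipeline. Per-clone fitness values are cached by
  genotype content during a run (pure memoisation; does not consume
  randomness).
* Extinct or undersized cohort samples are redrawn with fresh randomness up
  to 5 times (extinction is rare at the default feedback strength);
  persistent failure raises.

## Known limitations

* No chromothripsis/chromoplexy, copy-neutral LOH, allele-specific
  selection, or epistatic/order-dependent fitness.
* Single-timepoint sampling only.
* The backward-pass census approximation (end-of-step counts) slightly
  distorts coalescence times within a step; negligible at `tau <= 0.25`
  but visible if `tau` approaches a lifespan.
* The growth-mode ladder confounds growth rate with final population size
  by design (faster modes end larger), matching the qualitative behaviour
  it is meant to illustrate.
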