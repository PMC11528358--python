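# Methods

`socage` implements a three-stage computational pipeline for asking whether
age-related declines in social connectedness ("social ageing") protect
group-living animals from the accumulated cost of endemic infectious
disease: (1) a Bayesian edge model turns sampled grooming observations into
a posterior distribution over weighted social networks; (2) a stochastic
SIS model with age-dependent susceptibility, infection duration and
infection severity is simulated over draws from that posterior; (3) mixed
models on the simulated infection costs quantify how much of the age trend
in cost is carried by social centrality.  A synthetic-data generator stands
in for the behavioural data, with a tunable age–sociality coupling so the
whole chain is testable by parameter recovery.

## Synthetic observations

One *group-year* (a social group observed for one year) consists of `n`
adult females with integer ages, per-individual focal-sample counts, and
undirected dyadic grooming-bout counts.  The generator draws

- group size uniformly on 19–73 (mean ≈ 46, matching the scale of the
  emulated field data, which averages ~51 females per network);
- ages from a truncated geometric distribution on 6–28 years whose decay is
  solved numerically to give mean ≈ 11.2 — right-skewed, as adult female
  age pyramids are;
- focal counts uniformly on 15–25 per individual.  No empirical
  focal-count distribution is published for the system we emulate, so this
  range is a free choice; it is set so that the smallest non-zero observed
  edge weight per group-year (1 / max combined effort ≈ 0.02) lands in the
  reported 0.008–0.027 band, which matters because that minimum weight is
  the degree threshold downstream;
- a latent gregariousness `g_i = exp(b0 − rho·(age_i − 6) + eps_i)` with
  `eps_i ~ N(0, 0.25²)`, and dyadic bout counts
  `x_ij ~ Poisson(g_i g_j (f_i + f_j) exp(eta_ij) / (n − 1))` with
  mean-corrected log-normal dyad noise (`sd = 0.3`).

The `1/(n−1)` factor encodes a grooming **time budget**: an individual's
expected total bouts do not grow with group size, so network bout totals
scale linearly in `n` and stay inside the observed 33–392 range across the
full 19–73 size span (a quadratic scaling could not).

Two constants were calibrated once by pilot simulation (60 group-years) and
then frozen: the intercept `b0 = −0.76` targets ≈ 169 bouts per network at
the mean group size, and the default decline rate `rho = 0.035` per year
reproduces a pooled age–strength correlation of ≈ −0.12, matching the weak
negative age–centrality correlations (−0.11 to −0.13) the analysis is
designed around.  `rho = 0` switches social ageing off exactly: expected
log-gregariousness is then age-constant, which the null-calibration tests
exploit.  The generator does not model kinship, matriline structure,
grooming directionality, or community modularity; passing tests therefore
show that the *pipeline* recovers planted age–sociality structure, not that
real grooming networks lack additional structure.

## Edge model

For a dyad with `x` bouts over combined focal effort `d = f_i + f_j`, the
observed weight is `x/d` and the model is gamma-Poisson conjugate:
`x ~ Poisson(rate·d)`, `rate ~ Gamma(a0, b0)`, so the posterior is
`Gamma(a0 + x, b0 + d)`.  Every dyad — including never-observed ones —
keeps strictly positive support, so posterior network draws are complete
weighted graphs; uncertainty about rarely-sampled dyads propagates into
every downstream statistic rather than being rounded to zero.  Dyads are
independent given the data (no dyadic correlation structure), and draws
are one gamma variate per dyad.

The default prior is `(a0, b0) = (0.4, 0.15)` — prior mean 2.7 with heavy
mass near zero (shape < 1).  It was calibrated once against the
network-level summaries the pipeline is meant to emulate: with study-scale
effort (`d ≈ 40`), it puts grand mean strength near 0.6 and grand mean
thresholded degree near 10.  A much flatter prior such as (0.1, 0.1)
shrinks unobserved dyads so hard that strength collapses to ≈ 0.1 at this
effort scale.  Both hyperparameters are exposed everywhere
(`fit_edge_posterior`, `ExperimentConfig`, CLI).

## Centrality

Three measures per individual per draw:

- **strength** — sum of incident edge weights (total grooming rate);
- **closeness** — `1 / mean(shortest-path length to all others)`, with edge
  length the *reciprocal* of edge weight.  The reciprocal is the standard
  rate-to-distance transform; paths are computed on the full complete draw
  (Dijkstra on the dense distance matrix), not on a thresholded graph;
- **degree** — number of incident edges with weight **at or above** the
  group-year's minimum observed non-zero weight.  Complete draws make raw
  degree degenerate (`n − 1` everywhere); thresholding at the smallest
  observed weight keeps degree maximally independent of strength and
  sensitive to losing weak ties, which is how social ageing manifests.
  Edges exactly at the threshold count.

## Epidemic model

Discrete-time stochastic SIS, 500 steps per run.  Per step, susceptible
`i` is challenged by each infected neighbour `j` with probability
`clamp((si + ai_i)·A_ij^0.7, 0, 1)`; the exponent 0.7 raises the
epidemiological weight of weak connections.  The per-neighbour Bernoulli
trials are drawn as one combined trial with success probability
`1 − prod_j (1 − p_ij)` — identical in distribution, vectorizable.
Infections last `di + adi_i` steps and cost `ci + aci_i` per infected
step.  Age effects scale linearly between global anchors (6, 28) —
global, not per-group, so effects are comparable across group-years:
`f(a) = clamp((a−6)/22, 0, 1)`, with maxima `ai_max = 0.25`,
`adi_max = 10` (rounded to whole steps), `aci_max = 2`.  With all three off
(the control), every completed infection costs exactly `di·ci = 5` units.
`ai_max = 0.25` makes the oldest/youngest transmission-probability ratio
`(si + 0.25)/si` = 1.56, 1.42, 1.33 at `si` = 0.45, 0.60, 0.75.

Update order within a step: transmissions are evaluated synchronously
against the step-start infected set, costs accrue for that set, then
durations decrement; an individual recovering at step `t` transmits at `t`
but not `t+1`, and can be reinfected from `t+1` (the recovered state
exists but has duration 0).  The seeding rule is 10% of individuals
(at least one), uniformly at random at step 0, with no burn-in discarded —
the endemic regime is reached quickly at these transmissibilities and the
outcome of interest is total cost over the whole run; both choices are
configurable.  Equilibrium prevalence for the `R0 = 1/(1 − prevalence)`
approximation is the mean over the final 100 steps.

The experiment grid is the full factorial {ai on/off} × {adi on/off} ×
{aci on/off} × {si ∈ 0.45, 0.60, 0.75}: 24 cells, three of them controls.
At publication scale (23 group-years × 1000 draws × 24 cells) that implies
552 000 runs; the pipeline streams results and derives every run's seed
from a master seed and the run identity, so any subset reruns identically.

## Inference

Per parameterization, per-individual accumulated costs are joined with the
same draw's centralities; each centrality is z-scored within group-year
(pooling individuals and draws) and binned into five ordered categories at
−1.5, −0.5, 0.5, 1.5 (intervals closed on the left).  Three Gaussian
linear mixed models share one random-intercept structure — group-year,
individual ID, group-year × simulation — fitted with statsmodels MixedLM
using group-year as the grouping factor and individual and simulation as
variance components.  Because individuals and simulations are nested in
group-year in this design, the crossed structure of the original analysis
is exactly representable this way.  The reference category is "average",
so every "high" coefficient in model 3 reads directly as a high-vs-average
contrast.  Models are fitted by L-BFGS; non-convergence and singular
variance components are reported on the fit object and warned about, not
raised, since boundary estimates are routine on small designs.

The protective effect is `beta_age(model 1) − beta_age(model 2)`:
negative means the age trend flattens once centrality is controlled, i.e.
age-related social decline buffers infection cost.  Its uncertainty is
summarized as `sqrt(se1² + se2²)` — conservative, since the two estimates
are positively correlated.  Model-3 contrasts are computed from fixed
effects as predicted cost differences between categories at ages 8 and 18
(lower quartile and median-age-of-death anchors of the emulated
population).  Costs convert to baseline-infection equivalents by dividing
by `di·ci = 5`.  Effect sizes with SEs are reported throughout;
p-values are not, as the aim is description of simulation output.

## Problem sizes and numerical choices

Desk-scale defaults keep every stage tractable on one CPU: the validation
experiments use 5 group-years × 50 draws × 1 transmissibility (250 runs,
~12 000 model rows, ~15 s including both model fits), and the two-node
epidemic oracle uses 10⁴ replicates of a 6-step chain.  Determinism is
end-to-end: group-year seeds derive from the generator seed and a stable
FNV-1a label hash; run seeds from the master seed and run identity; all
derived seeds stay below 2³¹.  Degenerate inputs fail loudly — zero
within-group variance in a centrality (binning undefined), unreachable
nodes in closeness, empty networks, non-positive priors or thresholds all
raise with the offending unit named.

## Known limitations

- The generator omits kinship and community structure; protective-effect
  magnitudes on synthetic data are not calibrated to any empirical
  population, only their signs and mechanisms are.
- The edge model is edge-wise independent; it does not model zero
  inflation, directed grooming, or covariate effects on edges.
- Sickness behaviour, social support effects on recovery, and
  behaviour–disease feedbacks are deliberately outside the model: networks
  are static within a run.
- MixedLM variance components occasionally sit on the boundary (singular)
  for tiny designs; estimates are retained and flagged rather than
  re-parameterized.
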