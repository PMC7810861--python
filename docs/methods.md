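# Methods

## The model

`neurogrn` models the transcriptional core of direct fibroblast-to-neuron
conversion as a five-node gene regulatory network: the splicing repressor
PTB, its neural paralog nPTB, the neuronal microRNA pool **miRs** (an
aggregate of miR-124 and miR-9/9*), the REST repressor complex **RESTc**
(REST plus its cofactor SCP1), and endogenous Ascl1 as the conversion
read-out. Concentrations are relative mRNA levels, normalised so the
fibroblast state is 1 for every measured factor (endogenous Ascl1, which is
undetectable in fibroblasts, is measured in units of its qPCR detection
limit). Time is in hours.

Each node X evolves as

    d[X]/dt = alpha_X * SA(X) - delta_X * [X]

where `SA(X)` is the thermodynamic (Shea–Ackers) promoter-occupancy ratio

    SA(X) = (beta_X + sum_act (T/k_TX)^h_TX + ext_act)
          / (1 + beta_X + sum_act (.) + ext_act + sum_inh (T/k_TX)^h_TX + ext_inh)

The sums run over the node's explicit activators and inhibitors; `k` is a
dissociation constant, `h` a cooperativity exponent (capped at 4).
Regulators outside the network are folded by a change of variables into a
single constitutive background `beta_X`; a node with no activators of any
kind reduces to `SA = 1/(1 + sum_inh)`, where the background is redundant
and therefore dropped. A node carries a `beta_X` exactly when it has at
least one activator (edge or external input) — this reproduces the standard
assignments (miRs and RESTc in the literature network, plus PTB once the
nPTB → PTB edge is added) and generalises consistently to arbitrary
variants.

Two experimental manipulations enter as constant pseudo-regulators rather
than state variables, because the viral/shRNA levels are orders of magnitude
above the endogenous dynamic range and essentially flat in time:
`beta_RESTi` (shREST, a constant inhibitor term in RESTc's denominator) and
`beta_vAscl1` (virally expressed Ascl1, a constant activator term in miRs'
numerator). The three protocol stages differ only in which of these are
active: fibroblast (neither), rest_kd (shREST only, 72 h), conversion
(both, 504 h).

## Deterministic simulation

Fixed-step classic RK4 with step 0.05 h is the contract integrator; all
measurement anchors (8 h, 1–21 d) are multiples of the step, so anchor
values are grid reads, never interpolations. A trailing partial step covers
non-multiple durations; both endpoints are recorded. States are clamped at
zero (with an exposed counter) — with non-negative initial data the exact
flow is non-negative, so clamps only absorb roundoff-scale undershoots. An
adaptive reference integrator (scipy RK45 at rtol 1e-10) is used in the test
suite only.

Per-stage initial states: the fibroblast and knockdown stages start at the
measured baseline (1, 1, 1, 1, 0); the conversion stage starts from the
*observed* day-3 post-knockdown medians rather than the simulated knockdown
endpoint. The objective already penalises the mismatch between those two
quantities, so initialising from data keeps the conversion-stage error
independent of the knockdown-stage error; the carry-over alternative is a
one-line policy switch (`InitialPolicy`).

## Stochastic simulation

The same rate laws drive a Gillespie direct-method simulation with two
channels per node: production of a quantum `eta` at propensity
`alpha*SA/eta`, and decay of a quantum at `delta*[X]/eta`. The expected
drift equals the ODE right-hand side identically for every `eta`, while the
stationary variance of an isolated birth–death node is `eta * mean`
(concentration = eta × Poisson count). The base granularity is 0.1; PTB and
RESTc run at 0.004 (two successive 1/5 adjustments) because they operate
near concentration 1 (others near 5) and fit with much faster turnover, and
equal granularity would give them disproportionate relative noise.
Propensities are recomputed after every event; output is recorded on a
0.5 h grid by last-value carry-forward. The per-run PRNG is the MT19937
generator seeded explicitly, so ensembles are reproducible bit-for-bit from
their seed vectors.

## Parameter fitting

The objective integrates the three stages (conversion truncated at 5 days,
the extent of the fitted data) and scores `-(SSE + R1 + R2)`:

* **SSE** — squared error at six anchors per factor: the knockdown endpoint
  (72 h) and conversion 8 h, 1, 2, 3, 5 d, against the *median* of the three
  replicates. The fibroblast stage contributes nothing here.
* **R1** — smoothness: `lambda * sum_X ∫ |d²f/dt²| dt` over the first five
  conversion days (central differences on the RK4 grid, `edge_order=2`,
  trapezoid quadrature). Suppresses erratic inter-anchor oscillation.
* **R2** — fibroblast stability: `mu * sum_X ∫ |df/dt| dt` over the 72 h
  input-free stage, with the derivative taken from the model right-hand side
  along the trajectory. Encodes that fibroblasts do not convert
  spontaneously. `lambda = mu = 1/20`.

The genetic algorithm evolves one positive real per free parameter
(31 genes for the nPTB → PTB network). Hill genes are stored unbounded and
decoded through `h = 4h'/(1+h')`. Population 100, uniform per-gene
crossover (rate 1/2, random pairing), generational replacement with a
configurable number of elite survivors (default 2, giving mu+lambda
behaviour at larger settings) and tournament selection (default size 4) —
selection and elitism are not dictated by the model, and these are the
smallest settings that keep the best-ever fitness monotone while letting
fine mutations accumulate. Initial genes are Uniform(0, 1); genomes from
fits of simpler topologies can seed the population for more complex ones.

Mutation multiplies each gene by three independent draws from
`m(2/n, 1.01) * m(2/(3n), 1.05) * m(1/(5n), 1.5)`, where `m(p, s)` is 1
with probability `1-p` and otherwise log-normal. The three `s` values are
interpreted as *geometric* standard deviations (log-scale sigma `ln s`,
i.e. multiplicative steps of roughly 1%, 5% and 50%): read instead as raw
log-scale sigmas, 1.01 and 1.05 would define practically identical
distributions and the operator would lose its fine/medium/coarse structure
— and, empirically, the fine component is what lets the search refine a fit
below the data-noise floor. Expected genes touched per genome:
2 + 2/3 + 1/5.

Non-finite or exploding simulations score a worst-fitness sentinel rather
than raising, so the population size is invariant.

**Seeding and nested-model comparison.** Fits of richer topologies can be
seeded from fits of simpler ones: `embed_genome` maps a fitted genome into
an extended topology exactly (an added activation edge starts silent —
large k — and a node that newly gains a background receives a large beta
with its inhibitor dissociation constants rescaled by `beta^(-1/h)`, which
reproduces the pure-repression form to within 1/beta). An added-edge
parameter scan (`edge_profile_seeds`) spreads the seed population over
plausible values of the new edge's k, Hill gene and background, so the
search explores the new interaction from a converged base instead of
rediscovering the shared 28 parameters. Comparisons between nested
topologies at small budgets use the *paired* protocol: one shared base
pre-fit seeds an equal-budget continuation of the base model and an
embedded-plus-scan fit of the richer model. At desk-scale budgets this
matters: random-start fits of the two topologies differ mostly by
convergence luck (the 31-parameter model converges more slowly than the
28-parameter one), and only the paired protocol isolates what the added
edge actually buys.

## Topology comparison

Variants add edges to the literature network among the four actively
regulating nodes (PTB, nPTB, RESTc, miRs): all 12 admissible single
additions (self-edges and second edges on an occupied ordered pair are
excluded), named two-edge combinations, and two literature-motivated
blocks — miRs → Ascl1, and the experimentally observed PTB/nPTB
self-inhibitions (the only context in which self-edges are admitted).
Variants are ranked by raw best GA fitness over a shared budget and shared
restart seeds; no complexity penalty is applied, since the compared
single-addition variants have identical parameter counts. Note that a
time-series fit alone cannot always identify the mechanism: additions that
close some negative feedback loop onto PTB — the direct nPTB → PTB
activation, but also nPTB ⊣ miRs through the indirect loop
PTB ⊣ nPTB ⊣ miRs ⊣ PTB — can fit the dip-and-rebound comparably well, and
separating them requires the perturbation grid.

## Perturbation scenarios

Overexpression multiplies a node's `alpha` by 5, knockdown by 1/5; Ascl1
overexpression and REST knockdown instead toggle `beta_vAscl1` / `beta_RESTi`
on, exactly as in training. A scenario run is a single 14-day window from
the fibroblast baseline (deterministic trajectory + 50 Gillespie
replicates). A replicate converts when endogenous Ascl1 reaches 1 — the
text's "reached at least 1" (≥) is adopted over the table legend's
"exceeded" (a strict mode is exposed); viral Ascl1 is a parameter and is
never counted. A scenario converts when ≥ 1 of its replicates does. The
Ascl1-OX + REST-KD row, a conversion built into the training data, also
reports strict efficiency dominance over Ascl1-OX alone ("Yes+"); no
numeric margin beyond strict inequality is imposed. The deep-knockdown
probe reruns PTB KD at alpha × 1/5000 with and without `beta_RESTc × 1/5`,
isolating the constitutive REST background as the conversion barrier.
Perturbed parameter sets are tagged and refuse a second perturbation, so
multipliers cannot compose silently.

## Arrow dissection

At any state, a node's transcription is decomposed into arrow lengths
`L_act = S_act/(1+S_act)` (the activity that would be realised with no
inhibitors) and `L_inh = S_act*S_inh/((1+S_act)(1+S_act+S_inh))`, so that
`L_act - L_inh = SA` exactly; individual regulators receive sub-lengths
proportional to their `(T/k)^h` terms, with the background and the two
external inputs shown as the pseudo-regulators "constitutive", "shREST" and
"viral_Ascl1". A decay arrow `(delta/alpha)[X]` completes the picture: the
net arrow sum is the rate of change in units of `alpha`. Pure-repression
nodes have an unopposed unit drive (`L_act = 1`, carried by "constitutive",
`L_inh = 1 - SA`), the `S_act → ∞` limit of the general formula.

## Synthetic data

The study's qPCR time series is not deposited, so a generator stands in: it
simulates a ground-truth model through the full protocol, samples the ten
anchors (baseline; day-3 post-KD; conversion 8 h, 1, 2, 3, 5, 7, 14, 21 d),
and draws three replicates per anchor with multiplicative log-normal noise
(default sigma 0.1 — a realistic qPCR fold-change dispersion; replicates of
a ΔΔCt measurement scatter on the log scale). Aggregate nodes get
correlated shadow series (miR-9 tracks miR-124, SCP1 tracks REST, log-scale
jitter 0.05, median correlation > 0.9), and a viral-Ascl1 plateau of 1e5 is
emitted during conversion for schema completeness; neither enters the
objective. The generator refuses a truth whose fibroblast stage drifts
(non-convertible premise), and returns the hidden truth for recovery tests.

The shipped ground truth (nPTB → PTB topology) was designed, not fitted:
`alpha` is solved from the steady-state condition so the baseline is an
exact fibroblast fixed point. Its timescale separation produces the data
signature: miRs and RESTc respond to the input switches within hours
(delta 0.5, 0.4/h), so rising miRs knocks PTB down fast at conversion
onset, while slowly accumulating nPTB (delta 0.02/h) rebuilds PTB through
the added activation — a deep dip (to ≈ 0.5) with a ≥ 0.2 rebound spanning
the day-1 to day-5 anchors. Because PTB's only literature-network
regulator is miRs, and miRs rises monotonically, the feedback-free network
cannot produce this V-shape: it is what makes the added edge identifiable
from the anchors, mirroring how the measured dynamics demanded it.
`make_reference_truth` verifies the screens by simulation (≥ 1 derivative
sign change within 2 days for PTB, RESTc, miRs; < 1% fibroblast drift;
conversion-stage Ascl1 crossing 1) before returning. The
miRs ⊣ RESTc ⊣ miRs double-negative loop makes the truth genuinely
bistable: viral Ascl1 or miRs overexpression flips the switch, REST or PTB
knockdown alone does not. Thresholds are placed so the 8-scenario
stochastic grid gives stable calls at granularity 0.1/0.004; the KD-REST
scenario sits closest to the separatrix and can very rarely (roughly one
seed vector in a hundred) tip to a conversion call through a sustained
miRs excursion.

What the generator does *not* emulate: biological replicate structure
beyond iid noise (no batch effects), measurement censoring at the detection
limit, the neuronal maturation phase, and any protein-level or splicing
mechanism (the model is deliberately agnostic of mechanism). Passing
recovery tests on these data therefore demonstrates correctness of the
pipeline and identifiability of the trajectories under the model's own
assumptions, not performance on real qPCR data.

## Numerical choices and scales

* RK4 step 0.05 h everywhere a trajectory feeds the objective; stochastic
  output grid 0.5 h; conversion stage 504 h (fitting truncates it at 120 h).
* GA problem sizes in the test suite: recovery uses population 100 for 300
  generations from a random start; the nested-topology comparison uses
  three paired restarts of 80-generation segments (pre-fit, literature
  continuation, embedded nPTB → PTB fit). These are single-CPU scales; the
  31-parameter objective is far from fully converged there (its floor,
  measured with a derivative-free local polish, is ≈ −0.11 versus ≈ −0.21
  for the literature network), so per-anchor agreement beyond ~10% should
  not be expected from fits at this scale — the paired protocol is what
  keeps the topology comparison meaningful despite it.
* Scenario ensembles: 50 runs × 336 h, the classifier threshold 1.0
  inclusive.
* Degenerate inputs: zero-duration stages return a single-point trajectory;
  an all-zero propensity state freezes for the remaining time; decay never
  fires from an empty pool; double perturbation and ambiguous Ascl1-OX
  mechanisms raise.

## Known limitations

* SBML interchange is ODE-level (rate rules, constant parameters) with the
  topology mirrored in a model annotation; arbitrary third-party SBML
  (reaction networks, events, function definitions) is rejected with an
  explicit unsupported-feature error rather than partially imported.
* Parameter *identifiability* is not claimed: recovery is asserted for
  trajectories at the data anchors, not for individual constants (the
  steep-Hill regime is plateau-shaped in several directions).
* Conversion efficiencies are qualitative; mapping them onto laboratory
  efficiencies would need single-cell calibration of `eta`.
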