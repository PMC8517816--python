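# Methods

## The model

`companionbn` implements a discrete Bayesian network built entirely from
expert probability elicitation — no parameter is learned from data — for
turning repeated momentary self-report answers into clinical-state estimates
and a ranked list of preventive advice, in the setting of relapse prevention
after a suicide attempt.

Every latent quantity lives on one ordered four-level domain,
`absent < low < medium < high`. For each clinical dimension *i* (anxiety,
mood, sleep, ...) the network tracks three variables:

* **IF_i (immediate value)** — the momentary state, with an a priori
  distribution P(IF_i | context) conditioned on the patient's age group and
  gender (the only contextual variables in the model);
* **CF_i (cumulated value)** — an exponentially forgetting aggregate of past
  immediate states, `CF_new = (1 − α)·IF + α·CF_old` applied elementwise to
  the two probability vectors. α = 0 discards history, α = 1 freezes it;
* **CS_i (contextual severity)** — the clinical seriousness of the current
  state *given the habitual state*, through an elicited table
  P(CS_i | IF_i, CF_i). The table encodes judgments such as: a high moment
  on a high background is almost certainly severe (0.99), a low moment does
  not cancel a high background (0.90), and an isolated spike on an absent
  background is rarely severe (0.05).

Each four-level question *Q* attached to a dimension carries an elicited
answer table P(Q = j | IF_i = k); answers are conditionally independent
given IF (naive-Bayes structure), so one scoring's posterior is

    P(IF = k | answers) ∝ P(IF = k) · Π_q P(answer_q | IF = k),

accumulated in log space. Raw visual-analog scores in [0, 100] are binned to
the four answer levels at cut points 25/50/75 (per-question overridable; a
score on a cut point falls in the upper bin).

Advice relevance uses the **noisy-OR** model: each parent dimension at a
given severity level independently "causes" the advice to be relevant with
its elicited activation probability, plus an optional leak. For independent
parent severity distributions the exact marginal factorizes,

    P(relevant) = 1 − (1 − leak) · Π_p Σ_s P(CS_p = s)·(1 − c_{p,s}),

which keeps elicitation linear in the number of parents (3p + 1 free
parameters against 4^p full-table rows). Absolute scores are normalized
across all advice into a relative ranking (uniform and flagged if all
absolute scores are zero — only possible with zero leaks and all-absent
severities).

### The update cycle

At step 0, CF is initialized to the context prior and IF = CF. Per scoring:
the IF posterior uses the **current CF as its prior** (the static context
prior applies only at step 0) — the habitual state shapes how new answers
are read; then CF is updated by the forgetting rule; then CS is computed
from the new IF and the **updated** CF. The elicited material specifies only
that CS is based on CF, not whether the pre- or post-update CF is meant; we
use the post-update CF because it is the engine's single notion of "current
cumulated state" and already contains the present scoring at weight 1 − α.
IF and CF enter P(CS | IF, CF) as independent distributions within a step;
their temporal coupling is carried entirely by the CF recurrence. CF is
maintained as a distribution over the four levels (not a scalar percent
mean), which is the only reading compatible with the discrete severity
table.

### Numerical policy

Structural zeros in elicited tables are kept exactly 0 — no smoothing. A set
of answers whose likelihood is zero under every level raises a typed
inconsistent-evidence error instead of being silently renormalized; because
products are accumulated in log space, that error can only reflect
structural zeros, never floating-point underflow. All stored distribution
rows must sum to 1 within 1e-9; validation reports every violation with its
location and repairs nothing. Advice ties are broken by model-document
order.

## The default knowledge base

The shipped document (`companionbn/data/default_model.yaml`, format
`companion-bn/1`) has 9 dimensions, 23 questions and 10 pieces of advice.
Anxiety is the fully elicited dimension: its answer table (per-100 counts
100/0/0/0, 5/90/5/0, 0/15/80/5, 0/5/15/80 by latent level), its context
priors (e.g. man over 18: 0.30/0.40/0.15/0.15 in absent..high order) and the
"call friends" activation column (0.50/0.80/0.99 for low/medium/high) are
the expert panel's numbers; the severity table is elicited once and treated
as generic per factor.

The other eight dimensions (mood, cognitive retardation, sleep, appetite,
physical complaints, suicidal ideation, substance use, screen/game use — the
nine reconcile the named symptom categories by splitting cognitive
retardation out of the depression markers) are **placeholders**, marked
`provenance: placeholder`: structurally valid tables from a deterministic
recipe — the severity table verbatim, each context prior an equal-weight
blend of the anxiety prior with a per-dimension base-rate vector, and the
anxiety answer table reused for every question. They complete the structure
without claiming clinical ground truth; any conclusion about a non-anxiety
dimension from the default model is a statement about the recipe, not about
patients.

Advice parent sets and activations beyond the elicited call-friends column
are placeholders too, designed under three constraints: emergency-type
advice (emergency services, referent psychiatrist) activate strongly only at
medium/high severity; mindfulness and cardiac coherence share their anxiety
weights and differ only through cognitive retardation; and the low-level
activation sums are strictly distinct across advice (0.68, 0.56, 0.50, 0.44,
0.38, 0.32, 0.26, 0.20, 0.12, 0.06), so no two advice are exactly tied in
the stable low-severity regime, where scores are dominated by the residual
low-severity mass (≈ 0.01 per parent).

### Forgetting factor α = 0.1

α was never part of the published elicitation. We calibrate it against the
design requirement that a patient with a stable clinical state reach a
stable advice pattern within about three scorings. Under a constant answer
stream the transient part of every score decays as α^t while the gaps
between adjacent stabilized scores are of order 10⁻³ (see above), so
ranking stabilization by step 3 forces α ≲ 0.18. The default 0.1 yields
ranking convergence at exactly step 3 in all four contexts while still
smoothing single-scoring noise (the past keeps 10% weight per scoring, so a
one-off outlier moves CF by at most 90% of its distance to the outlier's
posterior). Models targeting slower-moving dimensions should raise α per
model document; rankings then take proportionally longer to stabilize.

## The in silico simulator

Virtual patients answer 15 scorings. Patterns: `constant_lowest` (all
lowest), `immediate_worsening` (lowest for 9 scorings, highest from scoring
10), `progressive_worsening` (true level ramps linearly in level index over
scorings 10–15: 0,1,1,2,2,3 — a chosen operationalization; no ramp shape is
canonical). Non-target dimensions always answer lowest, isolating
cross-dimension advice effects. Answers are deterministic extremes by
default — the pattern definitions describe fixed answers — with a seeded
`sampled` mode drawing answers from P(answer | IF = true level) for
population-style replication. Seeded runs are bit-reproducible end to end.

What the simulator does and does not emulate: it exercises the engine's
adaptation dynamics under idealized, fully compliant, single-dimension
perturbations. It does not model missed sessions, response styles,
multi-dimension comorbidity trajectories, or any real answer distribution —
so passing simulations validate internal coherence of the elicited model,
not clinical performance.

Observed dynamics on the default model (all recomputed by the test suite):

* extreme profiles bracket the prior in first-order stochastic dominance,
  P(−−) ≤_st prior ≤_st P(++), for every dimension and context;
* after an immediate worsening, CS mass at {medium, high} for the target
  dimension rises monotonically from onset and emergency-type advice scores
  rise strictly between scorings 9 and 15, while advice without the target
  dimension as parent keep absolute scores identical (within 1e-9) to the
  constant-baseline run — only their normalized share falls;
* progressive and immediate patterns agree at scoring 15 on CS mass at
  {medium, high} within 0.05 (0.985 vs 1.000): same terminal evidence,
  different path. Within the progressive ramp's flat segments (two scorings
  at the same true level) the medium+high mass can dip by ~1e-3 as the
  pre-onset transient decays; monotonicity is strict across ramp increments;
* `convergence_steps` — the first scoring after which the full advice
  ranking never changes — is 3 for the constant-lowest scenario in every
  context. This ranking-stability definition is this package's
  operationalization of "a stable advice pattern".

The expert-review loop is represented by exported artifacts (per-step CSV of
IF and negated CS per dimension, matching the plotting convention of
immediate state above zero and severity below; per-step CSV of absolute and
normalized advice scores; a JSON trajectory bundle), not by interactive
tooling.

## Problem sizes

Everything is desk-scale: the joint state space of one dimension's
sub-network is 4^(1+q) ≤ 256, a full 15-scoring simulation of the 9-dimension
model takes milliseconds, and the enumeration oracle used in tests is capped
at 10^6 joint configurations. The sampled-population check averages 500
seeded patients. The full test suite runs in well under a minute.

## Known limitations

* Only anxiety is genuinely elicited; eight dimensions and most activations
  are structural placeholders (clearly flagged in the document).
* The noisy-OR assumption (independent causal contributions per parent) and
  the within-step independence of IF and CF are modeling choices inherited
  from the elicitation design, not tested against data.
* No learning: the engine never updates Θ from usage data.
* The enumeration oracle is test-scope only; there is deliberately no
  general-purpose inference machinery (junction tree, variable elimination).
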