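# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order the pipeline runs.

## Derivation conventions

The axiom is the single symbol `0` and counts as generation 0. This is the
unique convention under which Fib "generation 12" has 233 symbols and Skip
"generation 4" has 97, i.e. the block sizes of the task (89 + 89 + 55 and
97) fall out of the derivation. Positions are 1-based everywhere a position
is reported. Generations are materialised eagerly with parent links; the
generation count is capped at 30 (Fib g30 ≈ 1.3 M symbols) to bound memory.
The concatenation identity is implemented and tested in the orientation
that actually holds under these rules, g_n = g_{n−2} ⌢ g_{n−1} (checked by
brute force on g4 = "01"+"101" and g5 = "101"+"01101" before asserting the
general law).

## Point classification

A k-point is a 1 whose parent is a 0 **and** whose children are exactly
[0 1]; n-points are 1s whose parent is a k; s-points are 1s whose parent is
an n or an s. Classification runs iteratively from generation 1 upward so
parent classes are available; children of a symbol are its rule image, so
the final generation is classified via a one-step lookahead rewrite rather
than left undefined. The downward clause is vacuous in Fib (every 1 rewrites
to 01) but is checked anyway: in Skip a 1 rewrites to 01101, which is what
formally empties the k-set there while greedy [01] segmentation still
strands 1s — the dissociation the whole design turns on.

Segmentation is greedy left-to-right chunking into [01] bigrams; no
tie-break is ever needed because the First Law forces a chunk wherever a 0
occurs. A trailing lone 0 (possible in arbitrary grammatical strings, not in
generated generations, which all end in 1) is left unchunked and unflagged.

## Three-Laws labels and reconstruction

Per-position predictability labels: position 1 is `undefined`; a position
after a 0 is `forced_one`; after the bigram 11, `forced_zero`; after a
single 1 (preceded by 0 or by the string start), `ambiguous`. A string
starting "1…" therefore has position 2 `ambiguous` — one symbol of context
is never enough to decide, which also covers strings shorter than 3.

`reconstruct_from_skeleton` implements the effective filling procedure:
each k is a 1 followed by the forced [0 1]; when the next k is 5 away the
two remaining slots are again forced [0 1]; a 2-slot prefix is forced the
same way. Anything else — gaps outside {3, 5}, a prefix of length other
than 0 or 2, more than 2 trailing slots — is rejected rather than guessed,
because those slots are genuinely under-determined. Round-tripping
skeleton → string → skeleton is exact on Fib generations 5–15.

## Task construction

The 89/89/55 split of g12 is contiguous (and not coincidentally equals
|g10|, |g10|, |g9|). Incongruent trials sit at every index divisible by 6;
the phase is anchored at trial 6 and practice trials are outside the table.
Side assignment is fully determined by congruency (congruent = the response
key's side, incongruent = opposite); nothing in the design requires a
separate left/right randomisation, so the builder is deterministic.
Context windows for the analysis flags read across block boundaries,
including the Fib→Skip junction, because the blocks are presented without
interruption; the junction "…01|01…" introduces no law violation and no
spurious hierarchy target.

## Learner models

The experiment's dependent variables are simulated, so the generator needs
a process model; the package uses the smallest family that dissociates the
three analyses:

* **static** — predicts 0.5 forever. Baseline: no block effects, no
  grammar effect.
* **sequential** — one exponentially updated estimate of P(next = 1) per
  left context (after-0, after-11, after-single-1), chance-initialised,
  update `new = (1−λ)·old + λ·[observed = 1]` with λ = 0.02. With constant
  evidence the estimate follows 1 − 0.5·(1−λ)^N, so the First Law is
  acquired over the first two blocks — consistent with learning appearing
  by block 3 of a 233-trial exposure.
* **structural** — the sequential learner plus k-tracking, gated on
  First-Law confidence (threshold 0.7): once chunking is licensed, it
  detects stranded 1s on line (the second 1 of any 11, or a leading 1) and
  projects the next k-point whenever the gap metric makes it determinate
  (last gap 3 → next in 5; two 5s → next in 3). On Fib every such
  projection is correct; on Skip the stranded-1 gaps never satisfy the
  metric, so projections effectively stop — structure is only learnable
  where it exists.

RT benefit: anticipation ramps linearly from 0 at a confidence threshold
θ = 0.8 to the full `anticipation_gain` (70 ms) at certainty, i.e.
`gain · max(0, (p − θ)/(1 − θ))`. Gating at a level no ambiguous context
can reach is deliberate: the raw frequency of 1 after an ambiguous single-1
context differs between the grammars (≈ .62 in Fib vs ≈ .37 in Skip) even
though both remain formally ambiguous, and an ungated benefit would let a
purely sequential learner fake a hierarchy effect out of that frequency
difference — exactly what the design must exclude, since the two grammars
are meant to offer identical sequential-learning opportunities. A
determinately projected k-slot is deterministic *for the structural
learner*, so it earns the full anticipation gain plus `k_gain` (40 ms).

Learner traces are deterministic functions of the symbol stream, so one
trace per learner is shared across subjects and replicates.

## Response-time model

Per-trial RT is lognormal: `rt = core · exp(ε)`, ε ~ N(0, σ²) with
σ = 0.18, where `core = intercept · (1 − decay·t/100) + 195·[incongruent]
− benefit`, the subject intercept is N(505, 85²) ms, and draws at or above
the 1000 ms deadline become timeouts (recorded as errors, excluded from RT
means). Lognormal noise is the standard choice for strictly positive,
right-skewed RTs. `practice_decay` defaults to 0: across-block speed-up is
carried by learning, so the static learner is a true null for block
effects. Correctness on answered trials is Bernoulli per congruency
(congruent .96, incongruent .70). Defaults were calibrated once against the
descriptive structure of the study this design family comes from: block-1
first-law cell means near 504 ms (congruent) and 699 ms (incongruent), and
an overall correct-response share near 91%. Later-block and
hierarchy-analysis cell means run somewhat faster than the study's printed
tables — the generator reproduces the *contrasts* the analyses test, not
every marginal mean. Seeding: one master seed spawns per-subject
substreams (`numpy.random.SeedSequence`), so cohorts are reproducible and
subjects independent.

What the generator does **not** emulate: trial-order autocorrelation in
residual RT, fatigue/novelty transients (e.g. a block-4 slowdown from
noticing the grammar change), response-repetition and post-error effects,
or between-subject variation in learning rate. Passing tests therefore
show that the analyses recover the effects the generator plants under the
stated noise model — not that children behave like these learners.

## Statistics

The two-factor within-subject ANOVA is computed from the classical
decomposition: SS for subjects, A, B, A×B and the three effect × subject
error terms; F_effect = MS_effect / MS_{effect×subjects};
partial η² = SS_effect / (SS_effect + SS_error). No sphericity correction
is applied by default (two-level factors are immune; a Greenhouse–Geisser
epsilon is available on request). The test suite checks the decomposition
against an independently coded brute-force oracle (and pingouin) to 1e-9
relative tolerance and verifies SS conservation on random designs.

Post-hocs are two-sided paired t-tests on subject-level marginal means
(pooled over congruency), Bonferroni-multiplied by L(L−1)/2 — 6 for four
blocks. A pair with zero within-pair variance reports t = 0, p = 1 when
the difference is zero and an undefined t otherwise.

Condition means use correct, non-timeout target trials only; accuracy is
descriptive (no accuracy ANOVA — RT is the analysed variable). Subjects
with an empty cell are dropped listwise with a logged warning. This
situation arises naturally: the Skip block contains only ~2 incongruent
hierarchy-target trials per subject, so at incongruent accuracy .70 a few
subjects per cohort genuinely have no usable trial there, shrinking the
error df of the hierarchy analysis by a couple of subjects — the same df
reduction a real cohort of this size shows.

## Problem sizes

Stochastic properties (power dissociation, null-calibration of the block
effect) are asserted as rates over 200 seeded replicates of full
22-subject cohorts; measured true rates are ≈ 94% power for the structural
learner's grammar effect and ≈ 5% rejection for the null learners, leaving
comfortable binomial margins around the ≥ 80% / ≤ 10% design targets.
Deterministic string-level properties are exhaustive over Fib generations
up to 20 and Skip up to 6.

## Known limitations

* The learner family is intentionally minimal; it is a design tool, not a
  cognitive model fit to data.
* `reconstruct_from_skeleton` only accepts fully forced skeletons; partial
  reconstruction with explicit unknowns is out of scope.
* The ANOVA requires complete balanced designs after listwise deletion;
  unbalanced or mixed-effects alternatives are deliberately not provided.
* Accuracy is modelled per congruency only, so fine-grained accuracy
  differences between analysis contexts are not reproduced.
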