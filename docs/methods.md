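# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the limitations of `oirdlab`. Notation: y ∈ {0,1} is the
latent OIRD status of a visit, λ_j ∈ {−1,0,1} the vote of labeling
function j (abstain / control / case), π = P(y=1) the class prior.

## The labeling layer

Each of the 14 LFs is a deterministic rule over one visit (the entire
encounter is a single record). Text matching is token-level: notes are
lowercased and split on word characters; single-token terms match whole
tokens only, multi-word phrases match consecutive token runs, and
"nearby" (LF1's naloxone-effect check, LF7's hypoxia-near-opioid check)
means a token-index distance of at most `window` tokens within the same
note. The window defaults to 10 and is configurable; the underlying
clinical guidance never fixed a value, and 10 tokens comfortably spans a
clause without crossing sentence-sized gaps.

Keyword families are configuration data (`LexiconSet`), seeded with every
published example term and extended with a small number of common clinical
synonyms; the full operational lists were never published, so the defaults
are an editorial choice and any list can be replaced from YAML. Negation
is handled only through the explicit phrase lists (e.g. "no response",
"no acute events"); there is no general negation detector — a documented
limitation, not an oversight.

LF1 detects naloxone from the medication-administration table by drug
name across all routes by default. An optional parenteral-only filter
exists because oral naloxone (bowel-regimen use) is a known
false-positive source, but the default keeps all routes since the
original rule was not documented to filter by route. When both
effectiveness and ineffectiveness keywords appear near a naloxone
mention, effectiveness wins (the branch order of the decision table);
the generator never produces that collision, and LF2 — which compares the
two keyword counts across all notes of the visit — is the rule designed
to arbitrate mixed documentation.

## The generative label model

The label model is a two-class latent-class model with full categorical
emissions:

    P(Λ_i) = Σ_y P(y) Π_j θ_j(λ_ij | y).

LF dependencies are deliberately not modeled; overlap and conflict are
reported as diagnostics instead. This is the main modeling
simplification, and it matters most when two LFs fire on the same textual
evidence (LF1 and LF2 share the naloxone-effect lexicons).

Why full emissions rather than a single class-independent casting
probability per LF: twelve of the fourteen LFs are *one-sided* — they
emit only one non-abstain value. For such an LF all information lies in
the class-conditional decision to cast a vote; under a
class-independent-propensity model the votes are deterministic given
casting, and the likelihood is then maximized by a degenerate
single-class solution that "explains" every one-sided column perfectly
(we verified numerically that the degenerate optimum dominates the
planted parameters by thousands of nats and that EM started at the truth
flows to it). With class-conditional emissions the generating process is
inside the model family, the degeneracy disappears, and planted
accuracies are recovered.

The interpretable per-LF summaries are derived from the fit:
propensity β_j = P(λ_j ≠ −1), accuracy α_j = P(λ_j = y | λ_j ≠ −1), and
learned weight log(α_j/(1−α_j)). The weight scale is log-odds accuracy
because the expert ordering used for tuning only needs a scale-free
monotone transform of accuracy.

Fitting is EM with closed-form M-steps. Smoothing adds a symmetric
Dirichlet pseudocount γ (default 1.0) to every emission row, keeping
probabilities off the boundary; this makes the procedure MAP-EM, whose
penalized objective is monotone by construction (the marginal
log-likelihood history is stored and is monotone to numerical tolerance
in all shipped configurations — the penalty is O(γ) against an O(m)
likelihood). Convergence: relative change of the objective below `tol`
(default 1e-6) or `max_iter` (default 500). Responsibilities are
initialized from each row's majority vote at confidence `init_accuracy`
(default 0.7), which anchors class 1 to case votes and breaks the
label-switching symmetry; the class prior is either learned or held fixed
at a configured value (`prior_mode`), the latter being the natural choice
when an epidemiological prevalence estimate exists.

Hyperparameter selection (`tune_by_weight_order`) fits every candidate in
a small grid (over prior mode, γ, initialization) and scores each by the
fraction of expert constraint pairs its learned weights satisfy, with
ties broken by marginal log-likelihood and then grid order. A degenerate
or collapsed fit produces clinically nonsensical weight orderings and is
rejected by this mechanism without ever consulting ground truth — which
is precisely the point of weight-order tuning for a rare outcome, where
too few adjudicated labels exist to tune on empirical accuracy.

The majority-vote baseline breaks ties toward control and votes control
on all-abstain rows: for a sub-1% outcome, "no evidence" should read as
"control".

## The discriminative stage

Features come only from source visits (never from LF votes or label-model
state): age, gender (one indicator per observed level), five code-tag
indicators, naloxone administration, ten keyword-family frequency counts,
respiratory-therapist note count and rapid-response mentions, in a fixed
documented column order. Training labels binarize the generative
posterior at 0.5; sample weights are |p − 0.5| (zero at maximal
uncertainty), and manually adjudicated development-set labels, when
enabled, override the probabilistic label and carry the maximum weight
0.5 so they are never down-weighted relative to a confident generative
label. The two toggles (weighting on/off, manual labels on/off)
reproduce the four sensitivity variants structurally.

The classifier is a certainty-weighted random forest (a weighted logistic
baseline is retained for smoke comparison). Nested cross-validation uses
3 inner folds (grid selection by F1 at a 0.5 cut) inside 10 outer folds
(reporting F1, rank AUC and mean squared error), with stratification on
the binarized label — unstated in the source protocol but necessary at
sub-1% prevalence — and returns the hyperparameter set chosen most often
across outer folds. The default grid (tree count 100, depth ∅/12, leaf
size 1/2, class weighting on/off) is a repo default; the original grid
was not published.

## The synthetic cohort generator

The generator emulates the study regime: ~1% outcome prevalence,
~50,000 visits, multi-visit patients (1.17 visits/patient), an
administrative flag that is a poor proxy for truth, and notes that
contain or omit each LF's keyword families. It does **not** emulate
realistic clinical language (notes are template sentences with injected
keywords), realistic code systems (codes are `SYN:<tag>:<n>` strings with
an explicit qualifying-procedure flag), or longitudinal structure across
a patient's encounters. Passing tests therefore demonstrate that the
*pipeline machinery* is correct under known conditions — planted
parameters are recovered, orderings are reproduced — not that the
shipped lexicons would achieve any particular accuracy on real charts.

Votes are planted, then realized as content. Two-sided LFs (LF1, LF2)
cast with probability p and vote with the truth with probability a. A
one-sided LF voting value v must satisfy a·p ≤ P(y=v), which forces
class-conditional firing rates P(vote|y=v) = a·p/P(y=v) and
P(vote|y≠v) = (1−a)·p/P(y≠v); infeasible (accuracy, propensity,
prevalence) combinations are rejected with a `ConfigError` naming the
field. Two couplings require adjustment passes:

* LF2 cannot abstain when LF1 placed effectiveness/ineffectiveness
  keywords; its direction (hence accuracy) is still drawn freely and its
  off-forced firing rate is deflated analytically so the marginal
  propensity stays near the configured value.
* LF13/LF14 abstain whenever keywords injected for other LFs (or
  background rapid-response mentions) are present; their firing rates are
  renormalized by the empirically measured eligible mass per class. When
  the forced-abstention mass exceeds the planted budget the rate clamps
  at 1 and the realized accuracy drifts slightly above the planted value
  (≤ 0.015 in the shipped configurations, within the ±0.02 fidelity band
  the tests enforce).

The administrative flag is drawn from (truth, sensitivity, PPV) with the
false-positive rate derived as sens·π(1−ppv)/(ppv(1−π)), independent of
note content — reproducing the weak-proxy regime. `ahrq_flag_rate` is
used only when no PPV is configured (flag independent of truth).
Feature-only background content (cardio/cerebrovascular codes, short
ventilation, benign code fillers) is generated at fixed low rates;
confounding sepsis/MI codes never co-occur with an LF11 case vote, since
that combination is contradictory by construction. Background sentences
are verified lexicon-clean by a test.

Default study conditions: prevalence 0.01; flag sensitivity 0.15 and PPV
0.10 (cohort-level — the high test-set flag sensitivity in the original
report is an artifact of flag-enriched test sampling, which the
partitioning reproduces); naloxone-related LF1 at (a=0.98, p=0.995) so
that nearly every true case receives naloxone and ~4% of controls do;
case-keyword LFs at propensities 0.004–0.008 with accuracies 0.70–0.92;
absence-heuristic LFs at high propensity. Marginal feature distributions
(age ~ N(60, 15²) clipped to [18,95], 1–2 benign notes, 6% ED contact)
are convenience defaults, chosen once and documented, not fitted — the
source never described its marginals.

The *balanced benchmark* (`balanced_benchmark_config`) is the
parameter-recovery configuration: prevalence 0.5, planted accuracies
spread over [0.6, 0.95], propensities 0.2–0.5. Balance is what makes a
±0.05 recovery check meaningful — at 1% prevalence the one-sided
feasibility bound caps case-LF propensities near 0.01, leaving a few
dozen votes per LF at n=5000, and the planted pairs in that range are
infeasible outright.

## Cohort partitioning

The elective-status proxy excludes visits whose qualifying surgery day
appears among their ED-visit days. A seeded random patient subset
(default 5% at full scale) forms the test candidate pool — the analog of
the pre-designated held-out patient subset in the original design; every
flagged pool visit plus a random unflagged sample becomes the Test Set,
and non-test visits of test patients are excluded and recorded in the
partition history (patient disjointness is enforced only between test
and non-test, matching the original exclusion of 285 visits).
Development and validation sets are drawn 2:1 flagged:unflagged (floor
rounding on the flagged share); no further stratification is applied.
Enrichment moves the k highest-probability training visits to dev/val,
alternating in descending probability order (dev receives ranks 1,3,5,…)
so the probability mass balances; ties at the cutoff break by ascending
visit id. Control enrichment (low-probability extraction) exists behind
a flag but is off by default. In the pipeline, the synthetic truth of
dev-set visits stands in for the human adjudication of enriched records,
and the final generative fit pools training + development rows.

## Evaluation conventions

Proportions are reported at 3 decimals. A metric with a zero denominator
is *undefined* and reported as missing, never coerced to 0, with one
stated convention: F1 = 0 whenever tp = 0. AUC is the Mann–Whitney rank
statistic with midrank tie handling (delegated to
`sklearn.metrics.roc_auc_score`; an exhaustive pairwise oracle checks it
in the tests). Binary-output approaches (majority vote, the
administrative flag, the joint-threshold rule) use their predictions as
two-valued scores, giving AUC = (sensitivity + specificity)/2 — this
convention reproduces the published baseline AUC of 0.738 exactly from
the published confusion counts. The generative row binarizes at 0.5; the
joint-threshold rule is strict (> 0.8 generative AND > 0.7
discriminative).

## Problem sizes and determinism

The test suite runs the recovery benchmark at n = 5000 × 10 seeds, the
fidelity check at n = 10,000, and the directional pipeline property at
n = 50,000 × 20 seeds (the package's study-scale configuration; one
pipeline run takes a few seconds). One master seed derives every stage
seed as the low 31 bits of sha256("seed:stage"), and a fixed seed
reproduces byte-identical artifacts, which the manifest checksums make
verifiable.

## Known limitations

* Conditional independence of LFs given the outcome; correlated LFs are
  only surfaced through overlap/conflict diagnostics.
* Accuracy is modeled symmetrically per class only in the *derived*
  summary α_j; the emission model itself is class-asymmetric.
* No general negation handling in text matching.
* Synthetic notes exercise the matching machinery, not language
  understanding; lexicon quality on real charts is untested by design.
* The one-sided feasibility bound means very rare outcomes cap how often
  a case-voting LF can fire — a real constraint of the setting, but it
  makes some (accuracy, propensity) configurations unrepresentable.
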