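# Methods

## The analysis procedure

The pipeline operationalizes a determinant analysis for implementation of
health promotion interventions. Its unit of observation is the
*intervention system*: one implemented intervention together with the
triple (behaviour change method, health theme, implementation setting)
that proxies the intervention's function. Its unit of measurement is the
*condition for implementation*: one of 47 survey statements in seven
categories — prime implementer (5), co-implementer(s) (5), intervention
(10), prime implementer's organization (10), co-implementer's
organization(s) (11), broader context (4), implementation strategy (2).

Per intervention × condition:

* **sub-optimal** — presence rated anything but "strongly agree"
  (rating ≠ 5). The cut is deliberately asymmetric: perceived presence is
  strongly right-skewed, so a midpoint split would classify almost
  everything as optimal and hide the bottlenecks.
* **important** — the condition is in the implementer's top-5 of
  importance, rank discarded, duplicates collapsed. Written-in answers are
  recoded onto pre-listed conditions only by exact (case-folded,
  whitespace-normalized) match against a user recode map; unmatched
  write-ins are dropped and counted. Exact matching is a reproducibility
  choice — the original recoding of such answers is a manual judgement
  that a fuzzy matcher would only pretend to replicate.
* **bottleneck** — sub-optimal ∧ important.

Aggregation: per-condition percentages use *all* systems as the
denominator; a missing rating contributes no flag (it can only deflate
percentages, never redistribute them). An `impute_missing_as_suboptimal`
switch provides the opposite reading for sensitivity analysis; the survey
text itself does not disambiguate the handling of missing answers.

Stratified calling: a triple is a *frequent system* when observed strictly
more than `min_count` (default 10) times; a condition is a stratum-level
bottleneck when flagged in strictly more than `threshold` (default 10%) of
the stratum's members. Both cuts are strict because they are defined as
"more than"; the rate comparison is made in exact rational arithmetic
(`Fraction(flagged, members) > Fraction(1, 10)`) so that a 2/20 stratum is
never called by a floating-point whisker.

Congruence: for each frequent system and condition, the system-level call
is compared with the calls in the three characteristic strata the system
belongs to (its method, its theme, its setting). EPB = called in both;
UPB = called in the system only; UAB = called only in a characteristic
stratum; otherwise concordant absent. "Associated with the system's
characteristics" is read **existentially** by default (at least one of the
three matching strata), because the congruence concept is naturally about
*some* characteristic explaining the bottleneck and published examples of
such labels typically cite a single characteristic. The universal reading
(all three strata) is genuinely defensible too and is available as
`require_all_characteristics=True`; neither reading is asserted to be the
original authors' intent. Similarly, characteristic strata contain *all*
records sharing the level by default, with a `frequent_only` restriction
as a sensitivity switch. The characteristic stratum that triggered each
EPB/UAB label is recorded as provenance.

All comparisons are observational; the pipeline computes no inferential
statistics beyond the descriptive cross-condition Pearson correlation
(with its two-sided p-value) between % sub-optimal and % important.

## The synthetic cohort model

The generator emulates the statistical structure such a survey exhibits,
at the scale of the motivating study. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_interventions` | 243 | implemented interventions (one record each) |
| `n_projects` / `n_implementers` | 30 / 120 | ids drawn uniformly / with replacement |
| `method_weights` | 137, 25, 57, 11, 13 | education, regulation, facilitation, citizen participation, case finding |
| `theme_weights` | 123, 102, 16 | overweight, alcohol, other |
| `setting_weights` | 75, 38, 24, 15, 24, 24, 38 | school, outdoor public, sports facility, home, commercial, health/welfare, public building |
| `cutpoints` | −2.0, −1.2, −0.5, 0.16 | latent thresholds; right-skewed so rating 5 is the modal answer |
| `presence_sd` | 1.0 | latent noise scale |
| `presence_base` | spread −0.8 … 0.45 | per-condition latent means |
| `base_importance` | spread −1.5 … 1.5 | per-condition selection logits |
| `importance_presence_coupling` | −0.9 | logit term × (5 − rating) |
| `importance_temperature` | 1.0 | softmax temperature |
| `importance_dropout_rate` | 0.11 | top-5 slots lost to uncodeable write-ins |
| `missing_rate` | 0.02 | uniformly missing ratings |

Presence follows a cumulative latent-threshold ordinal model — the
simplest model with a controllable skew. The default per-condition bases
are spread linearly so that P(rating = 5) spans ≈ 0.17–0.60 across
conditions, reproducing the observed spread of per-condition
sub-optimality (roughly 40–83%, mean ≈ 56%). Importance is a softmax draw
of 5 distinct conditions (Gumbel top-k, exactly equivalent to sequential
sampling without replacement proportional to exp(logit/T)). The coupling
term acts on the sub-optimality gap (5 − rating): with a negative
coefficient, implementers preferentially nominate conditions that are well
in place, which induces the negative cross-condition correlation between
% sub-optimal and % important that such surveys report. The default −0.9
was calibrated once, over 20 seeds, to put the mean correlation near
−0.40; per-condition importance bases are assigned through a fixed
stride permutation so they are not accidentally collinear with the
presence bases. The dropout rate reflects the ≈11% of importance answers
that are typically too unspecific to recode; dropped slots are emitted as
literal uncodeable write-in text so the recoding path is exercised.

Method, theme and setting are drawn independently from their marginal
weights — the joint distribution of real cohorts is not published, so
independence is the minimal assumption. Because independence disperses
mass, such a cohort concentrates less on its top triples than a real
sample does (typically 4–7 frequent systems instead of ~9). The
`joint_system_weights` override lets a config pin expected counts for
chosen triples (each record is drawn from that table with probability
`sum(weights)/n`, from the marginals otherwise); the acceptance script
uses it with the nine frequent triples of the motivating study and a
synthetic per-system allocation of their published total of 140.

Injected effects plant (condition × characteristic level) bottlenecks:
`presence_shift` lowers the latent presence and `importance_boost` raises
the selection logit for all matching records; the pairs are recorded as
ground truth. `recovery_experiment` replays the *full* pipeline per
replicate and reports the per-pair call rate: sensitivity for injected
pairs, false-call rate for all others.

What the generator does **not** model: project- or implementer-level
clustering of answers, implementer covariates, structured nonresponse,
correlations between conditions beyond those induced by the shared
system, and any joint method–theme–setting structure beyond the optional
override. Passing recovery tests therefore shows that the pipeline's
*rules* recover characteristic-linked effects under realistic marginals
and noise — not that any particular real cohort satisfies the model.

## Numerical and scale choices

* Threshold comparisons are exact-rational; float thresholds are
  interpreted via their decimal literal (0.1 ≡ 1/10).
* Percentages are carried at full precision and rendered to one decimal.
* The Pearson correlation raises on constant input vectors or fewer than
  3 conditions rather than returning NaN silently.
* Determinism: every sampler takes a seeded `numpy` Generator; replicate
  seeds are spawned with `SeedSequence`. Identical configs (including
  seed) yield byte-identical CSV exports.
* Problem sizes: the test suite uses the study-scale cohort (n = 243) for
  end-to-end checks, 120 random small instances (≤ 30 records, 6
  conditions) for brute-force oracle equivalence, 200 replicates for the
  recovery experiment and 50 for the correlation sign test; the
  acceptance script uses 120 recovery replicates. These sizes give
  stable Monte-Carlo estimates (binomial s.e. ≤ 0.035 at 200 reps) while
  keeping a full run in well under a minute each.
* The pinned null config for the false-call bound uses flat importance
  bases and a higher flat presence base (1.2): under the defaults, the
  most sub-optimal conditions are legitimately called in small strata
  often enough that a "false-call" bound would conflate natural
  bottlenecks with noise. The null cohort is constructed to contain no
  planted or structural bottlenecks, so any call is noise.

## Known limitations

* The default registry ships placeholder statement texts (the category
  exemplars head each block); computations depend only on ids and
  categories, and a user registry CSV can carry the real texts.
* The ordering of conditions within a category block is arbitrary.
* The EPB/UPB split of a synthetic cohort without injected effects leans
  more towards UPB than a real cohort with strong characteristic-linked
  structure would, because small frequent-system strata are noisier than
  the large characteristic strata they are compared against.
* Free-text recoding is exact-match only, by design.
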